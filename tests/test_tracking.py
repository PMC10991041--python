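import numpy as np
import pytest

from primpulse import BoundingBox, FrameSequence, SynthSpec, make_video, sway_path
from primpulse.tracking import (
    init_filter,
    peak_to_sidelobe_ratio,
    preprocess_patch,
    track,
    track_step,
)

from oracles import oracle_displacement


def _textured_frame(rng, h=80, w=100, patch=None, at=(30, 40)):
    """Flat background with a textured patch pasted at (row, col)."""
    img = np.full((h, w), 40.0)
    if patch is not None:
        ph, pw = patch.shape
        img[at[0] : at[0] + ph, at[1] : at[1] + pw] = patch
    return img


class TestPreprocess:
    def test_all_zero_patch_returns_window_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = preprocess_patch(np.zeros((8, 8)))
        assert out.shape == (8, 8)

    def test_zero_mean_unit_norm_before_window(self, rng):
        p = rng.uniform(0, 255, (16, 16))
        normed = np.log1p(p)
        normed = normed - normed.mean()
        normed /= np.linalg.norm(normed)
        out = preprocess_patch(p)
        # dividing out the Hann window on interior pixels recovers the
        # normalized patch
        win = np.outer(np.hanning(16), np.hanning(16))
        np.testing.assert_allclose(out[4:12, 4:12], (normed * win)[4:12, 4:12], atol=1e-12)

    def test_centered_impulse_stays_maximal_at_center(self):
        p = np.zeros((17, 17))
        p[8, 8] = 100.0
        out = preprocess_patch(p)
        assert np.unravel_index(np.argmax(out), out.shape) == (8, 8)


class TestInitFilter:
    def test_single_term_filter_is_g_fstar_over_ffstar(self, rng):
        patch = rng.uniform(0, 255, (24, 24))
        frame = _textured_frame(rng, patch=patch, at=(10, 10))
        box = BoundingBox(10, 10, 24, 24)
        state = init_filter(frame, box, n_augmentations=1, seed=0)
        F = np.fft.fft2(preprocess_patch(patch))
        from primpulse.tracking import _gaussian_response

        G = np.fft.fft2(_gaussian_response((24, 24), (12, 12), 2.0))
        np.testing.assert_allclose(state.H_conj, G * np.conj(F) / ((F * np.conj(F)).real + 1e-5), rtol=1e-9)

    def test_self_correlation_peaks_at_center(self, rng):
        patch = rng.uniform(0, 255, (32, 32))
        frame = _textured_frame(rng, patch=patch, at=(20, 30))
        state = init_filter(frame, BoundingBox(30, 20, 32, 32), seed=1)
        from primpulse.tracking import _response

        resp = _response(state, frame, state.box)
        py, px = np.unravel_index(np.argmax(resp), resp.shape)
        assert abs(py - 16) <= 1 and abs(px - 16) <= 1

    def test_seed_changes_warps_not_peak_location(self, rng):
        patch = rng.uniform(0, 255, (32, 32))
        frame = _textured_frame(rng, patch=patch, at=(20, 30))
        box = BoundingBox(30, 20, 32, 32)
        from primpulse.tracking import _response

        peaks = []
        for seed in (0, 99):
            state = init_filter(frame, box, seed=seed)
            resp = _response(state, frame, box)
            peaks.append(np.unravel_index(np.argmax(resp), resp.shape))
        assert peaks[0] == peaks[1]

    def test_constant_patch_rejected(self):
        frame = np.full((40, 40), 25.0)
        with pytest.raises(ValueError, match="constant"):
            init_filter(frame, BoundingBox(5, 5, 16, 16), seed=0)

    def test_eta_bounds_enforced(self, rng):
        patch = rng.uniform(0, 255, (16, 16))
        frame = _textured_frame(rng, patch=patch, at=(10, 10))
        with pytest.raises(ValueError, match="eta"):
            init_filter(frame, BoundingBox(10, 10, 16, 16), eta=0.0, seed=0)


class TestTrackStep:
    def test_eta_one_is_memoryless(self, rng):
        patch = rng.uniform(0, 255, (24, 24))
        frame = _textured_frame(rng, patch=patch, at=(20, 30))
        box = BoundingBox(30, 20, 24, 24)
        state = init_filter(frame, box, eta=1.0, n_augmentations=1, seed=0)
        new_state, new_box, _, _ = track_step(state, frame)
        # with eta=1 the accumulators equal the current frame's terms exactly
        from primpulse.tracking import _gaussian_response

        F = np.fft.fft2(preprocess_patch(new_box.crop(frame)))
        G = np.fft.fft2(_gaussian_response((24, 24), (12, 12), state.target_sigma))
        np.testing.assert_allclose(new_state.A, G * np.conj(F), rtol=1e-9)
        np.testing.assert_allclose(new_state.B, (F * np.conj(F)).real, rtol=1e-9)

    def test_static_target_does_not_drift(self, rng):
        patch = rng.uniform(0, 255, (24, 24))
        frame = _textured_frame(rng, patch=patch, at=(20, 30))
        box = BoundingBox(30, 20, 24, 24)
        state = init_filter(frame, box, seed=0)
        for _ in range(50):
            state, new_box, _, _ = track_step(state, frame)
        assert abs(new_box.x - 30) <= 1 and abs(new_box.y - 20) <= 1

    def test_translation_tracked_within_one_pixel_vs_oracle(self, rng):
        patch = rng.uniform(0, 255, (24, 24))
        state = None
        positions = [(20 + 2 * i, 30 + 2 * i) for i in range(8)]  # 2 px/frame diagonal
        frames = [_textured_frame(rng, h=100, w=120, patch=patch, at=p) for p in positions]
        box = BoundingBox(30, 20, 24, 24)
        state = init_filter(frames[0], box, seed=0)
        for i in range(1, len(frames)):
            prev_box = state.box
            state, new_box, _, _ = track_step(state, frames[i])
            true_y, true_x = positions[i]
            assert abs(new_box.x - true_x) <= 1 and abs(new_box.y - true_y) <= 1
            dy, dx = oracle_displacement(
                patch, frames[i], (prev_box.y, prev_box.x), max_shift=4
            )
            assert abs((new_box.y - prev_box.y) - dy) <= 1
            assert abs((new_box.x - prev_box.x) - dx) <= 1


class TestTrack:
    def test_zero_motion_video_keeps_initial_box(self, short_video):
        seq, truth = short_video
        sub = FrameSequence(seq.frames[:100], seq.frame_rate)
        result = track(sub, truth.face_box, seed=0)
        assert not result.loss_flags.any()
        for b in result.boxes:
            assert abs(b.x - truth.face_box.x) <= 1
            assert abs(b.y - truth.face_box.y) <= 1

    def test_sway_followed_exactly(self):
        spec = SynthSpec(hr_bpm=120, duration_s=12, noise_std=1.0, seed=21)
        spec.motion_path = sway_path(spec.n_frames, spec.frame_rate, 8, 0.3)
        seq, truth = make_video(spec)
        result = track(seq, truth.face_box, seed=2)
        errs = [
            max(abs(b.x - tb.x), abs(b.y - tb.y))
            for b, tb in zip(result.boxes, truth.face_boxes)
        ]
        assert max(errs) <= 1

    def test_occlusion_sets_loss_flags(self, rng):
        patch = rng.uniform(100, 255, (20, 20))
        frames = []
        n = 30
        for i in range(n):
            if i < 15:
                frames.append(_textured_frame(rng, h=60, w=80, patch=patch, at=(20, 30)))
            else:  # target disappears: uniform noise replaces the scene
                frames.append(rng.uniform(0, 255, (60, 80)))
        seq = FrameSequence(np.repeat(np.stack(frames)[..., None], 3, axis=-1), 25.0)
        result = track(seq, BoundingBox(30, 20, 20, 20), seed=0)
        assert not result.loss_flags[:14].any()
        assert result.loss_flags[16:].any()

    def test_psr_of_sharp_peak_is_high(self):
        resp = np.zeros((32, 32))
        resp[16, 16] = 1.0
        assert peak_to_sidelobe_ratio(resp) > 20

    def test_initial_box_must_fit(self, short_video):
        seq, _ = short_video
        with pytest.raises(ValueError, match="initial box"):
            track(seq, BoundingBox(0, 0, 1000, 1000), seed=0)
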
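"""Synthetic videos and reference pulse traces with known ground truth.

The generator emulates what the camera actually measures in the motion-based
method: cardiopulmonary activity modulates the light reflected from the
body surface, so the mean intensity of a facial ROI carries a small additive
quasi-sinusoidal component at the heart rate (plus a slower respiratory
component).  A textured "face" patch is rendered on a flat background; its
luma is modulated by

    A_c * sin(phi_hr(t)) + A_r * sin(phi_rr(t))

where the cardiac phase ``phi_hr`` integrates a (possibly piecewise) heart
rate schedule.  Global illumination drift and per-pixel white noise model
the disturbances the decomposition stage must reject, and an optional
motion path translates the patch to exercise the tracker.

Intensity units are on the luma (Y) scale: an amplitude of 1.0 produces a
1.0-unit oscillation of the ROI-mean Y trace.  All randomness flows from
``SynthSpec.seed``; a fixed spec reproduces bit-identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BoundingBox, FrameSequence, Trace

__all__ = ["SynthSpec", "GroundTruth", "make_video", "make_ppg", "sway_path"]

# first-row sum of the luma coefficients: converts Y-scale amplitudes to the
# equal-RGB pixel increments that produce them
_Y_GAIN = (65.841 + 128.553 + 24.966) / 255.0


def _hr_schedule(hr_bpm, duration_s: float):
    """Normalize hr_bpm (scalar or [(start_s, bpm), ...]) to a step function."""
    if np.isscalar(hr_bpm):
        return [(0.0, float(hr_bpm))]
    sched = [(float(t), float(v)) for t, v in hr_bpm]
    if not sched or sched[0][0] != 0.0:
        raise ValueError("hr_bpm schedule must start at t=0")
    if any(t1 >= t2 for (t1, _), (t2, _) in zip(sched, sched[1:])):
        raise ValueError("hr_bpm schedule times must increase")
    return sched


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording."""

    hr_bpm: float | list = 120.0  # scalar or piecewise [(start_s, bpm), ...]
    hrv_std: float = 0.0  # beat-to-beat interval jitter SD, seconds
    rr_bpm: float = 18.0
    pulse_amplitude: float = 1.0  # cardiac amplitude, luma units (0-255 scale)
    resp_amplitude: float = 0.5
    noise_std: float = 0.5  # per-pixel white noise, 0-255 RGB scale
    illum_drift: tuple[float, float] = (2.0, 0.1)  # (amplitude, Hz) global
    motion_path: np.ndarray | None = None  # (n, 2) per-frame (dx, dy), pixels
    duration_s: float = 110.0
    frame_rate: float = 25.0
    frame_size: tuple[int, int] = (120, 160)  # (height, width)
    face_size: tuple[int, int] = (48, 48)
    seed: int | None = None

    def __post_init__(self) -> None:
        sched = _hr_schedule(self.hr_bpm, self.duration_s)
        for _, bpm in sched:
            if not 2.0 * bpm / 60.0 < self.frame_rate:
                raise ValueError(
                    f"frame rate {self.frame_rate} under-samples {bpm} BPM (Nyquist)"
                )
        if self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


@dataclass
class GroundTruth:
    """What the generator actually rendered."""

    beat_times: np.ndarray  # seconds of each cardiac oscillation peak
    hr_per_frame: np.ndarray  # instantaneous HR (BPM) at each frame
    face_box: BoundingBox  # patch position in frame 0
    face_boxes: list[BoundingBox]  # per-frame patch positions
    spec: SynthSpec

    def true_hr(self, t_start: float, t_end: float) -> float:
        """Mean scheduled HR over [t_start, t_end)."""
        fr = self.spec.frame_rate
        i0, i1 = int(t_start * fr), int(t_end * fr)
        return float(np.mean(self.hr_per_frame[i0:max(i1, i0 + 1)]))

    def true_hr_series(self, window_s: float = 10.0):
        import pandas as pd

        n_win = int(self.spec.duration_s // window_s)
        rows = [
            (k * window_s, self.true_hr(k * window_s, (k + 1) * window_s))
            for k in range(n_win)
        ]
        return pd.DataFrame(rows, columns=["window_start_s", "hr_bpm"])


def _cardiac_phase(spec: SynthSpec, t: np.ndarray) -> np.ndarray:
    """Integrated phase 2*pi*int f(t) dt of the (piecewise) HR schedule."""
    sched = _hr_schedule(spec.hr_bpm, spec.duration_s)
    phase = np.zeros_like(t)
    acc = 0.0
    for i, (t0, bpm) in enumerate(sched):
        t1 = sched[i + 1][0] if i + 1 < len(sched) else np.inf
        f = bpm / 60.0
        m = t >= t0
        phase[m] = acc + 2.0 * np.pi * f * (t[m] - t0)
        if np.isfinite(t1):
            acc += 2.0 * np.pi * f * (t1 - t0)
    return phase


def _beat_times(spec: SynthSpec) -> np.ndarray:
    """Times of the cardiac oscillation peaks.

    With ``hrv_std == 0`` these are the peaks of the scheduled sinusoid
    (phase = pi/2 mod 2*pi).  With beat-to-beat variability, successive
    intervals are the scheduled period plus independent Gaussian jitter —
    drawn from a stream derived from ``spec.seed`` so video and reference
    trace share the identical ground-truth beat sequence.
    """
    if spec.hrv_std <= 0.0:
        fine = np.arange(0.0, spec.duration_s, 1.0 / (20.0 * spec.frame_rate))
        phase = _cardiac_phase(spec, fine)
        k = np.arange(
            np.ceil((phase[0] - np.pi / 2) / (2 * np.pi)),
            (phase[-1] - np.pi / 2) / (2 * np.pi) + 1,
        )
        targets = np.pi / 2 + 2 * np.pi * k
        return np.interp(targets, phase, fine)
    rng = np.random.default_rng(None if spec.seed is None else [spec.seed, 77])
    sched = _hr_schedule(spec.hr_bpm, spec.duration_s)

    def freq_at(tt: float) -> float:
        f = sched[0][1] / 60.0
        for t0, bpm in sched:
            if tt >= t0:
                f = bpm / 60.0
        return f

    beats = [0.25 / freq_at(0.0)]  # first sinusoid peak, a quarter period in
    while True:
        period = 1.0 / freq_at(beats[-1])
        nxt = beats[-1] + max(0.2 * period, period + rng.normal(0.0, spec.hrv_std))
        if nxt >= spec.duration_s:
            break
        beats.append(nxt)
    return np.asarray(beats)


def _beat_phase(beats: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Phase hitting pi/2 + 2*pi*k at beat k, linear in between."""
    # extend one beat on each side so the edges keep oscillating
    ext = np.concatenate([[2 * beats[0] - beats[1]], beats, [2 * beats[-1] - beats[-2]]])
    ks = np.pi / 2 + 2 * np.pi * (np.arange(len(ext)) - 1)
    return np.interp(t, ext, ks)


def _face_texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Static textured patch: smoothed noise with strong local structure."""
    from scipy import ndimage

    tex = rng.uniform(0.0, 1.0, shape)
    tex = ndimage.gaussian_filter(tex, 1.5)
    tex = (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)
    return 90.0 + 90.0 * tex  # mid-gray face, well separated from background


def sway_path(
    n_frames: int, frame_rate: float, amplitude_px: float, freq_hz: float = 0.3
) -> np.ndarray:
    """Sinusoidal horizontal head sway as a per-frame (dx, dy) offset path."""
    t = np.arange(n_frames) / frame_rate
    dx = np.rint(amplitude_px * np.sin(2 * np.pi * freq_hz * t)).astype(int)
    return np.stack([dx, np.zeros_like(dx)], axis=1)


def make_video(spec: SynthSpec) -> tuple[FrameSequence, GroundTruth]:
    """Render the synthetic recording.

    Returns the frame sequence (uint8 RGB) and the ground truth (beat times,
    per-frame HR, per-frame face position).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    fh, fw = spec.face_size
    n = spec.n_frames
    t = np.arange(n) / spec.frame_rate

    base_y = (h - fh) // 2
    base_x = (w - fw) // 2
    if spec.motion_path is None:
        path = np.zeros((n, 2), dtype=int)
    else:
        path = np.asarray(spec.motion_path, dtype=int)
        if path.shape != (n, 2):
            raise ValueError(f"motion_path must have shape ({n}, 2), got {path.shape}")

    xs = base_x + path[:, 0]
    ys = base_y + path[:, 1]
    if xs.min() < 0 or ys.min() < 0 or xs.max() + fw > w or ys.max() + fh > h:
        raise ValueError("motion path takes the face patch outside the frame")

    texture = _face_texture((fh, fw), rng)
    beats = _beat_times(spec)
    if spec.hrv_std > 0.0:
        phase_hr = _beat_phase(beats, t)
    else:
        phase_hr = _cardiac_phase(spec, t)
    cardiac = spec.pulse_amplitude * np.sin(phase_hr)
    resp = spec.resp_amplitude * np.sin(2 * np.pi * spec.rr_bpm / 60.0 * t)
    illum = spec.illum_drift[0] * np.sin(2 * np.pi * spec.illum_drift[1] * t)

    background = 60.0
    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    boxes = []
    for i in range(n):
        img = np.full((h, w), background)
        img += illum[i]
        patch = texture + (cardiac[i] + resp[i]) / _Y_GAIN
        img[ys[i] : ys[i] + fh, xs[i] : xs[i] + fw] = patch
        rgb = np.repeat(img[:, :, None], 3, axis=2)
        if spec.noise_std > 0:
            rgb = rgb + rng.normal(0.0, spec.noise_std, rgb.shape)
        frames[i] = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
        boxes.append(BoundingBox(int(xs[i]), int(ys[i]), fw, fh))

    sched = _hr_schedule(spec.hr_bpm, spec.duration_s)
    hr_per_frame = np.empty(n)
    for i, (t0, bpm) in enumerate(sched):
        t1 = sched[i + 1][0] if i + 1 < len(sched) else np.inf
        hr_per_frame[(t >= t0) & (t < t1)] = bpm

    seq = FrameSequence(frames, spec.frame_rate)
    truth = GroundTruth(
        beat_times=beats,
        hr_per_frame=hr_per_frame,
        face_box=boxes[0],
        face_boxes=boxes,
        spec=spec,
    )
    return seq, truth


def make_ppg(
    spec: SynthSpec,
    sample_rate: float = 100.0,
    jitter_s: float = 0.0,
    dropouts: list[tuple[float, float]] | None = None,
    pulse_width_s: float = 0.12,
) -> Trace:
    """Quasi-periodic reference pulse waveform at the spec's heart rate.

    Gaussian-shaped pulses are placed at the true beat times, optionally
    jittered (independent N(0, jitter_s) per beat) and with dropout bursts
    (start_s, duration_s) during which the waveform flatlines — emulating a
    noisy contact sensor whose missed beats the interval filter must remove.
    """
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    beats = _beat_times(spec)
    if jitter_s > 0:
        beats = np.sort(beats + rng.normal(0.0, jitter_s, beats.shape))
    tt = np.arange(0.0, spec.duration_s, 1.0 / sample_rate)
    v = np.zeros_like(tt)
    for b in beats:
        lo = np.searchsorted(tt, b - 5 * pulse_width_s)
        hi = np.searchsorted(tt, b + 5 * pulse_width_s)
        v[lo:hi] += np.exp(-0.5 * ((tt[lo:hi] - b) / pulse_width_s) ** 2)
    for start, dur in dropouts or []:
        v[(tt >= start) & (tt < start + dur)] = 0.0
    return Trace(v, sample_rate)
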
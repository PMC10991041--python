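"""MOSSE correlation-filter tracking for ROI stabilization.

The Minimum Output Sum of Squared Error (MOSSE) tracker learns a correlation
filter H* in the Fourier domain that maps the appearance of the target patch
F to a desired Gaussian response G peaked on the target:

    H* = sum_i G_i . conj(F_i) / sum_i F_i . conj(F_i)          (init)
    H* = A_i / B_i
    A_i = eta * G_i . conj(F_i) + (1 - eta) * A_{i-1}           (update)
    B_i = eta * F_i . conj(F_i) + (1 - eta) * B_{i-1}

with "." elementwise multiplication and eta the learning rate (default
0.125).  Each frame the patch at the previous box is correlated with H*; the
response argmax gives the displacement, the box is moved, and A/B are updated
with the patch at the new location.  Tracking quality is monitored with the
peak-to-sidelobe ratio (PSR); low PSR flags target loss.

Translation only: the box size is fixed over the track, matching the filter
formulation, which has no scale term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .colorspace import luma
from .io import BoundingBox, FrameSequence

__all__ = ["MosseState", "TrackResult", "preprocess_patch", "init_filter", "track_step", "track"]

EPS = 1e-5  # denominator regularization; standard MOSSE practice


@dataclass
class MosseState:
    A: np.ndarray  # running numerator accumulator (Fourier domain)
    B: np.ndarray  # running denominator accumulator (real, >= 0)
    eta: float
    target_sigma: float
    box: BoundingBox

    def __post_init__(self) -> None:
        if not (0.0 < self.eta <= 1.0):
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        if self.A.shape != self.B.shape:
            raise ValueError("A and B must share the ROI's dimensions")

    @property
    def H_conj(self) -> np.ndarray:
        """The learned filter H* = A / (B + eps)."""
        return self.A / (self.B + EPS)


@dataclass
class TrackResult:
    boxes: list[BoundingBox]
    psr: np.ndarray
    loss_flags: np.ndarray  # bool, True where the target was lost

    def __len__(self) -> int:
        return len(self.boxes)


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    hy = np.hanning(shape[0])
    hx = np.hanning(shape[1])
    return np.outer(hy, hx)


def preprocess_patch(patch: np.ndarray) -> np.ndarray:
    """Bolme-style patch preprocessing: log, zero-mean/unit-norm, Hann window.

    A constant patch has zero norm after centering; it is returned as the
    bare window with a warning rather than dividing by zero.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2:
        raise ValueError("patch must be a 2-D luma crop")
    window = _hann2d(patch.shape)
    p = np.log1p(np.maximum(patch, 0.0))
    p = p - p.mean()
    norm = np.linalg.norm(p)
    if norm < 1e-12:
        warnings.warn("constant patch: preprocessing returns window only")
        return window
    return (p / norm) * window


def _gaussian_response(shape: tuple[int, int], center: tuple[float, float], sigma: float) -> np.ndarray:
    """2-D Gaussian peaked at ``center`` (row, col)."""
    ys = np.arange(shape[0])[:, None] - center[0]
    xs = np.arange(shape[1])[None, :] - center[1]
    return np.exp(-(ys**2 + xs**2) / (2.0 * sigma**2))


def _random_warp(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Small random affine warp of the training patch (rotation + scale)."""
    from scipy import ndimage

    angle = rng.uniform(-5.0, 5.0)
    scale = rng.uniform(0.95, 1.05)
    warped = ndimage.rotate(patch, angle, reshape=False, mode="reflect", order=1)
    mat = np.eye(2) / scale
    offset = (np.array(patch.shape) - mat @ np.array(patch.shape)) / 2.0
    return ndimage.affine_transform(warped, mat, offset=offset, mode="reflect", order=1)


def init_filter(
    frame: np.ndarray,
    box: BoundingBox,
    *,
    eta: float = 0.125,
    target_sigma: float = 2.0,
    n_augmentations: int = 8,
    seed: int | None = None,
) -> MosseState:
    """Initialize a MOSSE filter on the luma crop at ``box``.

    ``frame`` is a single RGB frame (h, w, 3) or a luma image (h, w).
    ``n_augmentations`` randomly warped copies of the patch are summed into
    the numerator/denominator accumulators; the first term uses the
    unwarped patch.
    """
    img = luma(frame) if frame.ndim == 3 else np.asarray(frame, dtype=float)
    if not box.fits_in(*img.shape):
        raise ValueError(f"box {box} not inside frame {img.shape}")
    patch = box.crop(img)
    if np.ptp(patch) < 1e-12:
        raise ValueError("cannot initialize tracker on a constant patch")
    rng = np.random.default_rng(seed)
    # integer center so a static target yields an unambiguous response argmax
    center = (box.height // 2, box.width // 2)
    G = np.fft.fft2(_gaussian_response(patch.shape, center, target_sigma))
    A = np.zeros(patch.shape, dtype=complex)
    B = np.zeros(patch.shape, dtype=float)
    for i in range(max(1, n_augmentations)):
        p = patch if i == 0 else _random_warp(patch, rng)
        F = np.fft.fft2(preprocess_patch(p))
        A += G * np.conj(F)
        B += (F * np.conj(F)).real
    return MosseState(A=A, B=B, eta=eta, target_sigma=target_sigma, box=box)


def _response(state: MosseState, img: np.ndarray, box: BoundingBox) -> np.ndarray:
    F = np.fft.fft2(preprocess_patch(box.crop(img)))
    return np.fft.ifft2(F * state.H_conj).real


def peak_to_sidelobe_ratio(response: np.ndarray, exclude: int = 5) -> float:
    """(peak - sidelobe mean) / sidelobe std, excluding an 11x11 peak window."""
    peak_idx = np.unravel_index(np.argmax(response), response.shape)
    mask = np.ones(response.shape, dtype=bool)
    y0, x0 = peak_idx
    mask[
        max(0, y0 - exclude) : y0 + exclude + 1,
        max(0, x0 - exclude) : x0 + exclude + 1,
    ] = False
    sidelobe = response[mask]
    sd = sidelobe.std()
    if sd < 1e-12:
        return np.inf
    return float((response[peak_idx] - sidelobe.mean()) / sd)


def track_step(
    state: MosseState, frame: np.ndarray
) -> tuple[MosseState, BoundingBox, float, bool]:
    """One localization + update step.

    Returns (new_state, new_box, psr, at_boundary).  The correlation
    response at the previous box locates the target; the filter is then
    updated with the patch at the NEW location.
    """
    img = luma(frame) if frame.ndim == 3 else np.asarray(frame, dtype=float)
    resp = _response(state, img, state.box)
    psr = peak_to_sidelobe_ratio(resp)
    py, px = np.unravel_index(np.argmax(resp), resp.shape)
    # the trained response peaks at the patch center for a centered target,
    # so displacement is the argmax offset from that center
    dy = py - resp.shape[0] // 2
    dx = px - resp.shape[1] // 2
    box = state.box
    nx = min(max(box.x + int(dx), 0), img.shape[1] - box.width)
    ny = min(max(box.y + int(dy), 0), img.shape[0] - box.height)
    clamped = BoundingBox(nx, ny, box.width, box.height)
    at_boundary = (nx != box.x + int(dx)) or (ny != box.y + int(dy))

    center = (clamped.height // 2, clamped.width // 2)
    G = np.fft.fft2(_gaussian_response((clamped.height, clamped.width), center, state.target_sigma))
    F = np.fft.fft2(preprocess_patch(clamped.crop(img)))
    A = state.eta * G * np.conj(F) + (1.0 - state.eta) * state.A
    B = state.eta * (F * np.conj(F)).real + (1.0 - state.eta) * state.B
    return replace(state, A=A, B=B, box=clamped), clamped, psr, at_boundary


def track(
    seq: FrameSequence,
    initial_box: BoundingBox,
    *,
    eta: float = 0.125,
    target_sigma: float = 2.0,
    n_augmentations: int = 8,
    psr_threshold: float = 5.0,
    seed: int | None = None,
) -> TrackResult:
    """Track ``initial_box`` through the sequence.

    Frames whose correlation peak-to-sidelobe ratio drops below
    ``psr_threshold`` (or where the box hit the frame boundary) are flagged
    as target loss; downstream segment qualification excludes them.
    """
    if not seq.contains(initial_box):
        raise ValueError(f"initial box {initial_box} not inside frames {seq.frame_shape}")
    state = init_filter(
        seq.frames[0],
        initial_box,
        eta=eta,
        target_sigma=target_sigma,
        n_augmentations=n_augmentations,
        seed=seed,
    )
    n = len(seq)
    boxes = [initial_box]
    psrs = np.full(n, np.inf)
    lost = np.zeros(n, dtype=bool)
    for t in range(1, n):
        state, box, psr, at_boundary = track_step(state, seq.frames[t])
        boxes.append(box)
        psrs[t] = psr
        lost[t] = (psr < psr_threshold) or at_boundary
    return TrackResult(boxes=boxes, psr=psrs, loss_flags=lost)
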
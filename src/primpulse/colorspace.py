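"""RGB -> YCbCr conversion and ROI mean-intensity extraction.

The luma (Y) channel carries the motion signal: subtle head/body movement
driven by cardiopulmonary activity modulates the light reflected into the
camera, so averaging Y over a facial ROI yields a raw ballistocardiographic
trace.  Chroma (Cb, Cr) is computed but unused downstream.

Two coefficient sets are offered.  The default ("paper") matrix follows the
source method's printed coefficients; "bt601" is the ITU-R BT.601 full-range
studio-swing matrix they approximate.  They differ in three entries at the
third decimal and are interchangeable in practice, since only the temporal
variation of Y matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import BoundingBox, FrameSequence, Trace

__all__ = ["ColorMatrix", "PAPER_MATRIX", "BT601_MATRIX", "rgb_to_ycbcr", "roi_mean_intensity"]


@dataclass(frozen=True)
class ColorMatrix:
    """3x3 RGB->YCbCr coefficients (RGB on [0,1]) plus a 0-255-scale offset."""

    matrix: np.ndarray
    offset: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        o = np.asarray(self.offset, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"color matrix must be 3x3, got {m.shape}")
        if o.shape != (3,):
            raise ValueError(f"color offset must be a 3-vector, got {o.shape}")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "offset", o)


PAPER_MATRIX = ColorMatrix(
    matrix=np.array(
        [
            [65.841, 128.553, 24.966],
            [-39.797, -74.203, 112.0],
            [112.0, -93.786, -18.2214],
        ]
    ),
    offset=np.array([16.0, 128.0, 128.0]),
    name="paper",
)

BT601_MATRIX = ColorMatrix(
    matrix=np.array(
        [
            [65.481, 128.553, 24.966],
            [-37.797, -74.203, 112.0],
            [112.0, -93.786, -18.214],
        ]
    ),
    offset=np.array([16.0, 128.0, 128.0]),
    name="bt601",
)

_PRESETS = {"paper": PAPER_MATRIX, "bt601": BT601_MATRIX}


def get_color_matrix(spec: str | ColorMatrix) -> ColorMatrix:
    if isinstance(spec, ColorMatrix):
        return spec
    try:
        return _PRESETS[spec]
    except KeyError:
        raise ValueError(
            f"unknown color matrix {spec!r}; use 'paper', 'bt601' or a ColorMatrix"
        ) from None


def rgb_to_ycbcr(
    frame: np.ndarray, color_matrix: str | ColorMatrix = "paper"
) -> np.ndarray:
    """Convert RGB pixels (canonical 0-255 scale) to YCbCr.

    Per pixel: ``[Y, Cb, Cr] = M @ [R, G, B]/255 + [16, 128, 128]``.  The
    division by 255 reflects the convention of the coefficients, whose first
    row sums to ~219 so that Y spans [16, 235].

    Accepts a single frame (h, w, 3) or a stack (n, h, w, 3).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim < 1 or frame.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB channel axis of size 3, got shape {frame.shape}")
    cm = get_color_matrix(color_matrix)
    return (frame / 255.0) @ cm.matrix.T + cm.offset


def luma(frame: np.ndarray, color_matrix: str | ColorMatrix = "paper") -> np.ndarray:
    """Y channel only (cheaper than full conversion for long sequences)."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB channel axis of size 3, got shape {frame.shape}")
    cm = get_color_matrix(color_matrix)
    return (frame / 255.0) @ cm.matrix[0] + cm.offset[0]


def roi_mean_intensity(
    seq: FrameSequence,
    boxes: BoundingBox | Sequence[BoundingBox],
    color_matrix: str | ColorMatrix = "paper",
) -> Trace:
    """Mean Y intensity inside the ROI of every frame.

    ``boxes`` is either one fixed box applied to all frames or one box per
    frame (e.g. from the tracker).  The result is a Trace sampled at the
    sequence frame rate: ``i_Y(t) = sum_{(x,y) in ROI} I(x,y,t) / |ROI|``.
    """
    n = len(seq)
    if isinstance(boxes, BoundingBox):
        boxes = [boxes] * n
    if len(boxes) != n:
        raise ValueError(f"need one box per frame: got {len(boxes)} boxes for {n} frames")
    h, w = seq.frame_shape
    values = np.empty(n)
    for t, box in enumerate(boxes):
        if not box.fits_in(h, w):
            raise ValueError(f"ROI {box} exceeds frame bounds {h}x{w} at frame {t}")
        patch = box.crop(seq.frames[t])
        values[t] = float(np.mean(luma(patch, color_matrix)))
    return Trace(values, sample_rate=seq.frame_rate)
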
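"""Frame-sequence and trace I/O, plus the coordinate/value conventions.

All pixel data are carried on the canonical 0-255 real-valued scale; sources
delivered as normalized reals in [0, 1] are rescaled on ingestion.  Bounding
boxes are 0-based, half-open rectangles: a box at (x, y, w, h) selects the
pixel block ``frame[y:y+h, x:x+w]`` — exactly ``w*h`` pixels.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "BoundingBox",
    "Trace",
    "read_video",
    "write_frames",
    "read_trace",
    "write_trace",
]

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class BoundingBox:
    """Rectangular ROI in pixel coordinates (0-based, half-open)."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        for name in ("x", "y", "width", "height"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"BoundingBox.{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.width <= 0 or self.height <= 0:
            raise ValueError("BoundingBox width/height must be positive")
        if self.x < 0 or self.y < 0:
            raise ValueError("BoundingBox corner must be non-negative")

    @property
    def size(self) -> int:
        """|ROI|: number of pixels inside the box."""
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    def fits_in(self, height: int, width: int) -> bool:
        return self.x + self.width <= width and self.y + self.height <= height

    def shifted(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.x + dx, self.y + dy, self.width, self.height)

    def clamped(self, height: int, width: int) -> "BoundingBox":
        x = min(max(self.x, 0), width - self.width)
        y = min(max(self.y, 0), height - self.height)
        return BoundingBox(x, y, self.width, self.height)

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.y : self.y + self.height, self.x : self.x + self.width]


@dataclass
class FrameSequence:
    """Ordered stack of RGB frames with a frame rate.

    frames : (n, height, width, 3) array, channel order R,G,B, values on the
        canonical 0-255 scale (any dtype; uint8 is kept to save memory).
    frame_rate : frames per second.
    """

    frames: np.ndarray
    frame_rate: float
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (n, h, w, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] == 0:
            raise ValueError("empty frame sequence")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of each frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return len(self) / self.frame_rate

    def contains(self, box: BoundingBox) -> bool:
        h, w = self.frame_shape
        return box.fits_in(h, w)


@dataclass
class Trace:
    """Uniformly sampled 1-D signal."""

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be 1-D")
        if self.values.size < 1:
            raise ValueError("Trace must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.sample_rate

    def slice(self, start: int, stop: int) -> "Trace":
        """Sub-trace over sample indices [start, stop)."""
        if not (0 <= start < stop <= len(self)):
            raise IndexError(f"invalid trace slice [{start}, {stop})")
        return Trace(
            self.values[start:stop],
            self.sample_rate,
            t0=self.t0 + start / self.sample_rate,
        )

    def with_values(self, values: np.ndarray) -> "Trace":
        if len(values) != len(self):
            raise ValueError("replacement values must preserve length")
        return replace(self, values=np.asarray(values, dtype=float))


def _natural_key(name: str):
    # frame_2.png sorts before frame_10.png
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name)]


def _canonical_frames(arr: np.ndarray, policy: str) -> np.ndarray:
    """Coerce a decoded frame stack to RGB on the 0-255 scale."""
    if arr.ndim == 3:  # grayscale stack
        warnings.warn("grayscale source: replicating across RGB channels")
        arr = np.repeat(arr[..., None], 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if policy == "auto":
        policy = "unit" if np.issubdtype(arr.dtype, np.floating) and arr.max() <= 1.0 else "byte"
    if policy == "unit":
        arr = np.asarray(arr, dtype=float) * 255.0
    elif policy != "byte":
        raise ValueError(f"unknown value_range_policy {policy!r}")
    return arr


def read_video(
    path: str | os.PathLike,
    frame_rate: float | None = None,
    value_range_policy: str = "auto",
) -> FrameSequence:
    """Read a video container or a directory of numbered frame images.

    Parameters
    ----------
    path : file or directory.  A directory is read as lexicographically
        (naturally) ordered image files and **requires** ``frame_rate``,
        since bare frames embed no timing metadata.
    frame_rate : override/supply frames per second.  For containers the
        rate from the metadata is used when this is None.
    value_range_policy : "auto" | "byte" | "unit" — how to interpret the
        pixel scale of the source ("unit" rescales [0,1] floats to 0-255).
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        if frame_rate is None:
            raise ValueError(
                "frame directories carry no frame-rate metadata; pass frame_rate="
            )
        names = sorted(
            (n for n in os.listdir(path) if os.path.splitext(n)[1].lower() in _IMAGE_EXTS),
            key=_natural_key,
        )
        if not names:
            raise ValueError(f"no image frames found in directory {path!r}")
        import imageio.v3 as iio

        frames = np.stack([iio.imread(os.path.join(path, n)) for n in names])
        return FrameSequence(_canonical_frames(frames, value_range_policy), frame_rate)

    if not os.path.exists(path):
        raise FileNotFoundError(f"cannot read video: no such path {path!r}")
    try:
        import imageio.v3 as iio

        frames = np.stack(list(iio.imiter(path)))
        if frame_rate is None:
            meta = iio.immeta(path)
            frame_rate = float(meta.get("fps", 0.0)) or None
    except Exception as exc:  # pragma: no cover - depends on codec plugins
        raise IOError(f"cannot decode video container {path!r}: {exc}") from exc
    if frames.shape[0] == 0:
        raise ValueError(f"video {path!r} contains zero frames")
    if frame_rate is None:
        raise ValueError(f"container {path!r} reports no frame rate; pass frame_rate=")
    return FrameSequence(_canonical_frames(frames, value_range_policy), frame_rate)


def write_frames(seq: FrameSequence, directory: str | os.PathLike) -> list[str]:
    """Write a frame sequence as zero-padded PNG files (lossless round trip)."""
    import imageio.v3 as iio

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    width = max(6, len(str(len(seq))))
    paths = []
    data = np.clip(np.rint(seq.frames), 0, 255).astype(np.uint8)
    for i, frame in enumerate(data):
        p = os.path.join(directory, f"frame_{i:0{width}d}.png")
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def write_trace(trace: Trace, path: str | os.PathLike) -> None:
    """Write a trace as CSV with columns time_s,value (full double precision)."""
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path: str | os.PathLike) -> Trace:
    """Read a time_s,value CSV back into a Trace.

    The sample rate is recovered from the median time step; non-uniform
    sampling (>1% step jitter) is rejected.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"trace file {path!r} is empty") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse trace file {path!r}: {exc}") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(
                f"trace file {path!r} lacks required column {col!r} (line 1)"
            )
    if len(df) == 0:
        raise ValueError(f"trace file {path!r} has a header but no samples")
    for col in ("time_s", "value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[df["value"].isna() | df["time_s"].isna()]
    if len(bad):
        raise ValueError(
            f"trace file {path!r}: unparseable number at line {bad.index[0] + 2}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) == 1:
        raise ValueError(
            f"trace file {path!r} has a single sample; sample rate is undefined"
        )
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > 0.01 * dt):
        raise ValueError(f"trace file {path!r} is not uniformly sampled")
    return Trace(df["value"].to_numpy(dtype=float), 1.0 / dt, t0=float(t[0]))
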
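"""Peak events, windowed heart rate, and interbeat intervals.

Heart rate over a segment is the peak-count estimator

    HR [BPM] = 60 * p * F_r / n

with ``p`` detected peaks, ``n`` frames, and ``F_r`` the frame rate.  The
HR series averages over consecutive non-overlapping windows (default 10 s).
Interbeat intervals are the successive peak-time differences; intervals
deviating more than 25% from the mean raw interval are discarded as
noise-corrupted before any distributional comparison.  Segments qualify for
validation only when tracking ran loss-free for at least 100 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Trace

__all__ = [
    "PulseEstimate",
    "detect_peaks",
    "heart_rate",
    "hr_windows",
    "interpeak_intervals",
    "qualify_segments",
]


@dataclass
class PulseEstimate:
    """Beat events and derived heart-rate quantities for one trace."""

    peak_indices: np.ndarray  # frame indices of detected beats
    hr_series: pd.DataFrame  # columns: window_start_s, hr_bpm (NaN if no peaks)
    intervals: np.ndarray  # filtered interbeat intervals, seconds
    window_s: float
    raw_intervals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        d = np.diff(self.peak_indices)
        if len(d) and np.any(d <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if len(self.intervals) and np.any(self.intervals <= 0):
            raise ValueError("interbeat intervals must be positive")

    @property
    def mean_hr(self) -> float:
        """Mean of the windowed HR values (NaN windows excluded)."""
        return float(self.hr_series["hr_bpm"].mean())


def detect_peaks(
    trace: Trace,
    min_bpm: float = 90.0,
    max_bpm: float = 250.0,
    prominence_factor: float = 0.3,
) -> np.ndarray:
    """Locate beat peaks in the cardiac IMF.

    Local maxima separated by at least ``60/max_bpm`` seconds with
    prominence >= ``prominence_factor`` times the trace standard deviation.
    ``min_bpm`` bounds the plausible rate but imposes no hard constraint on
    individual gaps (a missed beat must stay visible to the interval
    filter).
    """
    if len(trace) == 0:
        raise ValueError("cannot detect peaks in an empty trace")
    if not min_bpm < max_bpm:
        raise ValueError(f"need min_bpm < max_bpm, got ({min_bpm}, {max_bpm})")
    sd = float(np.std(trace.values))
    if sd == 0:
        return np.empty(0, dtype=int)
    distance = max(1, int(round(trace.sample_rate * 60.0 / max_bpm)))
    peaks, _ = sps.find_peaks(
        trace.values, distance=distance, prominence=prominence_factor * sd
    )
    return peaks


def heart_rate(p_peaks: int, n_frames: int, frame_rate: float) -> float:
    """Peak-count heart rate in BPM: 60 * p * F_r / n."""
    if n_frames <= 0:
        raise ValueError(f"n_frames must be positive, got {n_frames}")
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be positive, got {frame_rate}")
    if p_peaks < 0:
        raise ValueError(f"p_peaks must be non-negative, got {p_peaks}")
    return 60.0 * p_peaks * frame_rate / n_frames


def hr_windows(
    trace: Trace,
    window_s: float = 10.0,
    min_bpm: float = 90.0,
    max_bpm: float = 250.0,
) -> pd.DataFrame:
    """Average heart rate over consecutive non-overlapping windows.

    Each window's BPM comes from peak detection plus the peak-count formula
    applied to that window alone.  Windows without any detected peak report
    NaN (missing), not zero.  Returns a DataFrame with columns
    ``window_start_s`` and ``hr_bpm``.
    """
    win = int(round(window_s * trace.sample_rate))
    if win <= 0:
        raise ValueError("window too short for the sample rate")
    if len(trace) < win:
        raise ValueError(
            f"trace of {trace.duration_s:.1f} s shorter than one {window_s} s window"
        )
    starts, hrs = [], []
    for s in range(0, len(trace) - win + 1, win):
        sub = trace.slice(s, s + win)
        p = len(detect_peaks(sub, min_bpm, max_bpm))
        starts.append(trace.t0 + s / trace.sample_rate)
        hrs.append(heart_rate(p, win, trace.sample_rate) if p > 0 else np.nan)
    return pd.DataFrame({"window_start_s": starts, "hr_bpm": hrs})


def interpeak_intervals(
    peak_indices: np.ndarray,
    frame_rate: float,
    filter_frac: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Interbeat intervals with the +/-25% plausibility filter.

    Raw intervals are successive peak-index differences divided by the
    frame rate.  Intervals outside ``[(1-filter_frac)*mu, (1+filter_frac)*mu]``,
    where ``mu`` is the mean of the *raw* intervals (computed once, not
    iterated), are discarded — these arise from missed or spurious peaks.

    Returns (kept_intervals, raw_intervals).
    """
    peak_indices = np.asarray(peak_indices)
    if len(peak_indices) < 3:
        raise ValueError(f"need at least 3 peaks for intervals, got {len(peak_indices)}")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    raw = np.diff(peak_indices) / frame_rate
    mu = float(np.mean(raw))
    kept = raw[(raw >= (1.0 - filter_frac) * mu) & (raw <= (1.0 + filter_frac) * mu)]
    if len(kept) == 0:
        warnings.warn("all interbeat intervals fall outside the plausibility band")
    return kept, raw


def qualify_segments(
    loss_flags: np.ndarray,
    frame_rate: float,
    min_len_s: float = 100.0,
) -> list[tuple[int, int]]:
    """Maximal loss-free frame runs of duration >= ``min_len_s``.

    ``loss_flags`` is one boolean per frame (True = target lost).  Returns
    half-open (start, end) frame ranges; an empty list means no segment of
    the video qualifies for analysis.
    """
    loss_flags = np.asarray(loss_flags, dtype=bool)
    min_frames = int(np.ceil(min_len_s * frame_rate))
    segments: list[tuple[int, int]] = []
    start = None
    for i, lost in enumerate(loss_flags):
        if not lost and start is None:
            start = i
        elif lost and start is not None:
            if i - start >= min_frames:
                segments.append((start, i))
            start = None
    if start is not None and len(loss_flags) - start >= min_frames:
        segments.append((start, len(loss_flags)))
    return segments
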
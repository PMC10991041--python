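"""Comparison statistics between the video estimate and a reference trace.

Three session-level quality metrics:

* mean error % — ``100 * |mean(videoHR) - mean(refHR)| / mean(refHR)`` on the
  paired windowed HR series (session means, not per-window errors);
* Pearson correlation between the paired windowed HR series;
* two-sample Kolmogorov-Smirnov test between the interbeat-interval
  distributions (after the +/-25% plausibility filter), which probes whether
  the video signal captures the same beat-to-beat variability as the
  reference sensor.

A comparison requires at least ten overlapping HR windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Trace
from .pulse import PulseEstimate, detect_peaks, hr_windows, interpeak_intervals

__all__ = [
    "ComparisonReport",
    "mean_error_pct",
    "pearson_corr",
    "ks_two_sample",
    "compare",
]

MIN_OVERLAP_WINDOWS = 10


@dataclass
class ComparisonReport:
    mean_error_pct: float
    pearson_r: float
    ks_statistic: float
    ks_p: float
    ref_hr_mean: float
    video_hr_mean: float
    n_windows: int

    def __post_init__(self) -> None:
        # NaN marks an undefined correlation (constant series), kept rather
        # than raised so a report can still carry the other metrics
        if not np.isnan(self.pearson_r) and not (-1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValueError("Pearson r outside [-1, 1]")
        if not (0.0 <= self.ks_statistic <= 1.0):
            raise ValueError("KS statistic outside [0, 1]")
        if self.mean_error_pct < 0:
            raise ValueError("mean error % is defined as non-negative")

    def to_dict(self) -> dict:
        return {
            "mean_error_pct": self.mean_error_pct,
            "pearson_r": self.pearson_r,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
            "ref_hr_mean": self.ref_hr_mean,
            "video_hr_mean": self.video_hr_mean,
            "n_windows": self.n_windows,
        }

    def summary(self) -> str:
        return (
            f"windows paired      : {self.n_windows}\n"
            f"video HR mean [BPM] : {self.video_hr_mean:.1f}\n"
            f"ref HR mean [BPM]   : {self.ref_hr_mean:.1f}\n"
            f"mean error [%]      : {self.mean_error_pct:.2f}\n"
            f"Pearson r           : {self.pearson_r:.2f}\n"
            f"KS D (p)            : {self.ks_statistic:.3f} ({self.ks_p:.2f})"
        )


def mean_error_pct(video_hr: np.ndarray, ref_hr: np.ndarray) -> float:
    """Session-mean error %: 100 * |mean(video) - mean(ref)| / mean(ref)."""
    video_hr = np.asarray(video_hr, dtype=float)
    ref_hr = np.asarray(ref_hr, dtype=float)
    if video_hr.shape != ref_hr.shape:
        raise ValueError(
            f"paired series must match in length: {video_hr.shape} vs {ref_hr.shape}"
        )
    if video_hr.size == 0:
        raise ValueError("need at least one paired window")
    ref_mean = float(np.nanmean(ref_hr))
    if ref_mean == 0:
        raise ValueError("reference mean HR is zero")
    return 100.0 * abs(float(np.nanmean(video_hr)) - ref_mean) / ref_mean


def pearson_corr(video_hr: np.ndarray, ref_hr: np.ndarray) -> float:
    """Sample Pearson correlation between paired windowed HR series."""
    video_hr = np.asarray(video_hr, dtype=float)
    ref_hr = np.asarray(ref_hr, dtype=float)
    if video_hr.shape != ref_hr.shape:
        raise ValueError("paired series must match in length")
    if video_hr.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(video_hr) == 0 or np.std(ref_hr) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(video_hr, ref_hr).statistic)


def ks_two_sample(intervals_a: np.ndarray, intervals_b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|.

    The p-value is exact at small sample sizes and switches to the
    asymptotic Kolmogorov distribution (effective sample size
    ``n_a n_b / (n_a + n_b)``) at the interval counts a 100+ s segment
    produces, where the two agree to well under a percent.
    """
    a = np.asarray(intervals_a, dtype=float)
    b = np.asarray(intervals_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(min(1.0, res.pvalue))


def _reference_hr_series(
    reference: Trace | pd.DataFrame, window_s: float
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Windowed HR series (and filtered intervals if derivable) of the reference.

    Accepts a raw pulse waveform (peaks detected the same way as the video
    signal) or a pre-computed (window_start_s, hr_bpm) table.
    """
    if isinstance(reference, Trace):
        hr = hr_windows(reference, window_s=window_s)
        peaks = detect_peaks(reference)
        intervals = None
        if len(peaks) >= 3:
            intervals, _ = interpeak_intervals(peaks, reference.sample_rate)
        return hr, intervals
    df = reference
    required = {"window_start_s", "hr_bpm"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference HR table must have columns {sorted(required)}")
    return df[["window_start_s", "hr_bpm"]].copy(), None


def compare(
    estimate: PulseEstimate,
    reference: Trace | pd.DataFrame,
    window_s: float = 10.0,
    align_tol_s: float = 0.5,
) -> ComparisonReport:
    """Full comparison of a video pulse estimate against a reference.

    Windows are paired by start time (within ``align_tol_s``); at least ten
    overlapping windows are required, mirroring the session-inclusion rule.
    The KS comparison runs on the filtered interbeat intervals and is
    reported as (0, 1) degenerate-identical when the reference provides no
    raw waveform to derive intervals from.
    """
    ref_hr, ref_intervals = _reference_hr_series(reference, window_s)
    vid = estimate.hr_series.dropna(subset=["hr_bpm"])
    ref = ref_hr.dropna(subset=["hr_bpm"])
    # pair windows on start time
    pairs = []
    ref_starts = ref["window_start_s"].to_numpy()
    for _, row in vid.iterrows():
        d = np.abs(ref_starts - row["window_start_s"])
        j = int(np.argmin(d))
        if d[j] <= align_tol_s:
            pairs.append((row["hr_bpm"], ref["hr_bpm"].iloc[j]))
    if len(pairs) < MIN_OVERLAP_WINDOWS:
        raise ValueError(
            f"insufficient overlap: {len(pairs)} paired windows < {MIN_OVERLAP_WINDOWS}"
        )
    v = np.array([p[0] for p in pairs])
    r = np.array([p[1] for p in pairs])
    if ref_intervals is not None and len(estimate.intervals) and len(ref_intervals):
        D, p = ks_two_sample(estimate.intervals, ref_intervals)
    else:
        D, p = 0.0, 1.0
    try:
        r_pearson = pearson_corr(v, r)
    except ValueError:
        r_pearson = float("nan")  # constant series: correlation undefined
    return ComparisonReport(
        mean_error_pct=mean_error_pct(v, r),
        pearson_r=r_pearson,
        ks_statistic=D,
        ks_p=p,
        ref_hr_mean=float(np.mean(r)),
        video_hr_mean=float(np.mean(v)),
        n_windows=len(pairs),
    )
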
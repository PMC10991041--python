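"""Model/Results interface over the full video-to-pulse pipeline.

`CardiacVideoModel` holds a frame sequence, an initial ROI and the pipeline
configuration; `fit()` executes

    (track) -> luma ROI mean -> cardiac band-pass -> CEEMDAN -> IMF
    selection -> peak detection -> windowed HR -> interbeat intervals

and returns a `CardiacPulseResults` carrying every intermediate product,
diagnostics, a `summary()` table, `compare()` against a reference trace,
CSV export and plotting.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .colorspace import roi_mean_intensity
from .decomposition import (
    CARDIAC_BAND,
    RESPIRATORY_BAND,
    BandSpec,
    IMFSet,
    NoCardiacComponentError,
    bandpass,
    ceemdan,
    dominant_frequency,
    hz_to_bpm,
    select_cardiac_imf,
)
from .io import BoundingBox, FrameSequence, Trace, read_video
from .pulse import (
    PulseEstimate,
    detect_peaks,
    hr_windows,
    interpeak_intervals,
    qualify_segments,
)
from .tracking import TrackResult, track
from .validation import ComparisonReport, compare

__all__ = ["PipelineConfig", "CardiacVideoModel", "CardiacPulseResults"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its method-faithful default."""

    track: bool = True
    eta: float = 0.125  # MOSSE learning rate
    psr_threshold: float = 5.0  # peak-to-sidelobe ratio below which target is lost
    target_sigma: float = 2.0
    n_augmentations: int = 8
    cardiac_band: BandSpec = field(default_factory=lambda: CARDIAC_BAND)
    respiratory_band: BandSpec = field(default_factory=lambda: RESPIRATORY_BAND)
    ceemdan_noise_std: float = 0.2
    ceemdan_ensemble_size: int = 100
    ceemdan_max_imfs: int = 9
    window_s: float = 10.0  # HR averaging window
    filter_frac: float = 0.25  # interbeat-interval plausibility band
    min_segment_s: float = 100.0  # loss-free duration a segment must reach
    min_bpm: float = 90.0
    max_bpm: float = 250.0
    color_matrix: str = "paper"
    seed: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cardiac_band"] = [self.cardiac_band.low_hz, self.cardiac_band.high_hz, self.cardiac_band.order]
        d["respiratory_band"] = [
            self.respiratory_band.low_hz,
            self.respiratory_band.high_hz,
            self.respiratory_band.order,
        ]
        return d


class CardiacVideoModel:
    """Contact-free cardiac-signal model for one video recording.

    Parameters
    ----------
    frames : the recording as a FrameSequence.
    roi : initial facial bounding box (tracked from frame 0 when
        ``config.track`` is on, fixed otherwise).
    config : pipeline configuration; defaults reproduce the published
        processing chain.
    """

    def __init__(
        self,
        frames: FrameSequence,
        roi: BoundingBox,
        config: PipelineConfig | None = None,
    ) -> None:
        if not frames.contains(roi):
            raise ValueError(f"ROI {roi} does not fit inside frames {frames.frame_shape}")
        self.frames = frames
        self.roi = roi
        self.config = config or PipelineConfig()

    @classmethod
    def from_video(
        cls,
        path: str | os.PathLike,
        roi: BoundingBox | tuple[int, int, int, int],
        frame_rate: float | None = None,
        config: PipelineConfig | None = None,
    ) -> "CardiacVideoModel":
        """Build the model straight from a video file or frame directory."""
        if not isinstance(roi, BoundingBox):
            roi = BoundingBox(*roi)
        return cls(read_video(path, frame_rate=frame_rate), roi, config)

    def fit(self, seed: int | None = None) -> "CardiacPulseResults":
        """Run the pipeline and return the fitted results.

        ``seed`` overrides ``config.seed`` for the run's stochastic stages
        (tracker augmentations, CEEMDAN noise ensemble).
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        fr = self.frames.frame_rate

        if cfg.track:
            track_result = track(
                self.frames,
                self.roi,
                eta=cfg.eta,
                target_sigma=cfg.target_sigma,
                n_augmentations=cfg.n_augmentations,
                psr_threshold=cfg.psr_threshold,
                seed=seed,
            )
            boxes = track_result.boxes
            loss_flags = track_result.loss_flags
        else:
            track_result = None
            boxes = self.roi
            loss_flags = np.zeros(len(self.frames), dtype=bool)

        raw = roi_mean_intensity(self.frames, boxes, cfg.color_matrix)
        segments = qualify_segments(loss_flags, fr, cfg.min_segment_s)
        if not segments:
            # tolerate short loss-free recordings of at least one HR window;
            # the strict 100 s rule applies whenever any loss occurred
            if not loss_flags.any() and raw.duration_s >= cfg.window_s:
                segments = [(0, len(raw))]
            else:
                return CardiacPulseResults(
                    model=self, seed=seed, raw_trace=raw, track_result=track_result,
                    segments=[], status="no-qualifying-segment",
                )

        start, end = max(segments, key=lambda s: s[1] - s[0])
        seg = raw.slice(start, end)
        cardiac_bp = bandpass(seg, cfg.cardiac_band)
        imf_set = ceemdan(
            cardiac_bp,
            noise_std=cfg.ceemdan_noise_std,
            ensemble_size=cfg.ceemdan_ensemble_size,
            seed=seed,
            max_imfs=cfg.ceemdan_max_imfs,
        )
        try:
            imf_index, cardiac = select_cardiac_imf(imf_set, cfg.cardiac_band)
        except NoCardiacComponentError:
            return CardiacPulseResults(
                model=self, seed=seed, raw_trace=raw, track_result=track_result,
                segments=segments, status="no-cardiac-component",
                bandpassed=cardiac_bp, imf_set=imf_set,
            )

        peaks = detect_peaks(cardiac, cfg.min_bpm, cfg.max_bpm)
        hr = hr_windows(cardiac, cfg.window_s, cfg.min_bpm, cfg.max_bpm)
        if len(peaks) >= 3:
            intervals, raw_intervals = interpeak_intervals(peaks, fr, cfg.filter_frac)
        else:
            intervals, raw_intervals = np.empty(0), np.empty(0)
        estimate = PulseEstimate(
            peak_indices=peaks,
            hr_series=hr,
            intervals=intervals,
            window_s=cfg.window_s,
            raw_intervals=raw_intervals,
        )
        return CardiacPulseResults(
            model=self, seed=seed, raw_trace=raw, track_result=track_result,
            segments=segments, status="ok", bandpassed=cardiac_bp,
            imf_set=imf_set, imf_index=imf_index, cardiac_trace=cardiac,
            estimate=estimate,
        )


@dataclass
class CardiacPulseResults:
    """Everything `CardiacVideoModel.fit()` produced."""

    model: CardiacVideoModel
    seed: int | None
    raw_trace: Trace
    track_result: TrackResult | None
    segments: list[tuple[int, int]]
    status: str
    bandpassed: Trace | None = None
    imf_set: IMFSet | None = None
    imf_index: int | None = None
    cardiac_trace: Trace | None = None
    estimate: PulseEstimate | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def hr_series(self) -> pd.DataFrame:
        self._require_ok()
        return self.estimate.hr_series

    @property
    def mean_hr(self) -> float:
        self._require_ok()
        return self.estimate.mean_hr

    @property
    def dominant_hr(self) -> float:
        """Whole-segment HR from the dominant spectral frequency (BPM)."""
        self._require_ok()
        return hz_to_bpm(dominant_frequency(self.cardiac_trace))

    def _require_ok(self) -> None:
        if not self.ok:
            raise RuntimeError(f"pipeline did not complete: status={self.status!r}")

    def compare(self, reference: Trace | pd.DataFrame) -> ComparisonReport:
        """Validate against a reference pulse waveform or HR table."""
        self._require_ok()
        return compare(self.estimate, reference, self.model.config.window_s)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Contact-free cardiac signal estimate",
            "=" * 38,
            f"frames              : {len(self.model.frames)} @ {self.model.frames.frame_rate} fps",
            f"tracking            : {'on (eta=%g)' % cfg.eta if cfg.track else 'off'}",
            f"qualifying segments : {len(self.segments)}",
            f"status              : {self.status}",
        ]
        if self.ok:
            lost = int(self.track_result.loss_flags.sum()) if self.track_result else 0
            hr = self.estimate.hr_series["hr_bpm"]
            lines += [
                f"frames lost         : {lost}",
                f"cardiac IMF         : {self.imf_index}",
                f"beats detected      : {len(self.estimate.peak_indices)}",
                f"HR windows ({cfg.window_s:g} s)   : {len(hr)}",
                f"mean HR [BPM]       : {hr.mean():.1f}",
                f"HR range [BPM]      : {hr.min():.1f} - {hr.max():.1f}",
                f"dominant freq HR    : {self.dominant_hr:.1f}",
                f"intervals kept      : {len(self.estimate.intervals)}/{len(self.estimate.raw_intervals)}",
            ]
        return "\n".join(lines)

    def manifest(self) -> dict:
        return {
            "primpulse_version": __version__,
            "seed": self.seed,
            "config": self.model.config.to_dict(),
            "n_frames": len(self.model.frames),
            "frame_rate": self.model.frames.frame_rate,
            "roi": [self.model.roi.x, self.model.roi.y, self.model.roi.width, self.model.roi.height],
            "status": self.status,
            "segments": self.segments,
        }

    def to_csv(self, directory: str | os.PathLike) -> None:
        """Write HR series, intervals, per-frame boxes and the run manifest."""
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        if self.ok:
            self.estimate.hr_series.to_csv(os.path.join(directory, "hr.csv"), index=False)
            pd.DataFrame({"interval_s": self.estimate.intervals}).to_csv(
                os.path.join(directory, "intervals.csv"), index=False
            )
        if self.track_result is not None:
            rows = [
                (i, b.x, b.y, b.width, b.height, self.track_result.psr[i], bool(self.track_result.loss_flags[i]))
                for i, b in enumerate(self.track_result.boxes)
            ]
            pd.DataFrame(rows, columns=["frame", "x", "y", "w", "h", "psr", "lost"]).to_csv(
                os.path.join(directory, "boxes.csv"), index=False
            )
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(self.manifest(), fh, indent=2, default=str)

    def plot(self, ax=None):
        """Raw trace, cardiac IMF with beat marks, and the windowed HR."""
        import matplotlib.pyplot as plt

        self._require_ok()
        if ax is None:
            _, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
        else:
            axes = ax
        axes[0].plot(self.raw_trace.times, self.raw_trace.values, lw=0.6)
        axes[0].set_ylabel("ROI mean Y")
        axes[1].plot(self.cardiac_trace.times, self.cardiac_trace.values, lw=0.6)
        pk = self.estimate.peak_indices
        axes[1].plot(self.cardiac_trace.times[pk], self.cardiac_trace.values[pk], "r.", ms=4)
        axes[1].set_ylabel("cardiac IMF")
        hr = self.estimate.hr_series
        axes[2].step(hr["window_start_s"], hr["hr_bpm"], where="post")
        axes[2].set_ylabel("HR [BPM]")
        axes[2].set_xlabel("time [s]")
        return axes
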
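"""Model/Results surface orchestrating the full pressor-response analysis.

:class:`PressorResponseModel` is built from a recording plus its drug-event
annotations; :meth:`~PressorResponseModel.fit` runs beat detection, bolus
segmentation, midpoint detection, normalization and the windowed comparison,
and returns a :class:`PressorResponseResults` carrying per-bolus deltas,
their group mean +/- SD, paired-t and Shapiro-Wilk statistics, response
classification counts, and plotting/export helpers.

>>> model = PressorResponseModel.from_files("recording.csv", "events.csv")
>>> results = model.fit()
>>> print(results.summary())
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .beats import (
    BeatDetectionOptions,
    BeatHemodynamics,
    PerfusionSeries,
    beat_pressures,
    detect_beats,
    perfusion_pressures,
)
from .midpoint import MidpointResult, NormalizedSegment, SmoothingConfig, find_midpoint, normalize
from .segmentation import BolusSegment, segment_boluses
from .stats import (
    ComparisonConfig,
    ComparisonResult,
    classify_responses,
    compare_segments,
    delta_histogram,
    summarize_band,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PressorResponseModel", "PressorResponseResults", "run_analysis"]


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible run depends on."""

    channel_map: dict[str, str] = dataclasses.field(default_factory=dict)
    detection: BeatDetectionOptions = dataclasses.field(default_factory=BeatDetectionOptions)
    smoothing: SmoothingConfig = dataclasses.field(default_factory=SmoothingConfig)
    comparison: ComparisonConfig = dataclasses.field(default_factory=ComparisonConfig)
    min_context_s: float = 40.0
    grid_step_s: float = 1.0
    histogram_bin_mmHg: float = 2.0
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparison"]["before_window"] = list(self.comparison.before_window)
        d["comparison"]["after_window"] = list(self.comparison.after_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "detection" in d:
            d["detection"] = BeatDetectionOptions(**d["detection"])
        if "smoothing" in d:
            d["smoothing"] = SmoothingConfig(**d["smoothing"])
        if "comparison" in d:
            c = dict(d["comparison"])
            c["before_window"] = tuple(c["before_window"])
            c["after_window"] = tuple(c["after_window"])
            d["comparison"] = ComparisonConfig(**c)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


class PressorResponseModel:
    """Beat-by-beat calcium pressor-response analysis of one recording."""

    def __init__(
        self,
        recording: wio.Recording,
        events: list[wio.DrugEvent],
        config: RunConfig | None = None,
    ) -> None:
        self.recording = recording
        self.events = sorted(events, key=lambda e: e.time_s)
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        recording_path: str | Path,
        events_path: str | Path,
        config: RunConfig | None = None,
    ) -> "PressorResponseModel":
        config = config or RunConfig()
        recording = wio.read_recording(recording_path, channel_map=config.channel_map or None)
        events = wio.read_events(events_path)
        return cls(recording, events, config)

    def fit(self) -> "PressorResponseResults":
        cfg = self.config
        rec = self.recording
        aortic = rec.channels["aortic_pressure"]

        boundaries = detect_beats(aortic, rec.sampling_rate_hz, cfg.detection)
        beats = beat_pressures(aortic, boundaries, rec.sampling_rate_hz)
        beats = BeatHemodynamics(
            beats.beat_time_s + rec.start_time_s, beats.MAP, beats.AoS, beats.AoD
        ) if rec.start_time_s else beats
        perfusion = perfusion_pressures(
            beats,
            rec.channel("right_atrial_pressure"),
            rec.channel("intracranial_pressure"),
            boundaries,
            rec.sampling_rate_hz,
            aortic=aortic,
        )
        logger.info("fit: %d beats, perfusion=%s", len(beats), bool(len(perfusion)))

        segments = segment_boluses(self.events, beats, perfusion, rec.span, cfg.min_context_s)
        midpoints: list[MidpointResult] = []
        normalized: list[NormalizedSegment | None] = []
        for seg in segments:
            if not seg.usable:
                midpoints.append(MidpointResult(np.nan, {}, "none", {}, valid=False))
                normalized.append(None)
                continue
            mp = find_midpoint(seg, cfg.smoothing)
            midpoints.append(mp)
            normalized.append(normalize(seg, mp) if mp.valid else None)

        analyzed = [n for n in normalized if n is not None]
        comparison = compare_segments(analyzed, cfg.comparison) if analyzed else None

        # per-bolus MAP delta aligned with all segments (NaN where not analyzed)
        delta_map = np.full(len(segments), np.nan)
        if comparison is not None:
            j = 0
            for i, n in enumerate(normalized):
                if n is not None:
                    delta_map[i] = comparison.per_segment["delta_MAP"].iloc[j]
                    j += 1
        counts = classify_responses(delta_map, midpoints)

        return PressorResponseResults(
            model=self,
            beats=beats,
            perfusion=perfusion,
            segments=segments,
            midpoints=midpoints,
            normalized=normalized,
            comparison=comparison,
            delta_map=delta_map,
            counts=counts,
        )


@dataclasses.dataclass
class PressorResponseResults:
    """Fitted pressor-response analysis."""

    model: PressorResponseModel
    beats: BeatHemodynamics
    perfusion: PerfusionSeries
    segments: list[BolusSegment]
    midpoints: list[MidpointResult]
    normalized: list[NormalizedSegment | None]
    comparison: ComparisonResult | None
    delta_map: np.ndarray
    counts: dict[str, int]

    # -- accessors ---------------------------------------------------------

    @property
    def n_boluses(self) -> int:
        return len(self.segments)

    @property
    def n_usable(self) -> int:
        return sum(1 for s in self.segments if s.usable)

    @property
    def analyzed_segments(self) -> list[NormalizedSegment]:
        return [n for n in self.normalized if n is not None]

    def segment_manifest(self) -> pd.DataFrame:
        rows = []
        for seg, mp in zip(self.segments, self.midpoints):
            rows.append(
                {
                    "bolus_time_s": seg.bolus.time_s,
                    "dose": seg.bolus.dose,
                    "t_start_s": seg.t_start_s,
                    "t_end_s": seg.t_end_s,
                    "usable": seg.usable,
                    "n_beats": len(seg.beats),
                    "midpoint_valid": mp.valid,
                    "midpoint_time_s": mp.midpoint_time_s,
                    "consensus_rule": mp.consensus_rule_used,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "bolus_time_s", "dose", "t_start_s", "t_end_s", "usable",
                "n_beats", "midpoint_valid", "midpoint_time_s", "consensus_rule",
            ],
        )

    def normalized_tables(self) -> list[pd.DataFrame]:
        return [n.to_frame() for n in self.analyzed_segments]

    def band(self, grid_step_s: float | None = None) -> pd.DataFrame | None:
        if not self.analyzed_segments:
            return None
        step = grid_step_s if grid_step_s is not None else self.model.config.grid_step_s
        return summarize_band(self.analyzed_segments, grid_step_s=step)

    def delta_histogram(self, bin_width: float | None = None):
        d = self.delta_map[np.isfinite(self.delta_map)]
        if len(d) == 0:
            return None
        w = bin_width if bin_width is not None else self.model.config.histogram_bin_mmHg
        return delta_histogram(d, bin_width=w)

    # -- reporting ---------------------------------------------------------

    def summary_dict(self) -> dict:
        out: dict = {
            "n_boluses": self.n_boluses,
            "n_usable": self.n_usable,
            "n_analyzed": len(self.analyzed_segments),
            "counts": dict(self.counts),
            "classification_rule": (
                "no_effect = no detectable sigmoid midpoint; responder/negative_delta "
                "split detectable responses by the sign of delta MAP"
            ),
        }
        for p in ("MAP", "AoS", "AoD"):
            key = p.lower()
            out[f"delta_{key}"] = None
            out[f"delta_{key}_sd"] = None
            out[f"t_{key}"] = None
            out[f"df_{key}"] = None
            out[f"p_{key}"] = None
            out[f"shapiro_w_{key}"] = None
            out[f"shapiro_p_{key}"] = None
            if self.comparison is None:
                continue
            out[f"delta_{key}"] = _json_float(self.comparison.delta_mean[p])
            out[f"delta_{key}_sd"] = _json_float(self.comparison.delta_sd[p])
            if p in self.comparison.t_tests:
                tt = self.comparison.t_tests[p]
                out[f"t_{key}"] = _json_float(tt.t)
                out[f"df_{key}"] = tt.df
                out[f"p_{key}"] = _json_float(tt.p)
            if p in self.comparison.shapiro:
                w, sp = self.comparison.shapiro[p]
                out[f"shapiro_w_{key}"] = w
                out[f"shapiro_p_{key}"] = sp
        return out

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Calcium pressor-response analysis",
            "=" * 49,
            f"boluses: {self.n_boluses}   usable: {self.n_usable}   analyzed: {len(self.analyzed_segments)}",
            f"classification: {self.counts['responder']} responder, "
            f"{self.counts['negative_delta']} negative-delta, {self.counts['no_effect']} no-effect",
        ]
        if self.comparison is not None:
            lines.append("-" * 49)
            lines.append(f"{'pressure':>8} {'delta (mmHg)':>14} {'t':>8} {'p':>10}")
            for p in ("MAP", "AoS", "AoD"):
                mean = self.comparison.delta_mean[p]
                sd = self.comparison.delta_sd[p]
                tt = self.comparison.t_tests.get(p)
                sd_s = f"+/- {sd:4.1f}" if np.isfinite(sd) else " " * 8
                t_s = f"{tt.t:8.3f}" if tt else " " * 8
                p_s = f"{tt.p:10.4g}" if tt else " " * 10
                lines.append(f"{p:>8} {mean:7.1f} {sd_s} {t_s} {p_s}")
        lines.append("=" * 49)
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_band(self, band: pd.DataFrame | None = None):
        """Mean +/- SD band of normalized pressures (three stacked axes)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        band = band if band is not None else self.band()
        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(7, 8))
        for ax, p in zip(axes, ("MAP", "AoS", "AoD")):
            m, s = band[f"{p}_mean"], band[f"{p}_sd"]
            ax.plot(band["t"], m, color="tab:blue", label=f"mean {p}")
            ax.fill_between(band["t"], m - s, m + s, color="gray", alpha=0.4, label="+/- SD")
            ax.axvline(0.0, color="k", lw=0.5)
            ax.set_ylabel(f"{p} (mmHg)")
            ax.legend(loc="upper left", fontsize=8)
        axes[-1].set_xlabel("normalized time (s)")
        fig.tight_layout()
        return fig

    def plot_histogram(self, bin_width: float | None = None):
        """Histogram of per-bolus MAP deltas."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        counts, edges = self.delta_histogram(bin_width)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="k")
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel("delta MAP, after - before (mmHg)")
        ax.set_ylabel("boluses")
        fig.tight_layout()
        return fig

    def save(self, out_dir: str | Path) -> list[Path]:
        paths = wio.write_outputs(self, out_dir)
        paths.append(self.model.config.to_yaml(Path(out_dir) / "config.yaml"))
        return paths


def _json_float(x: float) -> float | None:
    """NaN is not valid JSON; report unavailable statistics as null."""
    return None if x is None or not np.isfinite(x) else float(x)


def run_analysis(
    config: RunConfig,
    recording_path: str | Path,
    events_path: str | Path,
    out_dir: str | Path | None = None,
) -> PressorResponseResults:
    """File-to-file pipeline: read, fit, and (optionally) write artifacts,
    including a copy of the config for byte-identical re-runs."""
    logging.getLogger("capressor").setLevel(config.log_level.upper())
    model = PressorResponseModel.from_files(recording_path, events_path, config)
    results = model.fit()
    if out_dir is not None:
        results.save(out_dir)
    return results
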
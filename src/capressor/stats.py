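"""Windowed before/after comparison of normalized segments and summaries.

The comparison averages each normalized pressure over a 4 s window before
(-40 < t < -36 s) and after (36 < t < 40 s) the midpoint, forms per-segment
deltas (after minus before), and tests them with a two-sided paired t test;
normality of the deltas is checked with the Shapiro-Wilk test.  No
multiple-testing correction is applied across the three pressures, and
repeated boluses within an animal are treated as independent — the analysis
mirrors the study design it re-implements rather than improving on it.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .midpoint import MidpointResult, NormalizedSegment

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonConfig",
    "ComparisonResult",
    "PairedTResult",
    "window_mean",
    "paired_t_test",
    "shapiro_wilk",
    "compare_segments",
    "classify_responses",
    "summarize_band",
    "delta_histogram",
]

PRESSURES = ("MAP", "AoS", "AoD")


@dataclasses.dataclass(frozen=True)
class ComparisonConfig:
    """Open-interval comparison windows on normalized time (seconds)."""

    before_window: tuple[float, float] = (-40.0, -36.0)
    after_window: tuple[float, float] = (36.0, 40.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("before_window", self.before_window), ("after_window", self.after_window)):
            if not lo < hi:
                raise ValueError(f"{name}: need t_lo < t_hi, got ({lo}, {hi})")
        if self.before_window[1] > 0:
            raise ValueError("before_window must lie entirely at negative t")
        if self.after_window[0] < 0:
            raise ValueError("after_window must lie entirely at positive t")


@dataclasses.dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def window_mean(segment: NormalizedSegment, window: tuple[float, float]) -> dict[str, float]:
    """Arithmetic mean of beat values with t strictly inside ``window``.

    An empty window returns NaN per pressure (the segment is then excluded
    from the paired test) with a logged warning.
    """
    lo, hi = window
    mask = (segment.t > lo) & (segment.t < hi)
    if not np.any(mask):
        logger.warning("no beats inside window (%g, %g); segment excluded", lo, hi)
        return {p: float("nan") for p in PRESSURES}
    return {
        "MAP": float(np.mean(segment.MAP_n[mask])),
        "AoS": float(np.mean(segment.AoS_n[mask])),
        "AoD": float(np.mean(segment.AoD_n[mask])),
    }


def paired_t_test(before: np.ndarray, after: np.ndarray) -> PairedTResult:
    """Two-sided paired t test on ``after - before`` with df = n - 1.

    Zero-variance differences are flagged degenerate: t = 0, p = 1 when all
    differences are zero, |t| = inf otherwise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before and after must have equal length")
    n = len(before)
    if n < 2:
        raise ValueError(f"paired t test needs n >= 2, got {n}")
    if not (np.all(np.isfinite(before)) and np.all(np.isfinite(after))):
        raise ValueError("paired t test requires finite values")
    d = after - before
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return PairedTResult(0.0, n - 1, 1.0, degenerate=True)
        return PairedTResult(float(np.sign(d[0]) * np.inf), n - 1, 0.0, degenerate=True)
    res = sstats.ttest_rel(after, before)
    return PairedTResult(float(res.statistic), int(res.df), float(res.pvalue), degenerate=False)


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 finite, non-constant values."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or len(x) > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("Shapiro-Wilk requires finite values")
    if np.ptp(x) == 0.0:
        raise ValueError("Shapiro-Wilk is degenerate on a constant sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = sstats.shapiro(x)
    return float(w), float(p)


@dataclasses.dataclass
class ComparisonResult:
    """Group-level before/after comparison across usable segments."""

    per_segment: pd.DataFrame  # columns: before_/after_/delta_ per pressure
    n: int
    delta_mean: dict[str, float]
    delta_sd: dict[str, float]
    t_tests: dict[str, PairedTResult]
    shapiro: dict[str, tuple[float, float]]


def compare_segments(
    segments: list[NormalizedSegment],
    config: ComparisonConfig | None = None,
) -> ComparisonResult:
    """Windowed means, deltas, paired t and Shapiro-Wilk per pressure.

    Segments with an empty before or after window are dropped from the
    group statistics (with a warning) but still appear in ``per_segment``
    with NaN entries.
    """
    config = config or ComparisonConfig()
    rows = []
    for seg in segments:
        b = window_mean(seg, config.before_window)
        a = window_mean(seg, config.after_window)
        row = {}
        for p in PRESSURES:
            row[f"before_{p}"] = b[p]
            row[f"after_{p}"] = a[p]
            row[f"delta_{p}"] = a[p] - b[p]
        rows.append(row)
    per_segment = pd.DataFrame(rows, columns=[f"{w}_{p}" for p in PRESSURES for w in ("before", "after", "delta")])

    complete = per_segment.dropna() if len(per_segment) else per_segment
    n = len(complete)
    delta_mean, delta_sd, t_tests, shapiro = {}, {}, {}, {}
    for p in PRESSURES:
        if n == 0:
            delta_mean[p] = float("nan")
            delta_sd[p] = float("nan")
            continue
        d = complete[f"delta_{p}"].to_numpy()
        delta_mean[p] = float(np.mean(d))
        delta_sd[p] = float(np.std(d, ddof=1)) if n > 1 else float("nan")
        if n >= 2:
            t_tests[p] = paired_t_test(
                complete[f"before_{p}"].to_numpy(), complete[f"after_{p}"].to_numpy()
            )
        if 3 <= n <= 5000 and np.ptp(d) > 0:
            shapiro[p] = shapiro_wilk(d)
    return ComparisonResult(per_segment, n, delta_mean, delta_sd, t_tests, shapiro)


def classify_responses(
    delta_map: np.ndarray,
    midpoints: list[MidpointResult],
) -> dict[str, int]:
    """Classify boluses into responder / negative_delta / no_effect.

    ``no_effect``: no detectable sigmoid (invalid midpoint), or no
    analyzable delta.  Among valid midpoints with a finite MAP delta,
    ``responder`` is positive and ``negative_delta`` non-positive.  Counts
    always sum to the number of boluses.
    """
    delta_map = np.asarray(delta_map, dtype=float)
    if len(delta_map) != len(midpoints):
        raise ValueError("delta_map and midpoints must be aligned")
    counts = {"responder": 0, "negative_delta": 0, "no_effect": 0}
    for d, mp in zip(delta_map, midpoints):
        if not mp.valid or not np.isfinite(d):
            counts["no_effect"] += 1
        elif d > 0:
            counts["responder"] += 1
        else:
            counts["negative_delta"] += 1
    return counts


def summarize_band(
    segments: list[NormalizedSegment],
    grid_step_s: float = 1.0,
    span: tuple[float, float] = (-40.0, 40.0),
) -> pd.DataFrame:
    """Across-segment mean +/- SD curves on a common normalized-time grid.

    Each segment is linearly interpolated onto the grid over the part of the
    span it covers; a (0, 0) knot — the definition of the normalized frame —
    is included, so mean and SD at t = 0 are exactly 0.  SD is the sample
    (ddof=1) standard deviation across segments covering the grid point, 0
    where only one segment contributes.
    """
    if not segments:
        raise ValueError("summarize_band needs at least one segment")
    if grid_step_s <= 0:
        raise ValueError("grid_step_s must be > 0")
    lo, hi = span
    grid = np.arange(lo, hi + 0.5 * grid_step_s, grid_step_s)
    out = {"t": grid}
    for p, attr in (("MAP", "MAP_n"), ("AoS", "AoS_n"), ("AoD", "AoD_n")):
        values = np.full((len(segments), len(grid)), np.nan)
        for i, seg in enumerate(segments):
            t = seg.t
            y = getattr(seg, attr)
            if 0.0 not in t:
                order = np.searchsorted(t, 0.0)
                t = np.insert(t, order, 0.0)
                y = np.insert(y, order, 0.0)
            cover = (grid >= t[0]) & (grid <= t[-1])
            values[i, cover] = np.interp(grid[cover], t, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean = np.nanmean(values, axis=0)
            n_cov = np.sum(np.isfinite(values), axis=0)
            sd = np.nanstd(values, axis=0, ddof=1)
        sd[n_cov <= 1] = 0.0
        mean[n_cov == 0] = np.nan
        sd[n_cov == 0] = np.nan
        out[f"{p}_mean"] = mean
        out[f"{p}_sd"] = sd
        out[f"{p}_n"] = n_cov
    return pd.DataFrame(out)


def delta_histogram(deltas: np.ndarray, bin_width: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-bolus deltas with bin edges aligned to multiples of
    ``bin_width`` (zero is always on an edge when spanned)."""
    d = np.asarray(deltas, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise ValueError("delta_histogram needs at least one finite delta")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    return counts, edges
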
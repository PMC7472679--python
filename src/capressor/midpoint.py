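"""Sigmoid-midpoint detection and normalization of bolus responses.

The pressor response to a calcium bolus is approximately sigmoid in time.
Its midpoint (the inflection) is located as the zero-crossing of the second
derivative of smoothed beat-level pressure series — systolic aortic pressure
always, coronary and cerebral perfusion pressure when reference channels are
available — and the consensus midpoint is the median of the per-signal
crossings.  The segment is then re-expressed in a normalized frame: time
minus the midpoint time, each pressure minus its value at the beat nearest
the midpoint, so the anchor beat sits exactly at (t = 0, pressure = 0).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import signal as _sps

from .segmentation import BolusSegment

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothingConfig",
    "MidpointResult",
    "NormalizedSegment",
    "moving_average",
    "second_derivative",
    "find_midpoint",
    "normalize",
]

#: second-derivative swing (mmHg/s^2) a zero-crossing must exceed on both
#: sides to count as a curvature change rather than numerical chatter
DEFAULT_EPSILON = 0.01
MIN_BEATS_AFTER_BOLUS = 10


@dataclasses.dataclass(frozen=True)
class SmoothingConfig:
    """Smoothing configuration for display and midpoint detection.

    ``window_samples`` is the centered windowed average used for display
    series and exported tables.  ``detection_window_beats`` sets the time
    scale of the pre-differentiation smoothing: detection low-passes the
    beat series (resampled to a uniform ``resample_dt_s`` grid) with a
    zero-phase Butterworth filter whose cutoff is one cycle per two
    detection windows — 0.05 Hz for the default 15 beats at 90 bpm.  A
    plain windowed average of that width leaves too much ventilation-
    artifact curvature to differentiate twice, so detection needs the
    sharper stop band; a zero-phase filter leaves the sigmoid's inflection
    time unmoved.
    """

    window_samples: int = 15
    detection_window_beats: int = 15
    derivative_scheme: str = "central_difference"
    epsilon: float = DEFAULT_EPSILON
    resample_dt_s: float = 0.5
    agreement_tol_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("window_samples", "detection_window_beats"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {w}")
        if self.derivative_scheme != "central_difference":
            raise ValueError(f"unsupported derivative scheme {self.derivative_scheme!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.resample_dt_s <= 0:
            raise ValueError("resample_dt_s must be > 0")


@dataclasses.dataclass
class MidpointResult:
    """Outcome of midpoint detection for one segment.

    ``valid=False`` means no signal showed a curvature change above
    threshold after the bolus — an annotated injection with no detectable
    sigmoid response.  Invalid results are values, not exceptions.
    """

    midpoint_time_s: float
    per_signal_crossings: dict[str, float]
    consensus_rule_used: str
    reference_pressures: dict[str, float]
    valid: bool


@dataclasses.dataclass
class NormalizedSegment:
    """A bolus segment in the normalized frame: t = 0 and pressure = 0 at
    the detected midpoint (anchor beat)."""

    t: np.ndarray
    MAP_n: np.ndarray
    AoS_n: np.ndarray
    AoD_n: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "MAP_n", "AoS_n", "AoD_n"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if any(len(getattr(self, f)) != n for f in ("MAP_n", "AoS_n", "AoD_n")):
            raise ValueError("NormalizedSegment fields must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def anchor_index(self) -> int:
        return int(np.argmin(np.abs(self.t)))

    def anchored_at_zero(self) -> "NormalizedSegment":
        """Re-anchor at t = 0; a no-op (identity) on an already-normalized
        segment, since the anchor beat is at (0, 0, 0, 0)."""
        i = self.anchor_index
        return NormalizedSegment(
            self.t - self.t[i] * 0.0,  # time is already midpoint-relative
            self.MAP_n - self.MAP_n[i],
            self.AoS_n - self.AoS_n[i],
            self.AoD_n - self.AoD_n[i],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_normalized_s": self.t, "MAP": self.MAP_n, "AoS": self.AoS_n, "AoD": self.AoD_n}
        )


def moving_average(series: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered windowed mean; edges shrink the window symmetrically so the
    output has the input's length and a linear ramp passes through
    unchanged in the interior."""
    x = np.asarray(series, dtype=float)
    w = int(window_samples)
    if w < 3 or w % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {w}")
    n = len(x)
    if w > n:
        raise ValueError(f"window ({w}) larger than series ({n})")
    half = w // 2
    # work on offsets from the first sample so a constant series comes back
    # bit-identical and the running sum stays well conditioned
    offset = x[0]
    csum = np.concatenate([[0.0], np.cumsum(x - offset)])
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    return offset + (csum[hi] - csum[lo]) / (hi - lo)


def second_derivative(series: np.ndarray, beat_times: np.ndarray) -> np.ndarray:
    """Central-difference second derivative on (possibly unevenly spaced)
    beat times; endpoints are NaN.  Exact for quadratics."""
    y = np.asarray(series, dtype=float)
    t = np.asarray(beat_times, dtype=float)
    if len(y) != len(t):
        raise ValueError("series and beat_times must have equal length")
    if len(y) < 5:
        raise ValueError(f"need at least 5 beats to differentiate twice, got {len(y)}")
    if not np.all(np.diff(t) > 0):
        raise ValueError("beat_times must be strictly increasing")
    out = np.full(len(y), np.nan)
    h1 = t[1:-1] - t[:-2]
    h2 = t[2:] - t[1:-1]
    out[1:-1] = 2.0 * (y[:-2] * h2 - y[1:-1] * (h1 + h2) + y[2:] * h1) / (h1 * h2 * (h1 + h2))
    return out


def _crossings(
    d2: np.ndarray, t: np.ndarray, after_s: float, epsilon: float
) -> list[tuple[float, float]]:
    """(crossing_time, swing_score) for sign changes of d2 after ``after_s``.

    A crossing counts only when the maximum |d2| over the same-sign runs on
    both sides exceeds ``epsilon``; the score is the sum of the two swings,
    so the dominant curvature change wins.
    """
    valid = np.isfinite(d2)
    idx = np.flatnonzero(valid)
    if len(idx) < 2:
        return []
    dv = d2[idx]
    tv = t[idx]
    sign = np.sign(dv)
    out: list[tuple[float, float]] = []
    for j in range(len(dv) - 1):
        if sign[j] == 0 or sign[j + 1] == 0 or sign[j] == sign[j + 1]:
            continue
        # zero-crossing time by linear interpolation
        tc = tv[j] + (tv[j + 1] - tv[j]) * dv[j] / (dv[j] - dv[j + 1])
        if tc <= after_s:
            continue
        k = j
        left = 0.0
        while k >= 0 and sign[k] == sign[j]:
            left = max(left, abs(dv[k]))
            k -= 1
        k = j + 1
        right = 0.0
        while k < len(dv) and sign[k] == sign[j + 1]:
            right = max(right, abs(dv[k]))
            k += 1
        if min(left, right) < epsilon:
            continue
        out.append((float(tc), float(left + right)))
    return out


def find_midpoint(segment: BolusSegment, config: SmoothingConfig | None = None) -> MidpointResult:
    """Locate the sigmoid midpoint of a bolus segment.

    Per signal (AoS always; CPP/CePP when perfusion channels exist): resample
    the beat series to a uniform grid, low-pass it (zero-phase, cutoff set by
    the detection window, see :class:`SmoothingConfig`), differentiate twice,
    and keep the post-bolus zero-crossing with the dominant curvature swing.
    The consensus midpoint is the median of per-signal crossings.
    """
    config = config or SmoothingConfig()
    invalid = MidpointResult(np.nan, {}, "none", {}, valid=False)
    beats = segment.beats
    n_after = int(np.sum(beats.beat_time_s > segment.bolus.time_s))
    if len(beats) < max(5, config.detection_window_beats) or n_after < MIN_BEATS_AFTER_BOLUS:
        logger.info(
            "segment @ %.1f s: too few beats for midpoint detection (%d total, %d after bolus)",
            segment.bolus.time_s, len(beats), n_after,
        )
        return invalid

    signals: dict[str, np.ndarray] = {"AoS": beats.AoS}
    if len(segment.perfusion) == len(beats) and len(segment.perfusion) > 0:
        signals["CPP"] = segment.perfusion.CPP
        signals["CePP"] = segment.perfusion.CePP

    t = beats.beat_time_s
    dt = config.resample_dt_s
    grid = np.arange(t[0], t[-1], dt)
    median_ibi = float(np.median(np.diff(t)))
    cutoff_hz = 1.0 / (2.0 * config.detection_window_beats * median_ibi)
    cutoff_hz = min(cutoff_hz, 0.4 / dt)
    # discard the filter's settling region at both ends (one cutoff cycle;
    # residual settling curvature there mimics a response)
    edge = int(round(1.0 / (cutoff_hz * dt)))
    if len(grid) <= 2 * edge + 5 or len(grid) < 30:
        logger.info("segment @ %.1f s: too short for detection filtering", segment.bolus.time_s)
        return invalid
    sos = _sps.butter(4, cutoff_hz, fs=1.0 / dt, output="sos")

    crossings: dict[str, float] = {}
    for name, y in signals.items():
        smoothed = _sps.sosfiltfilt(sos, np.interp(grid, t, y))
        d2 = second_derivative(smoothed, grid)
        d2[:edge] = np.nan
        d2[len(d2) - edge :] = np.nan
        candidates = _crossings(d2, grid, segment.bolus.time_s, config.epsilon)
        if candidates:
            best = max(candidates, key=lambda c: c[1])
            crossings[name] = best[0]
        logger.debug("segment @ %.1f s, signal %s: %d candidate crossings", segment.bolus.time_s, name, len(candidates))

    if not crossings:
        return invalid
    # with multiple signals available, a lone or scattered set of crossings
    # is noise, not a response: require two signals to agree
    if len(signals) >= 2:
        if len(crossings) < 2:
            logger.info("segment @ %.1f s: only one signal crossed; treated as no response", segment.bolus.time_s)
            return invalid
        xs = list(crossings.values())
        gaps = [abs(a - b) for i, a in enumerate(xs) for b in xs[i + 1 :]]
        if min(gaps) > config.agreement_tol_s:
            logger.info(
                "segment @ %.1f s: per-signal crossings disagree by > %g s; treated as no response",
                segment.bolus.time_s, config.agreement_tol_s,
            )
            return invalid
    midpoint = float(np.median(list(crossings.values())))
    if not (segment.t_start_s <= midpoint <= segment.t_end_s):
        return invalid
    rule = f"median_of_{len(crossings)}" if len(crossings) > 1 else "aos_only"
    anchor = int(np.argmin(np.abs(t - midpoint)))
    refs = {
        "MAP": float(beats.MAP[anchor]),
        "AoS": float(beats.AoS[anchor]),
        "AoD": float(beats.AoD[anchor]),
    }
    logger.info(
        "segment @ %.1f s: midpoint %.2f s from %s (rule %s)",
        segment.bolus.time_s, midpoint, sorted(crossings), rule,
    )
    return MidpointResult(midpoint, crossings, rule, refs, valid=True)


def normalize(segment: BolusSegment, midpoint: MidpointResult) -> NormalizedSegment:
    """Re-express the segment with the midpoint at the origin.

    Time becomes beat time minus midpoint time; each pressure has the value
    at the beat nearest t = 0 subtracted, making the anchor beat exactly
    (0, 0) in every pressure.
    """
    if not midpoint.valid:
        raise ValueError("cannot normalize a segment with an invalid midpoint")
    beats = segment.beats
    t = beats.beat_time_s - midpoint.midpoint_time_s
    anchor = int(np.argmin(np.abs(t)))
    return NormalizedSegment(
        t,
        beats.MAP - beats.MAP[anchor],
        beats.AoS - beats.AoS[anchor],
        beats.AoD - beats.AoD[anchor],
    )
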
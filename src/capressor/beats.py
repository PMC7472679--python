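"""Beat identification and per-beat hemodynamics from the aortic pressure channel.

Detection runs on a band-limited copy of the signal (0.5-5 Hz, the plausible
heart-rate band) so baseline drift and the ventilation artifact do not move
beat boundaries; the per-beat summaries (MAP, AoS, AoD) are always computed
from the raw samples.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "BeatDetectionOptions",
    "BeatHemodynamics",
    "PerfusionSeries",
    "detect_beats",
    "beat_pressures",
    "perfusion_pressures",
]


@dataclasses.dataclass(frozen=True)
class BeatDetectionOptions:
    """Tunables for pressure-only beat detection.

    ``pulse_floor_mmHg`` is the minimum robust peak-to-trough excursion for
    a signal to count as pulsatile; below it the detector reports no beats.
    ``min_beat_s``/``max_beat_s`` are physiologic beat-duration bounds for a
    ~30 kg swine; beats outside them are excluded from the series.
    """

    band_low_hz: float = 0.5
    band_high_hz: float = 5.0
    pulse_floor_mmHg: float = 5.0
    min_beat_s: float = 0.25
    max_beat_s: float = 2.0
    prominence_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if not (0 < self.min_beat_s < self.max_beat_s):
            raise ValueError("need 0 < min_beat_s < max_beat_s")


@dataclasses.dataclass
class BeatHemodynamics:
    """Per-beat hemodynamic summaries, time-stamped at the systolic peak.

    MAP is the within-beat sample mean, AoS the within-beat maximum and AoD
    the within-beat minimum, so AoD <= MAP <= AoS holds for every beat.
    """

    beat_time_s: np.ndarray
    MAP: np.ndarray
    AoS: np.ndarray
    AoD: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beat_time_s", "MAP", "AoS", "AoD"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.beat_time_s)
        if any(len(getattr(self, f)) != n for f in ("MAP", "AoS", "AoD")):
            raise ValueError("BeatHemodynamics fields must have equal length")
        if n > 1 and not np.all(np.diff(self.beat_time_s) > 0):
            raise ValueError("beat_time_s must be strictly increasing")
        if n and not (np.all(self.AoD <= self.MAP + 1e-9) and np.all(self.MAP <= self.AoS + 1e-9)):
            raise ValueError("per-beat invariant AoD <= MAP <= AoS violated")

    def __len__(self) -> int:
        return len(self.beat_time_s)

    def slice(self, mask: np.ndarray) -> "BeatHemodynamics":
        return BeatHemodynamics(
            self.beat_time_s[mask], self.MAP[mask], self.AoS[mask], self.AoD[mask]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beat_time_s": self.beat_time_s, "MAP": self.MAP, "AoS": self.AoS, "AoD": self.AoD}
        )

    @staticmethod
    def empty() -> "BeatHemodynamics":
        z = np.empty(0)
        return BeatHemodynamics(z, z, z, z)


@dataclasses.dataclass
class PerfusionSeries:
    """Per-beat coronary (CPP) and cerebral (CePP) perfusion pressures,
    aligned 1:1 with a :class:`BeatHemodynamics` series.

    Conventions: CPP = AoD minus the right-atrial pressure at the aortic
    diastolic instant; CePP = MAP minus the mean intracranial pressure over
    the beat.
    """

    beat_time_s: np.ndarray
    CPP: np.ndarray
    CePP: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beat_time_s", "CPP", "CePP"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.beat_time_s)
        if len(self.CPP) != n or len(self.CePP) != n:
            raise ValueError("PerfusionSeries fields must have equal length")

    def __len__(self) -> int:
        return len(self.beat_time_s)

    def slice(self, mask: np.ndarray) -> "PerfusionSeries":
        if len(self) == 0:
            return self
        return PerfusionSeries(self.beat_time_s[mask], self.CPP[mask], self.CePP[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beat_time_s": self.beat_time_s, "CPP": self.CPP, "CePP": self.CePP})

    @staticmethod
    def empty() -> "PerfusionSeries":
        z = np.empty(0)
        return PerfusionSeries(z, z, z)


def _bandpass(aortic: np.ndarray, rate: float, options: BeatDetectionOptions) -> np.ndarray:
    high = min(options.band_high_hz, 0.45 * rate)
    sos = sps.butter(2, [options.band_low_hz, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, aortic)


def detect_beats(
    aortic: np.ndarray,
    rate: float,
    options: BeatDetectionOptions | None = None,
) -> np.ndarray:
    """Partition the aortic signal into beats.

    Returns an ``(n_beats, 2)`` integer array of ``[start, end)`` sample
    boundaries, each interval spanning trough-to-trough around exactly one
    systolic peak.  A pulseless signal (robust excursion below
    ``pulse_floor_mmHg``) yields an empty array with a warning, not an error.
    """
    options = options or BeatDetectionOptions()
    aortic = np.asarray(aortic, dtype=float)
    if rate <= 0:
        raise ValueError("sampling rate must be > 0")
    if len(aortic) < 2 * rate:
        raise ValueError(f"need at least 2 s of signal, got {len(aortic) / rate:.3g} s")

    filt = _bandpass(aortic, rate, options)
    lo, hi = np.percentile(filt, [2, 98])
    excursion = hi - lo
    if excursion < options.pulse_floor_mmHg:
        warnings.warn(
            f"signal looks pulseless (excursion {excursion:.2f} mmHg "
            f"< floor {options.pulse_floor_mmHg} mmHg); no beats detected",
            stacklevel=2,
        )
        return np.empty((0, 2), dtype=int)

    distance = max(1, int(options.min_beat_s * rate))
    prominence = max(options.prominence_fraction * excursion, 0.5 * options.pulse_floor_mmHg)
    peaks, _ = sps.find_peaks(filt, distance=distance, prominence=prominence)
    if len(peaks) < 2:
        warnings.warn("fewer than two systolic peaks found; no beats detected", stacklevel=2)
        return np.empty((0, 2), dtype=int)

    median_ibi = int(np.median(np.diff(peaks)))
    # trough before each peak: minimum of the filtered signal between peaks
    troughs = [int(np.argmin(filt[max(0, peaks[0] - median_ibi) : peaks[0]]) + max(0, peaks[0] - median_ibi))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        troughs.append(int(np.argmin(filt[a:b]) + a))
    end = min(len(filt), peaks[-1] + median_ibi)
    troughs.append(int(np.argmin(filt[peaks[-1] : end]) + peaks[-1]))

    bounds = np.column_stack([troughs[:-1], troughs[1:]])
    durations = (bounds[:, 1] - bounds[:, 0]) / rate
    ok = (durations >= options.min_beat_s) & (durations <= options.max_beat_s)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        logger.info("excluded %d beats outside [%g, %g] s", n_dropped, options.min_beat_s, options.max_beat_s)
    logger.info("detected %d beats", int(np.sum(ok)))
    return bounds[ok]


def beat_pressures(aortic: np.ndarray, boundaries: np.ndarray, rate: float) -> BeatHemodynamics:
    """Per-beat AoS (max), AoD (min) and MAP (mean) from raw samples.

    ``beat_time_s`` is the time of the systolic peak within each beat.
    """
    aortic = np.asarray(aortic, dtype=float)
    boundaries = np.asarray(boundaries, dtype=int)
    if boundaries.size == 0:
        return BeatHemodynamics.empty()
    times, maps, aos, aod = [], [], [], []
    for s, e in boundaries:
        seg = aortic[s:e]
        if seg.size == 0:
            continue
        peak = int(np.argmax(seg))
        times.append((s + peak) / rate)
        aos.append(float(seg[peak]))
        aod.append(float(np.min(seg)))
        maps.append(float(np.mean(seg)))
    return BeatHemodynamics(np.array(times), np.array(maps), np.array(aos), np.array(aod))


def perfusion_pressures(
    beats: BeatHemodynamics,
    ra: np.ndarray | None,
    icp: np.ndarray | None,
    boundaries: np.ndarray,
    rate: float,
    aortic: np.ndarray | None = None,
) -> PerfusionSeries:
    """Per-beat perfusion pressures; empty series when either reference
    channel is absent (downstream midpoint consensus then falls back to the
    systolic aortic pressure alone).

    The aortic samples locate the diastolic instant for CPP; when they are
    not supplied, the beat-start trough boundary stands in for it.
    """
    if ra is None or icp is None:
        return PerfusionSeries.empty()
    boundaries = np.asarray(boundaries, dtype=int)
    ra = np.asarray(ra, dtype=float)
    icp = np.asarray(icp, dtype=float)
    if boundaries.size == 0 or len(beats) == 0:
        return PerfusionSeries.empty()
    n_needed = int(boundaries[-1, 1])
    if len(ra) < n_needed or len(icp) < n_needed:
        raise ValueError(
            f"reference channel shorter than aortic span ({len(ra)}, {len(icp)} < {n_needed})"
        )
    if boundaries.shape[0] != len(beats):
        raise ValueError("boundaries and beat series are misaligned")
    if aortic is not None:
        aortic = np.asarray(aortic, dtype=float)
        if len(aortic) < n_needed:
            raise ValueError("aortic channel shorter than boundary span")
    cpp = np.empty(len(beats))
    cepp = np.empty(len(beats))
    for i, (s, e) in enumerate(boundaries):
        dia_idx = s if aortic is None else s + int(np.argmin(aortic[s:e]))
        cpp[i] = beats.AoD[i] - ra[dia_idx]
        cepp[i] = beats.MAP[i] - float(np.mean(icp[s:e]))
    return PerfusionSeries(beats.beat_time_s.copy(), cpp, cepp)
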
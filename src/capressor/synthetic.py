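"""Ground-truthed surrogate recordings for testing the analysis pipeline.

The generator emulates the hemodynamics the pipeline assumes in a
post-resuscitation hypotensive animal: a pulsatile arterial beat train with
an asymmetric morphology (fast systolic upstroke, exponential diastolic
decay), a ventilation artifact, a slow baseline drift, superimposed logistic
(sigmoid) pressor responses with known midpoint/amplitude/rate, and additive
white Gaussian noise.  Right-atrial and intracranial channels are
low-amplitude scaled versions of the same beat clock — enough to compute
perfusion pressures, with no independent physiology model.

All randomness flows from ``SyntheticParams.seed``; identical parameters
produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .io import Drug, DrugEvent, Recording, write_events, write_recording

__all__ = [
    "BolusGroundTruth",
    "TrendSpec",
    "SyntheticParams",
    "generate_recording",
    "write_fixture_suite",
    "SCENARIOS",
]


@dataclasses.dataclass(frozen=True)
class BolusGroundTruth:
    """True parameters of one injected logistic pressor response.

    The pressure contribution is ``A / (1 + exp(-k (t - t0)))`` with
    amplitude ``A`` (mmHg, may be <= 0 for a depressor or null response),
    midpoint ``t0`` (s) and rate ``k`` (1/s).  ``annotation_time_s`` is when
    the bolus is "given" on the recording clock; the physiological midpoint
    always lags it.
    """

    annotation_time_s: float
    midpoint_time_s: float
    amplitude_mmHg: float
    rate_per_s: float

    def __post_init__(self) -> None:
        if self.rate_per_s <= 0:
            raise ValueError(f"rate_per_s must be > 0, got {self.rate_per_s}")
        if self.midpoint_time_s < self.annotation_time_s:
            raise ValueError("midpoint_time_s must be >= annotation_time_s")

    def contribution(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude_mmHg / (1.0 + np.exp(-self.rate_per_s * (t - self.midpoint_time_s)))


@dataclasses.dataclass(frozen=True)
class TrendSpec:
    """Slow baseline drift: ``linear`` (slope * t) or ``exponential``
    (slope * tau * (1 - exp(-t / tau)), i.e. initial slope saturating with
    time constant ``tau_s``)."""

    kind: str = "linear"
    slope_mmHg_per_s: float = 0.0
    tau_s: float = 120.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "exponential"):
            raise ValueError(f"unknown trend kind {self.kind!r}")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")

    def contribution(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "linear":
            return self.slope_mmHg_per_s * t
        return self.slope_mmHg_per_s * self.tau_s * (1.0 - np.exp(-t / self.tau_s))


@dataclasses.dataclass
class SyntheticParams:
    """Generator configuration.

    Defaults describe a hypotensive post-resuscitation state: MAP around
    45 mmHg with a 25 mmHg pulse pressure (systolic near 60 mmHg, the
    conventional return-of-circulation threshold), a mildly tachycardic
    90 bpm rhythm, a 0.25 Hz / 3 mmHg ventilation artifact, and 1.5 mmHg
    white measurement noise.  Pressures are sampled at 1000 Hz.
    """

    duration_s: float = 180.0
    sampling_rate_hz: float = 1000.0
    heart_rate_bpm: float = 90.0
    baseline_map_mmHg: float = 45.0
    pulse_pressure_mmHg: float = 25.0
    trend: TrendSpec = dataclasses.field(default_factory=TrendSpec)
    ventilation_freq_hz: float = 0.25
    ventilation_amp_mmHg: float = 3.0
    noise_sd_mmHg: float = 1.5
    boluses: list[BolusGroundTruth] = dataclasses.field(default_factory=list)
    seed: int = 0
    beat_shape: str = "asymmetric"  # or "sinusoid" for analytic checks
    ra_mean_mmHg: float = 4.0
    ra_pulse_mmHg: float = 2.0
    icp_mean_mmHg: float = 12.0
    icp_pulse_mmHg: float = 1.5

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if self.heart_rate_bpm <= 0:
            raise ValueError(f"heart_rate_bpm must be > 0, got {self.heart_rate_bpm}")
        if self.pulse_pressure_mmHg < 0:
            raise ValueError("pulse_pressure_mmHg must be >= 0")
        if self.noise_sd_mmHg < 0:
            raise ValueError("noise_sd_mmHg must be >= 0")
        if self.beat_shape not in ("asymmetric", "sinusoid"):
            raise ValueError(f"unknown beat_shape {self.beat_shape!r}")
        for b in self.boluses:
            if not (0.0 <= b.midpoint_time_s <= self.duration_s):
                raise ValueError(
                    f"bolus midpoint {b.midpoint_time_s} s lies outside the recording "
                    f"[0, {self.duration_s}] s"
                )


# --- beat morphology ---------------------------------------------------------

_RISE_FRACTION = 0.30  # fraction of the cycle spent on the systolic upstroke
_DECAY_TAU = 0.25  # diastolic decay time constant, in cycle fractions


def _pulse_shape(phase: np.ndarray, shape: str) -> np.ndarray:
    """Periodic pulse waveform on phase in [0, 1): min 0, max 1.

    Asymmetric: raised-sine upstroke over the first ``_RISE_FRACTION`` of the
    cycle, then an exponential decay rescaled to reach 0 at end of cycle, so
    the waveform is continuous across beats.
    """
    if shape == "sinusoid":
        return 0.5 + 0.5 * np.sin(2.0 * np.pi * phase)
    r, tau = _RISE_FRACTION, _DECAY_TAU
    out = np.empty_like(phase)
    rising = phase < r
    out[rising] = np.sin(0.5 * np.pi * phase[rising] / r) ** 2
    e_end = np.exp(-(1.0 - r) / tau)
    decay = (np.exp(-(phase[~rising] - r) / tau) - e_end) / (1.0 - e_end)
    out[~rising] = decay
    return out


def _pulse_mean(shape: str) -> float:
    """Cycle mean of the pulse shape (dense deterministic quadrature)."""
    if shape == "sinusoid":
        return 0.5
    phi = (np.arange(200_000) + 0.5) / 200_000
    return float(np.mean(_pulse_shape(phi, shape)))


def generate_recording(params: SyntheticParams) -> tuple[Recording, list[BolusGroundTruth]]:
    """Generate a surrogate recording plus its verbatim ground truth.

    The aortic channel is the sum of a zero-mean-adjusted beat train scaled
    to the requested pulse pressure, the baseline MAP, the trend, the
    ventilation sinusoid, every logistic bolus contribution, and white
    Gaussian noise.  Superposition is exact by construction, so adding a
    bolus of amplitude A shifts the noiseless plateau by exactly A.
    """
    n = int(round(params.duration_s * params.sampling_rate_hz))
    t = np.arange(n) / params.sampling_rate_hz
    phase = np.mod(params.heart_rate_bpm / 60.0 * t, 1.0)

    pulse = _pulse_shape(phase, params.beat_shape)
    m = _pulse_mean(params.beat_shape)

    aortic = params.baseline_map_mmHg + params.pulse_pressure_mmHg * (pulse - m)
    aortic = aortic + params.trend.contribution(t)
    if params.ventilation_amp_mmHg != 0.0:
        aortic = aortic + params.ventilation_amp_mmHg * np.sin(
            2.0 * np.pi * params.ventilation_freq_hz * t
        )
    for bolus in params.boluses:
        aortic = aortic + bolus.contribution(t)

    ra = params.ra_mean_mmHg + params.ra_pulse_mmHg * (pulse - m)
    icp = params.icp_mean_mmHg + params.icp_pulse_mmHg * (pulse - m)

    if params.noise_sd_mmHg > 0:
        rng = np.random.default_rng(params.seed)
        aortic = aortic + rng.normal(0.0, params.noise_sd_mmHg, n)
        ra = ra + rng.normal(0.0, 0.2 * params.noise_sd_mmHg, n)
        icp = icp + rng.normal(0.0, 0.2 * params.noise_sd_mmHg, n)

    recording = Recording(
        sampling_rate_hz=params.sampling_rate_hz,
        channels={
            "aortic_pressure": aortic,
            "right_atrial_pressure": ra,
            "intracranial_pressure": icp,
        },
    )
    return recording, list(params.boluses)


# --- scenario battery --------------------------------------------------------

def _scenario_params(name: str, seed: int) -> SyntheticParams:
    """Named study-like scenarios.  All run 180 s with the calcium bolus
    annotated at 85 s and the true sigmoid midpoint at 90 s."""
    bolus = dict(annotation_time_s=85.0, midpoint_time_s=90.0)
    table = {
        # textbook responder: flat baseline, clear 12 mmHg sigmoid
        "clean_responder": dict(
            trend=TrendSpec(),
            noise_sd_mmHg=1.0,
            boluses=[BolusGroundTruth(amplitude_mmHg=12.0, rate_per_s=0.5, **bolus)],
        ),
        # pressure drifting down, bolus still wins
        "declining_responder": dict(
            trend=TrendSpec("linear", slope_mmHg_per_s=-0.05),
            noise_sd_mmHg=1.5,
            boluses=[BolusGroundTruth(amplitude_mmHg=10.0, rate_per_s=0.4, **bolus)],
        ),
        # annotated bolus with no physiological effect
        "non_responder": dict(
            trend=TrendSpec(),
            noise_sd_mmHg=1.5,
            boluses=[BolusGroundTruth(amplitude_mmHg=0.0, rate_per_s=0.4, **bolus)],
        ),
        # rapidly decompensating animal: drift loss exceeds the bolus benefit,
        # producing a negative before/after delta
        "rapid_decompensation": dict(
            trend=TrendSpec("linear", slope_mmHg_per_s=-0.20),
            baseline_map_mmHg=55.0,
            noise_sd_mmHg=1.5,
            boluses=[BolusGroundTruth(amplitude_mmHg=5.0, rate_per_s=0.4, **bolus)],
        ),
    }
    if name not in table:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(table)}")
    return SyntheticParams(seed=seed, **table[name])


SCENARIOS = ("clean_responder", "declining_responder", "non_responder", "rapid_decompensation")


def scenario_params(name: str, seed: int = 0) -> SyntheticParams:
    """Parameters for a named scenario (see :data:`SCENARIOS`)."""
    return _scenario_params(name, seed)


def write_fixture_suite(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the scenario battery: recording + events + ground-truth JSON
    for each named scenario.  Returns all written paths."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    written: list[Path] = []
    for i, name in enumerate(SCENARIOS):
        params = _scenario_params(name, seed + i)
        recording, truth = generate_recording(params)
        written.append(write_recording(recording, out_dir / f"{name}.csv"))
        events = [
            DrugEvent(time_s=b.annotation_time_s, drug=Drug.CALCIUM, dose="10 mg") for b in truth
        ]
        written.append(write_events(events, out_dir / f"{name}_events.csv"))
        gt = {
            "scenario": name,
            "seed": params.seed,
            "trend": dataclasses.asdict(params.trend),
            "boluses": [dataclasses.asdict(b) for b in truth],
        }
        p = out_dir / f"{name}_truth.json"
        p.write_text(json.dumps(gt, indent=2, sort_keys=True) + "\n")
        written.append(p)
    return written
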
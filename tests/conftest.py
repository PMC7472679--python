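import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from capressor.beats import beat_pressures, detect_beats, perfusion_pressures
from capressor.io import Drug, DrugEvent
from capressor.model import PressorResponseModel
from capressor.segmentation import segment_boluses
from capressor.synthetic import BolusGroundTruth, SyntheticParams, TrendSpec, generate_recording


def make_bolus_recording(
    seed: int = 0,
    amplitude: float = 12.0,
    rate: float = 0.4,
    noise_sd: float = 1.5,
    duration: float = 180.0,
    annotation: float | None = None,
    midpoint: float | None = None,
    **kwargs,
):
    """One-calcium-bolus synthetic recording plus its events and truth.

    By default the bolus is annotated just before the recording's middle
    (85/90 s for the default 180 s duration)."""
    if midpoint is None:
        midpoint = duration / 2.0
    if annotation is None:
        annotation = midpoint - min(5.0, duration / 36.0)
    boluses = (
        [BolusGroundTruth(annotation, midpoint, amplitude, rate)] if amplitude is not None else []
    )
    params = SyntheticParams(
        duration_s=duration, seed=seed, noise_sd_mmHg=noise_sd, boluses=boluses, **kwargs
    )
    recording, truth = generate_recording(params)
    events = [DrugEvent(b.annotation_time_s, Drug.CALCIUM, "10 mg") for b in truth]
    return recording, events, truth


def beat_series(recording):
    """Beats + perfusion for a recording (shared shorthand)."""
    aortic = recording.channels["aortic_pressure"]
    rate = recording.sampling_rate_hz
    bounds = detect_beats(aortic, rate)
    beats = beat_pressures(aortic, bounds, rate)
    perfusion = perfusion_pressures(
        beats,
        recording.channel("right_atrial_pressure"),
        recording.channel("intracranial_pressure"),
        bounds,
        rate,
        aortic=aortic,
    )
    return beats, perfusion, bounds


def single_segment(recording, events, min_context_s: float = 40.0):
    beats, perfusion, _ = beat_series(recording)
    segments = segment_boluses(events, beats, perfusion, recording.span, min_context_s)
    assert len(segments) == 1
    return segments[0]


@pytest.fixture(scope="session")
def responder_recording():
    return make_bolus_recording(seed=0)


@pytest.fixture(scope="session")
def responder_results(responder_recording):
    recording, events, _ = responder_recording
    return PressorResponseModel(recording, events).fit()
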
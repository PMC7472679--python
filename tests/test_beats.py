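"""Beat detection and per-beat hemodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capressor.beats import (
    BeatHemodynamics,
    beat_pressures,
    detect_beats,
    perfusion_pressures,
)
from capressor.synthetic import SyntheticParams, generate_recording
from capressor.synthetic import _pulse_mean  # noqa: F401 - shape mean for expected extremes

from conftest import beat_series, make_bolus_recording


def test_beat_count_matches_heart_rate_noiseless():
    params = SyntheticParams(duration_s=60.0, heart_rate_bpm=120.0, noise_sd_mmHg=0.0)
    rec, _ = generate_recording(params)
    bounds = detect_beats(rec.channels["aortic_pressure"], 1000.0)
    assert abs(len(bounds) - 120) <= 1


def test_constant_signal_yields_no_beats():
    with pytest.warns(UserWarning, match="pulseless"):
        bounds = detect_beats(np.full(5000, 60.0), 1000.0)
    assert bounds.shape == (0, 2)


def test_beat_count_robust_to_noise_across_seeds():
    """At 2 mmHg noise the count stays within 2% of the 90-beat truth."""
    counts = []
    for seed in range(20):
        params = SyntheticParams(duration_s=60.0, heart_rate_bpm=90.0, noise_sd_mmHg=2.0, seed=seed)
        rec, _ = generate_recording(params)
        counts.append(len(detect_beats(rec.channels["aortic_pressure"], 1000.0)))
    counts = np.array(counts)
    assert np.all(np.abs(counts - 90) <= 0.02 * 90)


def test_beat_count_invariant_to_constant_offset():
    params = SyntheticParams(duration_s=30.0, noise_sd_mmHg=1.0, seed=2)
    rec, _ = generate_recording(params)
    ao = rec.channels["aortic_pressure"]
    assert len(detect_beats(ao, 1000.0)) == len(detect_beats(ao + 40.0, 1000.0))


def test_too_short_signal_rejected():
    with pytest.raises(ValueError, match="2 s"):
        detect_beats(np.zeros(500), 1000.0)


def test_constant_beat_collapses_to_value():
    beats = beat_pressures(np.full(800, 47.0), np.array([[0, 800]]), 1000.0)
    assert beats.MAP[0] == beats.AoS[0] == beats.AoD[0] == 47.0


def test_sinusoid_beat_extremes_and_mean():
    """One full cycle of 80 + 20 sin: AoS 100, AoD 60, MAP 80 (within one
    sample of discretization)."""
    t = np.arange(1000) / 1000.0
    y = 80 + 20 * np.sin(2 * np.pi * t)
    beats = beat_pressures(y, np.array([[0, 1000]]), 1000.0)
    assert beats.AoS[0] == pytest.approx(100.0, abs=0.01)
    assert beats.AoD[0] == pytest.approx(60.0, abs=0.01)
    assert beats.MAP[0] == pytest.approx(80.0, abs=0.05)


def test_generator_systolic_diastolic_recovered():
    """Generator configured for 95/55 mmHg: detected AoS/AoD within 1 mmHg."""
    m = _pulse_mean("asymmetric")
    pp = 40.0
    params = SyntheticParams(
        duration_s=30.0,
        baseline_map_mmHg=55.0 + pp * m,
        pulse_pressure_mmHg=pp,
        noise_sd_mmHg=0.0,
        ventilation_amp_mmHg=0.0,
    )
    rec, _ = generate_recording(params)
    bounds = detect_beats(rec.channels["aortic_pressure"], 1000.0)
    beats = beat_pressures(rec.channels["aortic_pressure"], bounds, 1000.0)
    np.testing.assert_allclose(beats.AoS[1:], 95.0, atol=1.0)
    np.testing.assert_allclose(beats.AoD[1:], 55.0, atol=1.0)


def test_map_matches_naive_loop_oracle():
    rec, _, _ = make_bolus_recording(seed=3, duration=30.0, noise_sd=2.0)
    ao = rec.channels["aortic_pressure"]
    bounds = detect_beats(ao, 1000.0)
    beats = beat_pressures(ao, bounds, 1000.0)
    for i, (s, e) in enumerate(bounds):
        acc = 0.0
        for v in ao[s:e]:
            acc += v
        assert beats.MAP[i] == pytest.approx(acc / (e - s), abs=1e-12)
        assert beats.AoS[i] == max(ao[s:e])
        assert beats.AoD[i] == min(ao[s:e])


def test_beat_time_invariants_enforced():
    with pytest.raises(ValueError, match="increasing"):
        BeatHemodynamics([1.0, 1.0], [50, 50], [60, 60], [40, 40])
    with pytest.raises(ValueError, match="AoD <= MAP <= AoS"):
        BeatHemodynamics([1.0, 2.0], [50, 70], [60, 60], [40, 40])


@settings(max_examples=8, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    hr=st.floats(60.0, 150.0),
    noise=st.floats(0.0, 3.0),
)
def test_pressure_ordering_invariant(seed, hr, noise):
    """AoD <= MAP <= AoS on every beat of random synthetic recordings."""
    params = SyntheticParams(duration_s=20.0, heart_rate_bpm=hr, noise_sd_mmHg=noise, seed=seed)
    rec, _ = generate_recording(params)
    bounds = detect_beats(rec.channels["aortic_pressure"], 1000.0)
    beats = beat_pressures(rec.channels["aortic_pressure"], bounds, 1000.0)
    assert np.all(beats.AoD <= beats.MAP) and np.all(beats.MAP <= beats.AoS)


def test_perfusion_zero_references_identity():
    rec, _, _ = make_bolus_recording(seed=1, duration=30.0)
    ao = rec.channels["aortic_pressure"]
    bounds = detect_beats(ao, 1000.0)
    beats = beat_pressures(ao, bounds, 1000.0)
    zeros = np.zeros_like(ao)
    perf = perfusion_pressures(beats, zeros, zeros, bounds, 1000.0, aortic=ao)
    np.testing.assert_array_equal(perf.CPP, beats.AoD)
    np.testing.assert_array_equal(perf.CePP, beats.MAP)


def test_perfusion_constant_atrial_offset():
    rec, _, _ = make_bolus_recording(seed=1, duration=30.0)
    ao = rec.channels["aortic_pressure"]
    bounds = detect_beats(ao, 1000.0)
    beats = beat_pressures(ao, bounds, 1000.0)
    perf = perfusion_pressures(beats, np.full_like(ao, 5.0), np.zeros_like(ao), bounds, 1000.0, aortic=ao)
    np.testing.assert_allclose(perf.CPP, beats.AoD - 5.0)


def test_perfusion_matches_brute_force_recomputation():
    rec, _, _ = make_bolus_recording(seed=4, duration=30.0, noise_sd=1.0)
    ao = rec.channels["aortic_pressure"]
    ra = rec.channels["right_atrial_pressure"]
    icp = rec.channels["intracranial_pressure"]
    bounds = detect_beats(ao, 1000.0)
    beats = beat_pressures(ao, bounds, 1000.0)
    perf = perfusion_pressures(beats, ra, icp, bounds, 1000.0, aortic=ao)
    for i, (s, e) in enumerate(bounds):
        dia = s + int(np.argmin(ao[s:e]))
        assert perf.CPP[i] == np.min(ao[s:e]) - ra[dia]
        assert perf.CePP[i] == pytest.approx(np.mean(ao[s:e]) - np.mean(icp[s:e]), abs=1e-12)


def test_perfusion_channel_mismatch_is_error():
    rec, _, _ = make_bolus_recording(seed=1, duration=30.0)
    ao = rec.channels["aortic_pressure"]
    bounds = detect_beats(ao, 1000.0)
    beats = beat_pressures(ao, bounds, 1000.0)
    with pytest.raises(ValueError, match="shorter"):
        perfusion_pressures(beats, ao[:100], ao, bounds, 1000.0)


def test_perfusion_absent_channels_give_empty_series():
    rec, _, _ = make_bolus_recording(seed=1, duration=30.0)
    ao = rec.channels["aortic_pressure"]
    bounds = detect_beats(ao, 1000.0)
    beats = beat_pressures(ao, bounds, 1000.0)
    assert len(perfusion_pressures(beats, None, None, bounds, 1000.0)) == 0
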
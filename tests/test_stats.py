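"""Windowed comparison, tests, classification, band and histogram."""

import math

import numpy as np
import pytest

from capressor.midpoint import MidpointResult, NormalizedSegment
from capressor.model import PressorResponseModel
from capressor.stats import (
    ComparisonConfig,
    classify_responses,
    compare_segments,
    delta_histogram,
    paired_t_test,
    shapiro_wilk,
    summarize_band,
    window_mean,
)

from conftest import make_bolus_recording


def tiny_segment(t, values):
    v = np.asarray(values, dtype=float)
    return NormalizedSegment(np.asarray(t, dtype=float), v, v, v)


def closed_form_paired_t(before, after):
    """Textbook paired t: mean difference over its standard error."""
    d = np.asarray(after) - np.asarray(before)
    n = len(d)
    sd = math.sqrt(sum((x - d.mean()) ** 2 for x in d) / (n - 1))
    t = d.mean() / (sd / math.sqrt(n))
    from scipy.stats import t as tdist

    return t, n - 1, 2 * tdist.sf(abs(t), n - 1)


# --- window means -----------------------------------------------------------

def test_window_mean_constant_series():
    seg = tiny_segment([-39, -20, 5, 38], [4.0, 4.0, 4.0, 4.0])
    assert window_mean(seg, (-40, -36))["MAP"] == 4.0
    assert window_mean(seg, (36, 40))["MAP"] == 4.0


def test_window_mean_arithmetic():
    seg = tiny_segment([37.0, 38.0, 39.0], [4.0, 6.0, 8.0])
    assert window_mean(seg, (36.0, 40.0))["MAP"] == 6.0


def test_window_mean_open_interval_excludes_bounds():
    seg = tiny_segment([36.0, 38.0, 40.0], [100.0, 6.0, 100.0])
    assert window_mean(seg, (36.0, 40.0))["MAP"] == 6.0


def test_window_mean_empty_returns_nan():
    seg = tiny_segment([0.0, 1.0], [1.0, 2.0])
    assert np.isnan(window_mean(seg, (36.0, 40.0))["MAP"])


def test_window_mean_order_invariant():
    rng = np.random.default_rng(3)
    t = np.array([36.5, 37.2, 38.1, 39.9])
    v = rng.normal(size=4)
    a = window_mean(tiny_segment(t, v), (36, 40))["MAP"]
    # beats cannot be reordered inside a NormalizedSegment (time sorted),
    # so check the mean is permutation-invariant directly
    b = np.mean(v[::-1])
    assert a == pytest.approx(b)


# --- paired t ---------------------------------------------------------------

def test_paired_t_matches_closed_form_example():
    before, after = [1.0, 2.0, 3.0], [2.0, 4.0, 5.0]
    res = paired_t_test(before, after)
    t, df, p = closed_form_paired_t(before, after)
    assert res.df == df == 2
    assert res.t == pytest.approx(t, abs=1e-12)
    assert res.p == pytest.approx(p, abs=1e-12)


def test_paired_t_oracle_equivalence_random():
    """Implementation matches an independently coded closed form to 1e-10."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = rng.integers(3, 50)
        before = rng.normal(0, 5, n)
        after = before + rng.normal(1, 2, n)
        res = paired_t_test(before, after)
        t, df, p = closed_form_paired_t(before, after)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.df == df


def test_paired_t_degenerate_cases():
    res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.degenerate and res.t == 0.0 and res.p == 1.0
    res = paired_t_test([1.0, 2.0], [2.0, 3.0])  # identical nonzero diffs
    assert res.degenerate and np.isinf(res.t)
    with pytest.raises(ValueError, match="n >= 2"):
        paired_t_test([1.0], [2.0])
    with pytest.raises(ValueError, match="finite"):
        paired_t_test([1.0, np.nan], [2.0, 3.0])


def test_paired_t_type_one_error_calibrated():
    """Null differences ~ N(0,1), n=34: rejection rate near alpha=0.05."""
    rng = np.random.default_rng(7)
    rejections = 0
    reps = 500
    for _ in range(reps):
        d = rng.normal(0, 1, 34)
        if paired_t_test(np.zeros(34), d).p < 0.05:
            rejections += 1
    assert 0.03 <= rejections / reps <= 0.075


# --- Shapiro-Wilk -----------------------------------------------------------

def test_shapiro_accepts_normal_rejects_skewed():
    """One independent 500-draw sample per seed 0..99."""
    normal_ok = sum(
        shapiro_wilk(np.random.default_rng(i).normal(size=500))[1] > 0.05 for i in range(100)
    )
    skew_rej = sum(
        shapiro_wilk(np.random.default_rng(i).exponential(size=500))[1] < 0.05 for i in range(100)
    )
    assert normal_ok >= 90
    assert skew_rej >= 95


def test_shapiro_degenerate_and_size_errors():
    with pytest.raises(ValueError, match="constant"):
        shapiro_wilk(np.full(10, 1.0))
    with pytest.raises(ValueError, match="3 <= n"):
        shapiro_wilk(np.array([1.0, 2.0]))


# --- classification ---------------------------------------------------------

def valid_mp(t=90.0):
    return MidpointResult(t, {"AoS": t}, "aos_only", {}, valid=True)


def invalid_mp():
    return MidpointResult(np.nan, {}, "none", {}, valid=False)


def test_classification_rule_application():
    counts = classify_responses([5.0, -3.0, np.nan], [valid_mp(), valid_mp(), invalid_mp()])
    assert counts == {"responder": 1, "negative_delta": 1, "no_effect": 1}


def test_classification_empty():
    assert classify_responses([], []) == {"responder": 0, "negative_delta": 0, "no_effect": 0}


def test_classification_counts_sum_and_end_to_end_suite():
    """Five responder recordings and one flat one: {5, 0, 1}."""
    totals = {"responder": 0, "negative_delta": 0, "no_effect": 0}
    amplitudes = [8.0, 10.0, 12.0, 14.0, 16.0, 0.0]
    for i, A in enumerate(amplitudes):
        rec, events, _ = make_bolus_recording(seed=i, amplitude=A)
        res = PressorResponseModel(rec, events).fit()
        for key in totals:
            totals[key] += res.counts[key]
    assert sum(totals.values()) == len(amplitudes)
    assert totals == {"responder": 5, "negative_delta": 0, "no_effect": 1}


# --- band and histogram -----------------------------------------------------

def make_norm(seed, **kw):
    rec, events, _ = make_bolus_recording(seed=seed, **kw)
    res = PressorResponseModel(rec, events).fit()
    (ns,) = res.analyzed_segments
    return ns


def test_band_single_segment_sd_zero():
    ns = make_norm(0)
    band = summarize_band([ns])
    covered = band["MAP_n"] == 1
    assert np.all(band.loc[covered, "MAP_sd"] == 0.0)


def test_band_zero_at_origin():
    band = summarize_band([make_norm(0), make_norm(1)])
    row = band[band["t"] == 0.0].iloc[0]
    for p in ("MAP", "AoS", "AoD"):
        assert row[f"{p}_mean"] == 0.0
        assert row[f"{p}_sd"] == 0.0


def test_band_mirror_segments_cancel():
    t = np.linspace(-40, 40, 81)
    y = np.sin(t / 10.0)
    up = NormalizedSegment(t, y, y, y)
    down = NormalizedSegment(t, -y, -y, -y)
    band = summarize_band([up, down])
    np.testing.assert_allclose(band["MAP_mean"], 0.0, atol=1e-12)


def test_histogram_single_bin_for_equal_deltas():
    counts, edges = delta_histogram(np.array([4.1, 4.1, 4.1]), bin_width=2.0)
    assert counts.sum() == 3
    assert (counts > 0).sum() == 1


def test_histogram_zero_edge_separates_signs():
    counts, edges = delta_histogram(np.array([-1.0, 1.0]), bin_width=2.0)
    assert 0.0 in edges
    below = counts[edges[:-1] < 0].sum()
    above = counts[edges[:-1] >= 0].sum()
    assert below == 1 and above == 1


def test_comparison_config_validation():
    with pytest.raises(ValueError):
        ComparisonConfig(before_window=(-36.0, -40.0))
    with pytest.raises(ValueError):
        ComparisonConfig(before_window=(-10.0, 5.0))
    with pytest.raises(ValueError):
        ComparisonConfig(after_window=(-5.0, 40.0))


def test_compare_segments_recovers_plateau_delta():
    """Plateaued logistic of amplitude 12: after minus before ~ 12."""
    ns = make_norm(5, amplitude=12.0, rate=0.5, noise_sd=1.0)
    result = compare_segments([ns, ns])
    assert result.delta_mean["MAP"] == pytest.approx(12.0, abs=1.0)
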
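"""z-scoring, smoothing, activity change, rhythmicity, sigh-triggered tests."""

import numpy as np
import pandas as pd
import pytest

from sighsort import (
    activity_change,
    autocorrelation_ci,
    detect_rhythmic,
    generate_roi_traces,
    rhythmic_fraction,
    sigh_triggered_test,
    smooth,
    zscore,
)
from sighsort.synthetic import _add_ramp_decay


# -- z-score ----------------------------------------------------------------


def test_zscore_example():
    assert np.allclose(zscore(np.array([0.0, 2.0, 0.0, 2.0])), [-1, 1, -1, 1])


def test_zscore_affine_invariance(rng):
    f = rng.normal(size=500)
    assert np.allclose(zscore(3.7 * f + 11.0), zscore(f))


def test_zscore_constant_errors():
    with pytest.raises(ValueError, match="constant"):
        zscore(np.full(100, 2.0))


def test_zscore_output_moments(rng):
    z = zscore(rng.gamma(2.0, size=1000))
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std() == pytest.approx(1.0, abs=1e-12)


# -- smoothing --------------------------------------------------------------


def test_impulse_response_is_ten_tenths():
    x = np.zeros(100)
    x[50] = 1.0
    y = smooth(x, span=10)
    nz = np.flatnonzero(y > 1e-12)
    assert nz.size == 10 and 50 in nz
    assert np.allclose(y[nz], 0.1)


def test_constant_unchanged_by_smoothing():
    assert np.allclose(smooth(np.full(50, 2.5), 10), 2.5)


def test_smoothing_reduces_white_noise_variance_tenfold(rng):
    x = rng.normal(size=100_000)
    y = smooth(x, 10)[100:-100]
    assert x.var() / y.var() == pytest.approx(10.0, rel=0.1)


# -- activity change --------------------------------------------------------


def test_percent_difference_examples(rng):
    x = np.concatenate([2.0 * rng.normal(size=3000), 3.0 * rng.normal(size=3000)])
    ch = activity_change(x, 10.0, (0.0, 300.0), (300.0, 600.0))
    assert ch.percent_diff == pytest.approx(50.0, abs=8.0)
    same = np.tile(rng.normal(size=3000), 2)
    ch0 = activity_change(same, 10.0, (0.0, 300.0), (300.0, 600.0))
    assert ch0.percent_diff == pytest.approx(0.0, abs=1e-9)


def test_activity_change_window_validation(rng):
    x = rng.normal(size=1000)
    with pytest.raises(ValueError, match="overlap"):
        activity_change(x, 1.0, (0.0, 500.0), (400.0, 900.0))
    with pytest.raises(ValueError, match="outside"):
        activity_change(x, 1.0, (0.0, 500.0), (600.0, 2000.0))


def test_drug_gain_raises_median_activity_change():
    """Generator ROIs with doubled transient amplitude after drug onset show
    a clearly positive SD change; gain-1 controls do not."""
    meds = {g: [] for g in (1.0, 2.0)}
    for seed in range(5):
        for gain in (1.0, 2.0):
            mat, _ = generate_roi_traces(
                n_roi=10, sampling_rate=5.0, duration=1200.0, frac_rhythmic=0.0,
                drug_onset=600.0, drug_gain=gain, seed=100 + seed,
            )
            pre = mat.preprocess()
            diffs = [
                activity_change(
                    pre.data[c].to_numpy(), 5.0, (0.0, 300.0), (600.0, 900.0)
                ).percent_diff
                for c in pre.roi_ids
            ]
            meds[gain].append(np.median(diffs))
    assert np.median(meds[2.0]) > 20.0
    assert np.median(meds[2.0]) > np.median(meds[1.0])


# -- autocorrelation --------------------------------------------------------


def test_acf_lag_zero_is_one(rng):
    res = autocorrelation_ci(rng.normal(size=400), max_lag=50)
    assert res.acf[0] == pytest.approx(1.0)


def test_white_noise_pointwise_band_excludes_zero_about_five_percent(rng):
    """~5% of white-noise lags fall outside the pointwise CI of zero."""
    out = []
    for _ in range(20):
        x = rng.normal(size=2000)
        res = autocorrelation_ci(x, max_lag=300)
        half = (res.upper - res.lower) / 2
        out.append(np.mean(np.abs(res.acf[1:]) > half[1:]))
    frac = np.mean(out)
    assert 0.02 <= frac <= 0.09


def test_ar1_acf_matches_closed_form(rng):
    phi, n = 0.7, 20000
    x = np.empty(n)
    x[0] = rng.normal()
    eps = rng.normal(size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    res = autocorrelation_ci(x, max_lag=10)
    for k in range(1, 6):
        assert res.acf[k] == pytest.approx(phi**k, abs=0.03)


def test_constant_input_errors():
    with pytest.raises(ValueError):
        autocorrelation_ci(np.ones(100))


# -- rhythmicity rule -------------------------------------------------------


def test_monotone_decay_not_rhythmic(rng):
    phi, n = 0.9, 3000
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.normal(size=n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    res = detect_rhythmic(autocorrelation_ci(x, max_lag=100))
    assert not res.is_rhythmic


def test_sinusoid_detected_with_correct_lag(rng):
    t = np.arange(300)
    hits = lag_ok = 0
    for _ in range(20):
        x = 2.0 * np.sin(2 * np.pi * t / 10.0 + rng.uniform(0, 2 * np.pi))
        x = x + rng.normal(size=t.size)
        res = detect_rhythmic(autocorrelation_ci(x, sampling_rate=1.0))
        hits += res.is_rhythmic
        if res.is_rhythmic and abs(res.lag - 10.0) <= 1.0:
            lag_ok += 1
    assert hits >= 18 and lag_ok >= 18


def test_white_noise_rarely_flagged(rng):
    flags = 0
    for _ in range(200):
        res = detect_rhythmic(autocorrelation_ci(rng.normal(size=300)))
        flags += res.is_rhythmic
    assert flags / 200 <= 0.08


def test_rhythmic_generator_roi_detected():
    mat, truth = generate_roi_traces(
        n_roi=6, sampling_rate=5.0, duration=600.0, frac_rhythmic=1.0,
        rhythm_period=10.0, noise_sd=0.05, seed=3,
    )
    pre = mat.preprocess()
    lags = []
    for c in pre.roi_ids:
        # scan lags to 30 s: a few rhythm periods, not the whole recording
        res = detect_rhythmic(autocorrelation_ci(
            pre.data[c].to_numpy(), max_lag=150, sampling_rate=5.0))
        if res.is_rhythmic:
            lags.append(res.lag)
    assert len(lags) >= 5
    assert np.median(lags) == pytest.approx(10.0, rel=0.15)


def test_rhythmic_fraction_arithmetic():
    df = pd.DataFrame(
        {"slice_id": ["a"] * 20 + ["b"] * 10,
         "is_rhythmic": [True] * 2 + [False] * 18 + [True] * 10}
    )
    per_slice, mean, sd = rhythmic_fraction(df)
    assert per_slice["a"] == pytest.approx(10.0)
    assert per_slice["b"] == pytest.approx(100.0)
    assert mean == pytest.approx(55.0)


# -- sigh-triggered test ----------------------------------------------------


def test_degenerate_zero_signal_flagged():
    fz = np.zeros(4000)
    res = sigh_triggered_test(fz, 10.0, [100.0, 200.0, 300.0], windows=(2.0,))
    assert res[0].degenerate and np.isnan(res[0].p_raw)


def test_too_few_sighs_errors(rng):
    with pytest.raises(ValueError):
        sigh_triggered_test(rng.normal(size=1000), 10.0, [10.0, 20.0])


def test_edge_sighs_dropped_with_warning(rng):
    fz = rng.normal(size=1000)
    with pytest.warns(UserWarning, match="edges"):
        res = sigh_triggered_test(fz, 10.0, [0.5, 30.0, 50.0, 70.0, 99.9], windows=(2.0,))
    assert res[0].n_sighs == 3


def test_locked_transients_detected(rng):
    """A transient at every sigh onset makes post > pre, Bonferroni-significant."""
    fs, dur = 5.0, 600.0
    n = int(fs * dur)
    sighs = np.sort(rng.uniform(15, dur - 15, size=25))
    y = rng.normal(0, 0.2, size=n)
    for t in sighs:
        _add_ramp_decay(y, fs, t, 1.0, 0.5, 3.0)
    res = sigh_triggered_test(zscore(y), fs, sighs, windows=(2.0,), n_comparisons=4)
    assert res[0].mean_post > res[0].mean_pre
    assert res[0].p_corrected < 0.05


def test_bonferroni_correction_applied(rng):
    fz = rng.normal(size=5000)
    res = sigh_triggered_test(fz, 10.0, [100.0, 200.0, 300.0, 400.0],
                              windows=(1.0, 2.0), n_comparisons=8)
    for r in res:
        assert r.p_corrected == pytest.approx(min(1.0, 8 * r.p_raw))
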
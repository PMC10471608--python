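"""PCA shape prior, MCD robust covariance, Mahalanobis gates."""

import itertools

import numpy as np
import pytest
from sklearn.covariance import MinCovDet

from sighsort.classifier import (
    FeaturePrior,
    classify_evoked,
    fit_feature_prior,
    fit_shape_prior,
    mahalanobis,
    outlier_threshold,
    robust_covariance,
)


# -- Eq. 1 threshold --------------------------------------------------------


def test_threshold_worked_example():
    # linear-interpolation quartiles: Q1=2, Q3=4 -> 3 + 4*2 = 11
    assert outlier_threshold([1, 2, 3, 4, 100]) == pytest.approx(11.0)


def test_threshold_of_constant_distances_is_that_constant():
    assert outlier_threshold([5.0] * 7) == pytest.approx(5.0)


# -- robust covariance ------------------------------------------------------


def test_support_fraction_one_gives_classical_estimates(rng):
    X = rng.normal(size=(40, 3))
    res = robust_covariance(X, support_fraction=1.0, seed=0)
    assert np.allclose(res.location, X.mean(axis=0))
    assert np.allclose(res.scatter, np.cov(X, rowvar=False, ddof=1))


def test_mcd_matches_exhaustive_search(rng):
    """FAST-MCD finds the exact minimal-determinant h-subset (n=10, d=2)."""
    for s in range(5):
        X = rng.normal(size=(10, 2))
        X[:2] += 8.0
        h = 8
        best_det, best_set = np.inf, None
        for comb in itertools.combinations(range(10), h):
            det = np.linalg.det(np.cov(X[list(comb)], rowvar=False, ddof=1))
            if det < best_det:
                best_det, best_set = det, set(comb)
        res = robust_covariance(X, support_fraction=0.8, seed=s)
        assert set(res.support.tolist()) == best_set


def test_mcd_resists_planted_outliers():
    """20% outliers at 10 sigma displace the classical mean by >= 1 sigma
    but leave the robust location within 0.2 sigma (>= 95% of seeds)."""
    good = 0
    n_seeds = 40
    for s in range(n_seeds):
        rng = np.random.default_rng(1000 + s)
        X = rng.normal(size=(200, 2))
        X[:40] += 10.0
        classical_shift = np.linalg.norm(X.mean(axis=0))
        res = robust_covariance(X, support_fraction=0.75, seed=s, n_restarts=100)
        robust_shift = np.linalg.norm(res.location)
        if robust_shift < 0.2 and classical_shift >= 1.0:
            good += 1
    assert good >= 0.95 * n_seeds


def test_mcd_agrees_with_sklearn_on_location(rng):
    X = rng.normal(size=(200, 2))
    X[:40] += 10.0
    ours = robust_covariance(X, support_fraction=0.75, seed=0, n_restarts=100)
    ref = MinCovDet(support_fraction=0.75, random_state=0).fit(X)
    assert np.linalg.norm(ours.location - ref.location_) < 0.3
    # both supports must exclude every planted outlier
    assert not (set(ours.support.tolist()) & set(range(40)))


def test_mcd_preconditions(rng):
    with pytest.raises(ValueError):
        robust_covariance(rng.normal(size=(3, 5)))
    with pytest.raises(ValueError):
        robust_covariance(rng.normal(size=(20, 2)), support_fraction=0.3)


# -- Mahalanobis ------------------------------------------------------------


def _prior(loc, scatter, d_thresh=10.0):
    return FeaturePrior(
        feature_names=("a", "b"),
        robust_location=np.asarray(loc, float),
        robust_scatter=np.asarray(scatter, float),
        d_spontaneous=np.array([1.0]),
        d_thresh=d_thresh,
    )


def test_mahalanobis_zero_at_center():
    p = _prior([1.0, 2.0], np.eye(2))
    assert mahalanobis(p, [1.0, 2.0]) == 0.0


def test_mahalanobis_identity_unit_vector():
    p = _prior([0.0, 0.0], np.eye(2))
    assert mahalanobis(p, [1.0, 0.0]) == pytest.approx(1.0, abs=1e-12)


def test_mahalanobis_closed_form():
    p = _prior([0.0, 0.0], np.diag([2.0, 0.5]))
    assert mahalanobis(p, [1.0, 1.0]) == pytest.approx(np.sqrt(2.5), abs=1e-12)


def test_mahalanobis_rejects_nonfinite():
    p = _prior([0.0, 0.0], np.eye(2))
    with pytest.raises(ValueError):
        mahalanobis(p, [np.nan, 0.0])


# -- priors -----------------------------------------------------------------


def test_rank_one_shapes_need_one_component(rng):
    template = np.sin(np.linspace(0, 3 * np.pi, 80))
    shapes = np.outer(1 + rng.normal(0, 0.3, size=40), template)
    shapes += rng.normal(0, 1e-6, size=shapes.shape)
    prior = fit_shape_prior(shapes, seed=0, n_restarts=50)
    assert prior.n_components == 1


def test_planted_spectrum_80_15_5_needs_two_components():
    """Exact sample variances split 80/15/5: 80+15 >= 95 -> 2 components."""
    n = 60
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
    q -= q.mean(axis=0)
    q, _ = np.linalg.qr(q)  # orthonormal, zero-mean columns
    X = q @ np.diag(np.sqrt(np.array([80.0, 15.0, 5.0]) * (n - 1)))
    basis = np.pad(X, ((0, 0), (0, 17)))  # embed in 20-d shape space
    prior = fit_shape_prior(basis, seed=0, n_restarts=50)
    assert prior.n_components == 2


def test_too_few_shapes_errors(rng):
    with pytest.raises(ValueError, match="10 spontaneous"):
        fit_shape_prior(rng.normal(size=(5, 30)))


def test_pca_basis_orthonormal_and_scatter_spd(rng):
    shapes = rng.normal(size=(60, 40)) + np.outer(rng.normal(size=60), np.ones(40))
    prior = fit_shape_prior(shapes, seed=0, n_restarts=50)
    g = prior.pca_basis @ prior.pca_basis.T
    assert np.allclose(g, np.eye(prior.n_components), atol=1e-8)
    eig = np.linalg.eigvalsh(prior.robust_scatter)
    assert np.all(eig > 0)
    assert prior.d_thresh == pytest.approx(outlier_threshold(prior.d_spontaneous))


def test_distances_invariant_to_uniform_rescaling(rng):
    """Amplitude rescaling of the recording rescales PCA scores and the
    robust scatter together, leaving D and the gates unchanged."""
    shapes = rng.normal(size=(80, 30)) * 2 + 1
    p1 = fit_shape_prior(shapes, seed=0, n_restarts=50)
    p2 = fit_shape_prior(shapes * 7.0, seed=0, n_restarts=50)
    x = shapes[3]
    assert mahalanobis(p1, x) == pytest.approx(mahalanobis(p2, 7.0 * x), rel=1e-6)
    assert p2.d_thresh == pytest.approx(p1.d_thresh, rel=1e-6)


# -- the dual gate ----------------------------------------------------------


def _fit_gaussian_priors(rng, n=150):
    mean = np.array([1.0, 0.45, 2.0])
    cov = np.diag([0.1, 0.05, 0.3]) ** 2
    feats = rng.multivariate_normal(mean, cov, size=n)
    template = np.sin(np.linspace(0, 3 * np.pi, 60)).clip(0)
    shapes = np.outer(feats[:, 0], template) + rng.normal(0, 0.02, size=(n, 60))
    sp = fit_shape_prior(shapes, seed=1, n_restarts=50)
    fp = fit_feature_prior(feats, seed=2, n_restarts=50)
    return sp, fp, shapes, feats, template, mean, cov


def test_mean_burst_is_eupnea(rng):
    sp, fp, shapes, feats, template, mean, cov = _fit_gaussian_priors(rng)
    labels = classify_evoked(sp, fp, feats[:, 0], [(mean[0] * template, mean)])
    assert labels == ["eupnea"]


def test_amplitude_criterion_blocks_median_amplitude_outlier(rng):
    sp, fp, shapes, feats, template, mean, cov = _fit_gaussian_priors(rng)
    # grotesque shape and features, but amplitude at the spontaneous median
    weird_feats = np.array([np.median(feats[:, 0]), 5.0, 30.0])
    weird_shape = np.ones(60) * weird_feats[0]
    labels = classify_evoked(sp, fp, feats[:, 0], [(weird_shape, weird_feats)])
    assert labels == ["eupnea"]


def test_missing_interval_disqualifies(rng):
    sp, fp, shapes, feats, template, mean, cov = _fit_gaussian_priors(rng)
    bad = np.array([2.0, 0.5, np.nan])
    labels = classify_evoked(sp, fp, feats[:, 0], [(2.0 * template, bad)])
    assert labels == ["unclassified"]


def test_null_sigh_attempt_rate_bounded_by_amplitude_gate(rng):
    """Evoked bursts drawn from the spontaneous distribution itself are
    called sigh attempts at most as often as the 10% amplitude criterion."""
    sp, fp, shapes, feats, template, mean, cov = _fit_gaussian_priors(rng, n=200)
    draws = rng.multivariate_normal(mean, cov, size=1000)
    evoked = [
        (d[0] * template + rng.normal(0, 0.02, 60), d) for d in draws
    ]
    labels = classify_evoked(sp, fp, feats[:, 0], evoked)
    rate = np.mean([lab == "sigh_attempt" for lab in labels])
    assert rate <= 0.10
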
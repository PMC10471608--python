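"""Unsupervised discrimination of evoked sigh attempts from eupnea.

The classifier builds an "expected eupnea" prior from the recording's own
spontaneous (non-evoked) bursts and flags evoked bursts that are robust
outliers against it:

1. spontaneous burst shapes are decomposed into principal components and
   the smallest number of components explaining >= 95% of the variance is
   kept as the feature space;
2. a minimum-covariance-determinant (MCD) estimator gives a robust
   location and scatter of the spontaneous scores;
3. each burst's Mahalanobis distance ``D`` to that location quantifies how
   unlike an average eupneic burst it is;
4. the outlier threshold is ``D_thresh = median(D_spont) + 4 x
   IQR(D_spont)`` (quartiles by linear interpolation);
5. an identical gate fit on the intuitive features (amplitude, FWHM,
   post-burst interval) must also fire, and the burst must be larger in
   amplitude than 90% of the spontaneous bursts, before it is called a
   sigh attempt.

The MCD estimator is implemented here (seeded random restarts +
concentration steps) so its subset choice can be verified exhaustively on
small problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from sklearn.decomposition import PCA

__all__ = [
    "MCDResult",
    "ShapePrior",
    "FeaturePrior",
    "outlier_threshold",
    "robust_covariance",
    "fit_shape_prior",
    "fit_feature_prior",
    "mahalanobis",
    "classify_evoked",
]

INTUITIVE_FEATURES = ("amplitude", "fwhm_s", "post_burst_interval_s")


def outlier_threshold(d_spontaneous: np.ndarray) -> float:
    """``median + 4 x IQR`` of the spontaneous distances.

    Quartiles use linear interpolation between order statistics (the
    convention matters: for ``{1,2,3,4,100}`` the threshold is exactly
    ``3 + 4 x (4 - 2) = 11``).
    """
    d = np.asarray(d_spontaneous, dtype=float)
    if d.size == 0:
        raise ValueError("no distances")
    q1, med, q3 = np.percentile(d, [25, 50, 75], method="linear")
    return float(med + 4.0 * (q3 - q1))


# ---------------------------------------------------------------------------
# minimum covariance determinant


@dataclass
class MCDResult:
    """Robust location/scatter with the supporting subset for audit."""

    location: np.ndarray
    scatter: np.ndarray
    support: np.ndarray  # sorted indices of the h-subset
    log_det: float

    def __iter__(self):  # allows ``loc, scatter = robust_covariance(...)``
        return iter((self.location, self.scatter))


def _subset_stats(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = X[idx]
    loc = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False, ddof=1)
    return loc, np.atleast_2d(cov)


def _sq_mahal(X: np.ndarray, loc: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = X - loc
    try:
        sol = linalg.solve(cov, diff.T, assume_a="pos")
    except linalg.LinAlgError:
        sol = np.linalg.lstsq(cov, diff.T, rcond=None)[0]
    return np.einsum("ij,ji->i", diff, sol)


def _consistency_factor(alpha: float, d: int) -> float:
    """Large-sample consistency correction for the h-subset covariance."""
    if alpha >= 1.0:
        return 1.0
    q = stats.chi2.ppf(alpha, d)
    return alpha / stats.chi2.cdf(q, d + 2)


def robust_covariance(
    points: np.ndarray,
    support_fraction: float = 0.75,
    seed: int = 0,
    n_restarts: int = 500,
    max_csteps: int = 100,
    reweight: bool = True,
) -> MCDResult:
    """Minimum-covariance-determinant location and scatter.

    Searches for the ``h = ceil(support_fraction * n)`` subset whose
    classical covariance has (approximately) minimal determinant, via
    ``n_restarts`` seeded random elemental starts each refined by
    concentration steps to convergence.  ``support`` in the result is that
    raw subset.  With ``reweight=True`` (the usual finishing step) the
    returned location/scatter are recomputed from all points within the
    97.5% chi-square distance of the raw estimate, restoring efficiency
    while keeping the breakdown point.  ``support_fraction = 1`` returns
    the classical mean and covariance exactly.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be 2-D (n x d)")
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more points ({n}) than dimensions ({d})")
    if not 0.5 <= support_fraction <= 1.0:
        raise ValueError("support_fraction must be in [0.5, 1]")
    h = int(np.ceil(support_fraction * n))
    if h >= n:
        loc, cov = _subset_stats(X, np.arange(n))
        return MCDResult(loc, cov, np.arange(n), float(np.linalg.slogdet(cov)[1]))
    h = max(h, d + 1)

    rng = np.random.default_rng(seed)
    best: MCDResult | None = None
    for _ in range(n_restarts):
        idx = rng.choice(n, size=d + 1, replace=False)
        loc, cov = _subset_stats(X, idx)
        if not np.all(np.isfinite(cov)) or np.linalg.matrix_rank(cov) < d:
            cov = cov + 1e-8 * np.eye(d)
        subset = None
        for _ in range(max_csteps):
            d2 = _sq_mahal(X, loc, cov)
            new_subset = np.sort(np.argsort(d2, kind="stable")[:h])
            if subset is not None and np.array_equal(new_subset, subset):
                break
            subset = new_subset
            loc, cov = _subset_stats(X, subset)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            continue
        if best is None or logdet < best.log_det:
            best = MCDResult(loc, cov, subset, float(logdet))
    if best is None:
        raise ValueError("MCD failed: all candidate subsets were singular")
    corr = _consistency_factor(h / n, d)
    loc, scatter = best.location, corr * best.scatter
    if reweight:
        d2 = _sq_mahal(X, loc, scatter)
        mask = d2 <= stats.chi2.ppf(0.975, d)
        if mask.sum() > d:
            loc = X[mask].mean(axis=0)
            scatter = _consistency_factor(0.975, d) * np.atleast_2d(
                np.cov(X[mask], rowvar=False, ddof=1)
            )
    return MCDResult(loc, scatter, best.support, best.log_det)


# ---------------------------------------------------------------------------
# priors


@dataclass
class ShapePrior:
    """Expected-eupnea prior in PCA shape space.

    ``pca_basis`` rows are the orthonormal components (components x
    samples); ``n_components`` is the smallest number explaining >= 95% of
    the spontaneous-shape variance.  ``robust_location`` / ``robust_scatter``
    are the MCD estimates in that score space, ``d_spontaneous`` the
    Mahalanobis distances of the spontaneous bursts themselves and
    ``d_thresh`` their ``median + 4 x IQR``.
    """

    mean_shape: np.ndarray
    pca_basis: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    robust_location: np.ndarray
    robust_scatter: np.ndarray
    d_spontaneous: np.ndarray
    d_thresh: float
    support: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    ridge: float = 0.0

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project a shape vector into the retained PC score space."""
        x = np.asarray(x, dtype=float)
        return (x - self.mean_shape) @ self.pca_basis.T


@dataclass
class FeaturePrior:
    """Expected-eupnea prior over the intuitive 3-vector
    (amplitude, FWHM, post-burst interval); no PCA step."""

    feature_names: tuple[str, ...]
    robust_location: np.ndarray
    robust_scatter: np.ndarray
    d_spontaneous: np.ndarray
    d_thresh: float
    support: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    ridge: float = 0.0

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)


def _regularize(scatter: np.ndarray) -> tuple[np.ndarray, float]:
    """Add a logged ridge term when the scatter is numerically singular."""
    d = scatter.shape[0]
    ridge = 0.0
    s = scatter
    for _ in range(12):
        try:
            linalg.cholesky(s, lower=True)
            return s, ridge
        except linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-10 * max(np.trace(scatter) / d, 1e-30))
            s = scatter + ridge * np.eye(d)
    raise ValueError("scatter matrix could not be regularized")


def mahalanobis(prior: ShapePrior | FeaturePrior, x: np.ndarray) -> float:
    """Mahalanobis distance ``D`` of a burst to the mean eupneic shape.

    ``D = sqrt((s - mu)^T Sigma^-1 (s - mu))`` with the prior's robust
    location and scatter, where ``s`` is the burst's representation in the
    prior's space (PC scores for a shape prior, the raw 3-vector for the
    feature prior).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    s = prior.transform(x)
    diff = s - prior.robust_location
    sol = linalg.solve(prior.robust_scatter, diff, assume_a="pos")
    return float(np.sqrt(diff @ sol))


def _finalize_prior(scores: np.ndarray, support_fraction, seed, n_restarts):
    mcd = robust_covariance(scores, support_fraction, seed=seed, n_restarts=n_restarts)
    scatter, ridge = _regularize(mcd.scatter)
    diff = scores - mcd.location
    sol = linalg.solve(scatter, diff.T, assume_a="pos")
    d_spont = np.sqrt(np.einsum("ij,ji->i", diff, sol))
    return mcd, scatter, ridge, d_spont, outlier_threshold(d_spont)


def fit_shape_prior(
    spontaneous_shapes: np.ndarray,
    var_explained: float = 0.95,
    support_fraction: float = 0.75,
    seed: int = 0,
    n_restarts: int = 500,
) -> ShapePrior:
    """Fit the PCA + robust-covariance eupnea prior on spontaneous shapes.

    ``spontaneous_shapes`` is an ``n x samples`` matrix of burst shapes
    from spontaneous (not optogenetically evoked) activity; since
    spontaneous bursts used here are never putative sighs, the fitted
    covariance represents the prior distribution of eupnea.  Requires at
    least 10 shapes, and more shapes than retained components.
    """
    S = np.asarray(spontaneous_shapes, dtype=float)
    if S.ndim != 2 or S.shape[0] < 10:
        raise ValueError("need >= 10 spontaneous burst shapes")
    pca = PCA()
    scores_full = pca.fit_transform(S)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_explained - 1e-12) + 1)
    if S.shape[0] <= n_comp:
        raise ValueError(
            f"{S.shape[0]} spontaneous bursts cannot constrain {n_comp} shape "
            "components; record more spontaneous bursts"
        )
    scores = scores_full[:, :n_comp]
    mcd, scatter, ridge, d_spont, d_thresh = _finalize_prior(
        scores, support_fraction, seed, n_restarts
    )
    return ShapePrior(
        mean_shape=pca.mean_,
        pca_basis=pca.components_[:n_comp],
        explained_variance_ratio=pca.explained_variance_ratio_[:n_comp],
        n_components=n_comp,
        robust_location=mcd.location,
        robust_scatter=scatter,
        d_spontaneous=d_spont,
        d_thresh=d_thresh,
        support=mcd.support,
        ridge=ridge,
    )


def fit_feature_prior(
    spontaneous_features: np.ndarray,
    feature_names: tuple[str, ...] = INTUITIVE_FEATURES,
    support_fraction: float = 0.75,
    seed: int = 0,
    n_restarts: int = 500,
) -> FeaturePrior:
    """Fit the robust-covariance eupnea prior on the intuitive features.

    Rows with missing values (e.g. the last burst's undefined post-burst
    interval) must be dropped by the caller; they disqualify a burst from
    classification rather than being imputed.
    """
    F = np.asarray(spontaneous_features, dtype=float)
    if F.ndim != 2 or F.shape[0] < 10:
        raise ValueError("need >= 10 spontaneous bursts")
    if not np.all(np.isfinite(F)):
        raise ValueError("spontaneous features must be finite (drop missing rows)")
    mcd, scatter, ridge, d_spont, d_thresh = _finalize_prior(
        F, support_fraction, seed, n_restarts
    )
    return FeaturePrior(
        feature_names=tuple(feature_names),
        robust_location=mcd.location,
        robust_scatter=scatter,
        d_spontaneous=d_spont,
        d_thresh=d_thresh,
        support=mcd.support,
        ridge=ridge,
    )


def classify_evoked(
    shape_prior: ShapePrior,
    feature_prior: FeaturePrior,
    spontaneous_amplitudes: np.ndarray,
    evoked_bursts: list[tuple[np.ndarray, np.ndarray]],
    amplitude_percentile: float = 90.0,
) -> list[str]:
    """Label evoked bursts ``"sigh_attempt"`` or ``"eupnea"``.

    A burst is a sigh attempt iff it is an outlier in BOTH the shape-space
    gate and the intuitive-feature gate (``D > D_thresh`` in each) AND its
    amplitude exceeds the 90th percentile of the spontaneous amplitudes.
    Bursts whose feature vector contains a missing value (last burst of a
    sweep) are returned as ``"unclassified"``.
    """
    amps = np.asarray(spontaneous_amplitudes, dtype=float)
    amp_cut = float(np.percentile(amps, amplitude_percentile))
    labels: list[str] = []
    for shape, feats in evoked_bursts:
        feats = np.asarray(feats, dtype=float)
        if not np.all(np.isfinite(feats)):
            labels.append("unclassified")
            continue
        d_shape = mahalanobis(shape_prior, shape)
        d_feat = mahalanobis(feature_prior, feats)
        is_sigh = (
            d_shape > shape_prior.d_thresh
            and d_feat > feature_prior.d_thresh
            and feats[0] > amp_cut
        )
        labels.append("sigh_attempt" if is_sigh else "eupnea")
    return labels
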
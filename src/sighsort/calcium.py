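"""ROI calcium-fluorescence analysis.

The pipeline consumes neuropil-corrected ROI fluorescence matrices (rows =
time, columns = ROIs) and provides:

* z-scoring ``F_z = (F - mean) / SD`` and, for fast resonance-mode
  acquisitions (> 20 Hz), a 10-sample centered moving-average smoothing;
* drug-epoch activity change: the percent difference between the SD of the
  preprocessed signal in a baseline window and in a post-drug window;
* rhythmicity detection: sample autocorrelation with per-lag 95%
  (Bartlett) confidence intervals; an ROI is rhythmic when, scanning lags
  upward, the upper CI bound first drops below zero and the lower bound
  later crosses above zero -- a significant trough followed by a
  significant peak, as a periodic signal produces at half and full period;
* sigh-triggered statistics: paired t-tests between the mean signal in
  windows before and after each sigh onset, Bonferroni-corrected across
  the test family.

Because z-scoring comes first, the whole module is invariant to affine
rescaling of the raw fluorescence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf

from .util import moving_average

__all__ = [
    "ROIMatrix",
    "AcfResult",
    "RhythmicityResult",
    "ActivityChange",
    "STAResult",
    "zscore",
    "smooth",
    "activity_change",
    "autocorrelation_ci",
    "detect_rhythmic",
    "rhythmic_fraction",
    "sigh_triggered_test",
    "sigh_triggered_batch",
]

SMOOTH_ABOVE_HZ = 20.0  # resonance-mode acquisitions get the 10-sample smoothing
DEFAULT_STA_WINDOWS = (1.0, 2.0, 5.0, 10.0)


@dataclass
class ROIMatrix:
    """Per-ROI fluorescence time series.

    ``data`` is a time x ROI DataFrame (index = time in seconds) of raw,
    neuropil-corrected fluorescence; ``roi_xy`` optionally carries slice
    coordinates per ROI for map-style reporting.
    """

    data: pd.DataFrame
    sampling_rate: float
    roi_xy: pd.DataFrame | None = None

    @property
    def roi_ids(self) -> list[str]:
        return list(self.data.columns)

    def preprocess(self, span: int = 10) -> "ROIMatrix":
        """z-score every ROI; smooth only when sampling_rate > 20 Hz."""
        out = {}
        for c in self.data.columns:
            z = zscore(self.data[c].to_numpy(float))
            if self.sampling_rate > SMOOTH_ABOVE_HZ:
                z = smooth(z, span)
            out[c] = z
        return ROIMatrix(
            pd.DataFrame(out, index=self.data.index), self.sampling_rate, self.roi_xy
        )


def zscore(f: np.ndarray) -> np.ndarray:
    """``(F - mean(F)) / SD(F)``; output has mean 0 and SD 1.

    The result is invariant to any positive affine transform of the input.
    A constant ROI has no SD and raises.
    """
    f = np.asarray(f, dtype=float)
    sd = f.std()
    if sd == 0:
        raise ValueError("constant ROI: z-score undefined")
    return (f - f.mean()) / sd


def smooth(fz: np.ndarray, span: int = 10) -> np.ndarray:
    """Centered moving average (span samples, truncated at the edges)."""
    return moving_average(fz, span)


@dataclass
class ActivityChange:
    """Percent difference of signal SD between two epochs."""

    sigma_baseline: float
    sigma_drug: float

    @property
    def percent_diff(self) -> float:
        return 100.0 * (self.sigma_drug - self.sigma_baseline) / self.sigma_baseline


def activity_change(
    fz: np.ndarray,
    sampling_rate: float,
    baseline_window: tuple[float, float],
    drug_window: tuple[float, float],
) -> ActivityChange:
    """SD-based activity change between a baseline and a drug epoch.

    Windows are (start_s, end_s), half-open, within the trace and
    non-overlapping; 5-minute windows are the conventional choice.
    """
    fz = np.asarray(fz, dtype=float)
    n = fz.size

    def _segment(win: tuple[float, float]) -> np.ndarray:
        a, b = win
        i0, i1 = int(round(a * sampling_rate)), int(round(b * sampling_rate))
        if not (0 <= i0 < i1 <= n):
            raise ValueError(f"window {win} outside trace")
        return fz[i0:i1]

    b0, b1 = baseline_window
    d0, d1 = drug_window
    if max(b0, d0) < min(b1, d1):
        raise ValueError("baseline and drug windows overlap")
    sb = float(_segment(baseline_window).std())
    sd = float(_segment(drug_window).std())
    if sb == 0:
        raise ValueError("baseline SD is zero")
    return ActivityChange(sigma_baseline=sb, sigma_drug=sd)


# ---------------------------------------------------------------------------
# rhythmicity


@dataclass
class AcfResult:
    """Sample autocorrelation with per-lag confidence bounds (lag 0..max)."""

    acf: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    nobs: int
    sampling_rate: float = 1.0

    @property
    def max_lag(self) -> int:
        return self.acf.size - 1


@dataclass
class RhythmicityResult:
    """Per-ROI rhythmicity verdict."""

    is_rhythmic: bool
    lag: float = float("nan")  # seconds
    strength: float = float("nan")  # acf value at that lag


def autocorrelation_ci(
    fz: np.ndarray,
    max_lag: int | None = None,
    alpha: float = 0.05,
    sampling_rate: float = 1.0,
) -> AcfResult:
    """Sample autocorrelation at lags 0..max_lag with Bartlett 95% CIs.

    ``max_lag`` defaults to a third of the trace length.  The per-lag
    bounds are centered on the acf values (large-sample Bartlett formula);
    under white noise about ``alpha`` of lags exclude zero.
    """
    fz = np.asarray(fz, dtype=float)
    if fz.std() == 0:
        raise ValueError("constant input: autocorrelation undefined")
    if max_lag is None:
        max_lag = fz.size // 3
    if fz.size <= max_lag:
        raise ValueError("trace shorter than max_lag")
    r, confint = _sm_acf(fz, nlags=max_lag, alpha=alpha, fft=True)
    return AcfResult(
        acf=r,
        lower=confint[:, 0],
        upper=confint[:, 1],
        alpha=alpha,
        nobs=fz.size,
        sampling_rate=sampling_rate,
    )


def detect_rhythmic(
    acf_result: AcfResult,
    simultaneous: bool = True,
) -> RhythmicityResult:
    """Apply the CI-crossing rhythmicity rule to an autocorrelation.

    Scanning lags in ascending order, the ROI is rhythmic when the upper
    CI bound first drops below zero and, at a later lag, the lower bound
    crosses above zero.  The reported lag maximizes the acf within that
    post-crossing positive excursion; strength is the acf value there.

    With ``simultaneous=True`` (default) the per-lag band is widened to a
    Sidak-adjusted simultaneous band over the scanned lags, so the
    family-wise false-positive rate on non-rhythmic traces stays near the
    band's alpha rather than growing with the number of lags scanned.
    """
    r = acf_result.acf
    m = acf_result.max_lag
    if m < 2:
        return RhythmicityResult(False)
    half = (acf_result.upper - acf_result.lower) / 2.0
    if simultaneous:
        alpha = acf_result.alpha
        alpha_lag = 1.0 - (1.0 - alpha) ** (1.0 / m)
        factor = stats.norm.ppf(1 - alpha_lag / 2) / stats.norm.ppf(1 - alpha / 2)
        half = half * factor
    upper = r + half
    lower = r - half
    # lag 0 is trivially 1; scan 1..m
    neg = np.flatnonzero(upper[1:] < 0) + 1
    if neg.size == 0:
        return RhythmicityResult(False)
    k_neg = neg[0]
    pos = np.flatnonzero(lower[k_neg + 1 :] > 0) + k_neg + 1
    if pos.size == 0:
        return RhythmicityResult(False)
    k_pos = pos[0]
    # contiguous excursion where the lower bound stays above zero
    k_end = k_pos
    while k_end + 1 <= m and lower[k_end + 1] > 0:
        k_end += 1
    k_best = k_pos + int(np.argmax(r[k_pos : k_end + 1]))
    return RhythmicityResult(
        is_rhythmic=True,
        lag=k_best / acf_result.sampling_rate,
        strength=float(r[k_best]),
    )


def rhythmic_fraction(results: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Percent rhythmic ROIs per slice, plus the across-slice mean and SD.

    ``results`` needs ``slice_id`` and boolean ``is_rhythmic`` columns.
    """
    if results.empty:
        raise ValueError("no ROIs")
    per_slice = results.groupby("slice_id")["is_rhythmic"].mean() * 100.0
    return per_slice, float(per_slice.mean()), float(per_slice.std(ddof=1)) if len(per_slice) > 1 else 0.0


# ---------------------------------------------------------------------------
# sigh-triggered statistics


@dataclass
class STAResult:
    """Paired pre/post comparison of the signal around sigh onsets."""

    window: float
    mean_pre: float
    mean_post: float
    p_raw: float
    p_corrected: float
    n_sighs: int
    degenerate: bool = False


def sigh_triggered_test(
    fz: np.ndarray,
    sampling_rate: float,
    sigh_times: list[float] | np.ndarray,
    windows: tuple[float, ...] = DEFAULT_STA_WINDOWS,
    n_comparisons: int | None = None,
) -> list[STAResult]:
    """Paired t-tests of the mean signal before vs after each sigh onset.

    For each window size ``w`` the signal mean over ``[t - w, t)`` is
    paired with the mean over ``[t, t + w)`` across sighs (half-open: the
    onset sample belongs to post).  Sighs whose windows fall off the trace
    are dropped with a warning; fewer than 3 usable sighs yields no result
    for that window.  ``p_corrected`` is the Bonferroni correction with
    ``n_comparisons`` (default: the number of windows; batch callers pass
    ``n_ROIs x n_windows``).
    """
    fz = np.asarray(fz, dtype=float)
    n = fz.size
    sighs = np.sort(np.asarray(sigh_times, dtype=float))
    if sighs.size < 3:
        raise ValueError("need at least 3 sighs")
    m = n_comparisons if n_comparisons is not None else len(windows)
    out: list[STAResult] = []
    for w in windows:
        wn = int(round(w * sampling_rate))
        pre, post = [], []
        dropped = 0
        for t in sighs:
            i = int(round(t * sampling_rate))
            if i - wn < 0 or i + wn > n:
                dropped += 1
                continue
            pre.append(fz[i - wn : i].mean())
            post.append(fz[i : i + wn].mean())
        if dropped:
            warnings.warn(f"{dropped} sighs too close to trace edges for window {w}s", stacklevel=2)
        if len(pre) < 3:
            continue
        pre_a, post_a = np.asarray(pre), np.asarray(post)
        diffs = post_a - pre_a
        if np.allclose(diffs, diffs[0]):
            out.append(
                STAResult(w, float(pre_a.mean()), float(post_a.mean()),
                          float("nan"), float("nan"), len(pre), degenerate=True)
            )
            continue
        t_stat, p = stats.ttest_rel(post_a, pre_a)
        out.append(
            STAResult(
                window=w,
                mean_pre=float(pre_a.mean()),
                mean_post=float(post_a.mean()),
                p_raw=float(p),
                p_corrected=float(min(1.0, m * p)),
                n_sighs=len(pre),
            )
        )
    return out


def sigh_triggered_batch(
    mat: ROIMatrix,
    sigh_times: list[float] | np.ndarray,
    windows: tuple[float, ...] = DEFAULT_STA_WINDOWS,
) -> pd.DataFrame:
    """Sigh-triggered tests for every ROI, Bonferroni-corrected over the
    whole family (#ROIs x #windows)."""
    pre = mat.preprocess()
    m = len(pre.roi_ids) * len(windows)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for roi in pre.roi_ids:
            results = sigh_triggered_test(
                pre.data[roi].to_numpy(float), mat.sampling_rate, sigh_times,
                windows, n_comparisons=m,
            )
            for res in results:
                rows.append(
                    {
                        "roi_id": roi,
                        "window_s": res.window,
                        "mean_pre": res.mean_pre,
                        "mean_post": res.mean_post,
                        "p_raw": res.p_raw,
                        "p_corrected": res.p_corrected,
                        "n_sighs": res.n_sighs,
                        "degenerate": res.degenerate,
                    }
                )
    return pd.DataFrame(rows)
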
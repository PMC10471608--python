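"""Burst characterization metrics, sigh-shape classification, epoch summaries.

The features are the ones that separate sighs from eupneic bursts in
integrated preBotC/EMG recordings: amplitude (peak above local baseline),
burst duration (onset-level crossing to the symmetric return crossing),
full width at half maximum, area under the curve, and the two intervals to
the next burst.  Sigh shapes are classified monophasic vs biphasic from the
extracted shape vector: biphasic means two sufficiently tall local maxima
separated by a sufficiently deep trough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .detection import Burst
from .trace import Trace

__all__ = [
    "BurstFeatures",
    "compute_features",
    "classify_shape",
    "features_table",
    "label_sighs_simple",
    "summarize_epochs",
]


@dataclass
class BurstFeatures:
    """Characterization metrics for one burst.

    ``duration`` runs from the 20%-onset crossing to the first return below
    that level after the peak; ``post_burst_interval`` from the burst end to
    the next onset; ``inter_event_interval`` from onset to next onset.  The
    interval fields are NaN (missing, not zero) for the last burst.
    """

    amplitude: float
    duration: float
    fwhm: float
    auc: float
    post_burst_interval: float = float("nan")
    inter_event_interval: float = float("nan")


def _cross_time(t0: float, y0: float, t1: float, y1: float, level: float) -> float:
    """Linear-interpolated time at which the segment crosses ``level``."""
    if y1 == y0:
        return t1
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def _width_at_level(trace: Trace, peak_idx: int, level: float, stop_idx: int) -> tuple[float, float]:
    """(left, right) crossing times of ``level`` nearest the peak."""
    x = trace.samples
    i = peak_idx
    while i > 0 and x[i - 1] >= level:
        i -= 1
    if i == 0:
        left = trace.time_at(0)
    else:
        left = _cross_time(trace.time_at(i - 1), x[i - 1], trace.time_at(i), x[i], level)
    j = peak_idx
    while j < stop_idx - 1 and x[j + 1] >= level:
        j += 1
    if j >= stop_idx - 1:
        right = trace.time_at(stop_idx - 1)
    else:
        right = _cross_time(trace.time_at(j), x[j], trace.time_at(j + 1), x[j + 1], level)
    return left, right


def compute_features(
    burst: Burst,
    trace: Trace,
    next_burst: Burst | None = None,
    onset_fraction: float = 0.2,
) -> BurstFeatures:
    """Characterization metrics of ``burst`` on ``trace``.

    Amplitude and area are measured above the burst's local baseline; the
    burst end is the first return below the onset-level
    (``baseline + onset_fraction * amplitude``) after the peak, searched no
    further than the next burst's onset (or the trace end).
    """
    base = burst.baseline
    peak_idx = trace.index_at(burst.peak_time)
    amplitude = burst.peak_amplitude - base
    stop_time = next_burst.onset_time if next_burst is not None else trace.t_end
    stop_idx = max(peak_idx + 2, trace.index_at(stop_time) + 1)
    onset_level = base + onset_fraction * amplitude
    _, end_time = _width_at_level(trace, peak_idx, onset_level, stop_idx)
    duration = end_time - burst.onset_time
    half_level = base + 0.5 * amplitude
    left, right = _width_at_level(trace, peak_idx, half_level, stop_idx)
    fwhm = right - left
    i0 = trace.index_at(burst.onset_time)
    i1 = max(i0 + 2, trace.index_at(end_time) + 1)
    auc = float(np.trapezoid(trace.samples[i0:i1] - base, dx=trace.dt))
    if next_burst is not None:
        post = next_burst.onset_time - end_time
        iei = next_burst.onset_time - burst.onset_time
    else:
        post = float("nan")
        iei = float("nan")
    return BurstFeatures(
        amplitude=float(amplitude),
        duration=float(duration),
        fwhm=float(fwhm),
        auc=auc,
        post_burst_interval=float(post),
        inter_event_interval=float(iei),
    )


def classify_shape(
    shape: np.ndarray,
    baseline: float = 0.0,
    min_peak_fraction: float = 0.2,
    trough_fraction: float = 0.2,
) -> str:
    """Classify a sigh shape vector as ``"monophasic"`` or ``"biphasic"``.

    Biphasic requires two local maxima, each at least ``min_peak_fraction``
    of the global peak height (above ``baseline``), separated by a trough at
    least ``trough_fraction`` below the smaller of the two maxima.  The rule
    is deterministic and invariant to amplitude scaling.

    Doublets of eupneic activity are never auto-labeled sighs: this
    classifier is only meant to run on bursts already identified as sighs.
    """
    rel = np.asarray(shape, dtype=float) - baseline
    top = float(rel.max())
    if top <= 0:
        return "monophasic"
    peaks, _ = find_peaks(rel)
    peaks = [p for p in peaks if rel[p] >= min_peak_fraction * top]
    # any pair of tall maxima separated by a deep enough trough (noise can
    # sprinkle minor maxima between the two genuine components)
    for i, a in enumerate(peaks[:-1]):
        for b in peaks[i + 1 :]:
            trough = float(rel[a + 1 : b].min()) if b > a + 1 else min(rel[a], rel[b])
            smaller = min(rel[a], rel[b])
            if trough <= (1.0 - trough_fraction) * smaller:
                return "biphasic"
    return "monophasic"


def features_table(
    bursts: list[Burst], trace: Trace, onset_fraction: float = 0.2
) -> pd.DataFrame:
    """Per-burst feature table (one row per non-artifact burst, time order)."""
    rows = []
    live = [b for b in bursts if not b.artifact]
    for i, b in enumerate(live):
        nxt = live[i + 1] if i + 1 < len(live) else None
        f = compute_features(b, trace, nxt, onset_fraction)
        rows.append(
            {
                "onset_s": b.onset_time,
                "peak_s": b.peak_time,
                "amplitude": f.amplitude,
                "prominence": b.prominence,
                "rise_s": b.rise_time,
                "duration_s": f.duration,
                "fwhm_s": f.fwhm,
                "auc": f.auc,
                "post_burst_interval_s": f.post_burst_interval,
                "inter_event_interval_s": f.inter_event_interval,
                "artifact": b.artifact,
            }
        )
    return pd.DataFrame(rows)


def label_sighs_simple(
    features: pd.DataFrame,
    amp_ratio: float = 1.8,
    interval_ratio: float = 1.5,
) -> pd.Series:
    """Heuristic spontaneous-sigh labels from the characterization metrics.

    A burst is called a sigh when its amplitude exceeds ``amp_ratio`` times
    the median burst amplitude AND its post-burst interval exceeds
    ``interval_ratio`` times the median (sighs are large and followed by an
    extended pause).  This is the descriptive rule for spontaneous activity;
    evoked "sigh attempts" use the full outlier classifier instead.
    """
    med_amp = features["amplitude"].median()
    med_post = features["post_burst_interval_s"].median()
    lab = (features["amplitude"] > amp_ratio * med_amp) & (
        features["post_burst_interval_s"].fillna(0.0) > interval_ratio * med_post
    )
    return lab.map({True: "sigh", False: "eupnea"})


def summarize_epochs(
    bursts: pd.DataFrame,
    epochs: list[tuple[str, float, float]],
    window: float = 1200.0,
) -> pd.DataFrame:
    """Per-epoch burst counts and mean features by class.

    ``bursts`` must carry ``onset_s``, ``kind`` (eupnea/sigh) and
    ``amplitude`` columns.  Counts are normalized to events per ``window``
    seconds (default 20 min).  Epochs must be non-overlapping
    ``(name, start_s, end_s)`` tuples.  Empty epochs yield zero counts and
    missing means.
    """
    spans = sorted((s, e) for _, s, e in epochs)
    for (s0, e0), (s1, _) in zip(spans[:-1], spans[1:]):
        if s1 < e0:
            raise ValueError("epochs overlap")
    rows = []
    for name, start, end in epochs:
        if end <= start:
            raise ValueError(f"epoch {name!r} has non-positive length")
        sel = bursts[(bursts["onset_s"] >= start) & (bursts["onset_s"] < end)]
        scale = window / (end - start)
        eup = sel[sel["kind"] == "eupnea"]
        sig = sel[sel["kind"] == "sigh"]
        mean_eup = eup["amplitude"].mean() if len(eup) else float("nan")
        mean_sig = sig["amplitude"].mean() if len(sig) else float("nan")
        rows.append(
            {
                "epoch": name,
                "start_s": start,
                "end_s": end,
                "n_eupnea": len(eup),
                "n_sigh": len(sig),
                "eupnea_per_window": len(eup) * scale,
                "sigh_per_window": len(sig) * scale,
                "mean_eupnea_amplitude": mean_eup,
                "mean_sigh_amplitude": mean_sig,
                "sigh_eupnea_amp_ratio": mean_sig / mean_eup if len(eup) and len(sig) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
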
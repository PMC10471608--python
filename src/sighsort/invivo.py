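"""In vivo sigh labeling on integrated diaphragm-EMG burst sequences.

Bursts are detected on the rectified, integrated EMG exactly as on the in
vitro population trace (2.5 x SD prominence rule); each burst's amplitude
and area under the curve are then compared against the 20 bursts preceding
and the 20 following it.  A burst is a sigh when BOTH metrics deviate from
the neighbors' median by more than 6 x the neighbors' median absolute
deviation (MAD).

The printed rule compares "the area ... and the amplitude" to 6 x MAD; raw
values and MADs live on different scales, so the default comparison is the
standard robust-outlier reading ``|value - median(neighbors)| > k x
MAD(neighbors)``; ``mode="literal"`` preserves the raw-value reading
``value > k x MAD(neighbors)``.  The MAD carries no 1.4826 consistency
factor unless ``mad_scale`` says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import detect_bursts, reject_artifacts
from .features import features_table
from .trace import Trace
from .util import median_abs_deviation, moving_average

__all__ = ["EmgBurst", "rectify_integrate", "classify_sighs_invivo", "classify_emg_trace"]


@dataclass
class EmgBurst:
    """One detected diaphragm-EMG burst."""

    onset_time: float
    amplitude: float
    auc: float
    label: str = "eupnea"


def rectify_integrate(raw: Trace, window: float = 0.05) -> Trace:
    """Rectify (absolute value) then integrate (centered moving average).

    ``window`` is the moving-average span in seconds; it must cover at
    least 2 samples.  Output has the same length and sampling rate.
    """
    span = int(round(window * raw.sampling_rate))
    if span < 2:
        raise ValueError("integration window must cover at least 2 samples")
    y = moving_average(np.abs(raw.samples), span)
    return Trace(y, raw.sampling_rate, t0=raw.t0, channel=raw.channel)


def classify_sighs_invivo(
    bursts: list[EmgBurst] | pd.DataFrame,
    k: float = 6.0,
    n_neighbors: int = 20,
    min_neighbors: int = 5,
    mode: str = "deviation",
    mad_scale: float = 1.0,
) -> pd.DataFrame:
    """Label each burst sigh/eupnea by the rolling 6 x MAD rule.

    For each burst the up-to-``n_neighbors`` bursts before and after it
    (excluding itself) supply a median and MAD for amplitude and for AUC; a
    sigh requires strict exceedance on BOTH metrics.  Edge bursts use all
    available neighbors, but fewer than ``min_neighbors`` neighbors means
    the burst defaults to eupnea.  The output is a deterministic function
    of the burst table and invariant to uniform amplitude rescaling.
    """
    if isinstance(bursts, pd.DataFrame):
        df = bursts.copy()
    else:
        df = pd.DataFrame(
            {
                "onset_s": [b.onset_time for b in bursts],
                "amplitude": [b.amplitude for b in bursts],
                "auc": [b.auc for b in bursts],
            }
        )
    if mode not in ("deviation", "literal"):
        raise ValueError("mode must be 'deviation' or 'literal'")
    amp = df["amplitude"].to_numpy(float)
    auc = df["auc"].to_numpy(float)
    n = len(df)
    labels = np.full(n, "eupnea", dtype=object)
    for i in range(n):
        lo = max(0, i - n_neighbors)
        hi = min(n, i + n_neighbors + 1)
        idx = [j for j in range(lo, hi) if j != i]
        if len(idx) < min_neighbors:
            continue
        a_n, u_n = amp[idx], auc[idx]
        mad_a = median_abs_deviation(a_n, mad_scale)
        mad_u = median_abs_deviation(u_n, mad_scale)
        if mode == "deviation":
            hit_a = abs(amp[i] - np.median(a_n)) > k * mad_a
            hit_u = abs(auc[i] - np.median(u_n)) > k * mad_u
        else:
            hit_a = amp[i] > k * mad_a
            hit_u = auc[i] > k * mad_u
        if hit_a and hit_u:
            labels[i] = "sigh"
    out = df.copy()
    out["label"] = labels
    return out


def classify_emg_trace(
    trace: Trace,
    prominence_factor: float = 2.5,
    k: float = 6.0,
    n_neighbors: int = 20,
    **mad_kwargs,
) -> pd.DataFrame:
    """Full in vivo pipeline: detect bursts on an integrated EMG trace,
    compute amplitude/AUC, and apply the rolling MAD sigh rule."""
    bursts = detect_bursts(trace, prominence_factor=prominence_factor)
    bursts = reject_artifacts(bursts, trace)
    feats = features_table(bursts, trace)
    if feats.empty:
        return feats.assign(label=pd.Series(dtype=object))
    return classify_sighs_invivo(feats, k=k, n_neighbors=n_neighbors, **mad_kwargs)
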
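"""Burst detection on integrated traces.

Bursts are local maxima whose topographic prominence exceeds a multiple
(default 2.5) of the standard deviation of the whole integrated trace.  Each
burst's onset is the latest time at which the trace reaches 20% of the peak
height above a local baseline; aberrantly large (>75x the mean burst
amplitude) or very fast rising (<150 ms onset-to-peak) events are flagged as
artifacts; and a fixed 1.5-s shape vector is extracted from the onset.

Conventions
-----------
* "standard deviation of the integrated activity" is the SD of the full
  trace, not of a baseline segment.
* Peak height for the onset rule is measured above a local baseline: the
  median of the trace between the preceding burst's peak and the current
  peak (``baseline_mode="local"``); ``baseline_mode="absolute"`` uses 0.
* Peaks closer than a refractory gap (default 200 ms) are merged, keeping
  the larger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .trace import Trace

__all__ = [
    "Burst",
    "detect_bursts",
    "locate_onset",
    "reject_artifacts",
    "extract_shape",
]


@dataclass
class Burst:
    """A detected burst.

    ``shape`` spans ``[onset, onset + window)`` at the trace's sampling rate,
    zero-padded past the trace end (``shape_padded`` records this).
    ``baseline`` is the local baseline level the onset/amplitude rules used.
    """

    onset_time: float
    peak_time: float
    peak_amplitude: float
    prominence: float
    baseline: float = 0.0
    shape: np.ndarray | None = None
    shape_padded: bool = False
    onset_clamped: bool = False
    artifact: bool = False

    @property
    def rise_time(self) -> float:
        return self.peak_time - self.onset_time

    @property
    def amplitude(self) -> float:
        """Peak height above the local baseline."""
        return self.peak_amplitude - self.baseline


def _merge_refractory(peaks: np.ndarray, heights: np.ndarray, gap_samples: int) -> np.ndarray:
    """Greedily merge peaks closer than ``gap_samples``, keeping the larger."""
    if peaks.size == 0:
        return peaks
    kept: list[int] = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] < gap_samples:
            if heights[p] > heights[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return np.asarray(kept, dtype=int)


def _locate_onset_idx(
    x: np.ndarray,
    peak_idx: int,
    fraction: float,
    baseline: float,
    start_idx: int,
    level_from: np.ndarray | None = None,
) -> tuple[int, bool]:
    """Latest sample index at which ``x`` reaches ``fraction`` of peak height.

    Walking backward from the peak, the onset is the latest index ``m`` with
    ``x[m-1] < level <= x[m]``.  The onset is forced strictly before the peak
    (an instantaneous rise yields ``peak_idx - 1``).  Returns
    ``(index, clamped)`` with ``clamped`` True when no crossing exists before
    ``start_idx``.  ``level_from`` optionally supplies the array the peak
    height is read from (the raw trace when ``x`` is a smoothed copy).
    """
    ref = x if level_from is None else level_from
    level = baseline + fraction * (ref[peak_idx] - baseline)
    m = peak_idx
    while m > start_idx and x[m - 1] >= level:
        m -= 1
    if m == start_idx and peak_idx > start_idx:
        # never dropped below the level inside the search range
        return start_idx, True
    return max(start_idx, min(m, peak_idx - 1)), False


def locate_onset(
    trace: Trace,
    peak_time: float,
    fraction: float = 0.2,
    baseline: float = 0.0,
    search_start: float | None = None,
) -> float:
    """Onset time of the burst peaking at ``peak_time``.

    The onset is the latest time the trace reaches ``fraction`` (default 20%)
    of the peak height above ``baseline``, walking backward from the peak.
    When the trace never drops below that level before ``search_start``
    (default: trace start), the onset is clamped there.
    """
    peak_idx = trace.index_at(peak_time)
    start_idx = 0 if search_start is None else trace.index_at(search_start)
    idx, _ = _locate_onset_idx(trace.samples, peak_idx, fraction, baseline, start_idx)
    return trace.time_at(idx)


def extract_shape(
    trace: Trace, onset_time: float, window: float = 1.5
) -> tuple[np.ndarray, bool]:
    """Fixed-length shape vector over ``[onset, onset + window)``.

    Returns ``(shape, padded)``; samples past the trace end are zero and
    ``padded`` is True in that case.  Raises if the onset is not inside the
    trace.
    """
    n = int(round(window * trace.sampling_rate))
    i0 = trace.index_at(onset_time)
    if onset_time >= trace.t_end - trace.dt / 2 or onset_time < trace.t0:
        raise ValueError("onset outside trace")
    chunk = trace.samples[i0 : i0 + n]
    padded = chunk.size < n
    if padded:
        chunk = np.concatenate([chunk, np.zeros(n - chunk.size)])
    return chunk.astype(float), padded


def _local_baseline(trace: Trace, prev_peak_idx: int, peak_idx: int) -> float:
    """Median of the inter-burst segment preceding the burst.

    The segment between the previous peak and the current peak is trimmed
    on both sides (previous burst's decay, current burst's rise) before
    taking the median; for very short gaps the trim shrinks to a third of
    the gap on each side.
    """
    x = trace.samples
    gap = peak_idx - prev_peak_idx
    if gap <= 2:
        return float(np.median(x[prev_peak_idx : peak_idx + 1]))
    trim_l = min(int(round(1.0 * trace.sampling_rate)), gap // 3)
    trim_r = min(int(round(1.2 * trace.sampling_rate)), gap // 3)
    seg = x[prev_peak_idx + trim_l : peak_idx - trim_r]
    if seg.size == 0:
        seg = x[prev_peak_idx:peak_idx]
    return float(np.median(seg))


def detect_bursts(
    trace: Trace,
    prominence_factor: float = 2.5,
    refractory: float = 0.2,
    onset_fraction: float = 0.2,
    shape_window: float = 1.5,
    baseline_mode: str = "local",
    onset_smooth: float = 0.0,
) -> list[Burst]:
    """Detect bursts whose prominence exceeds ``prominence_factor`` x SD.

    The SD is taken over the full trace.  Peaks closer than ``refractory``
    seconds are merged keeping the larger.  Each burst is returned with its
    local baseline, 20%-rule onset and fixed-length shape vector, ordered by
    time.  A constant trace (SD = 0) yields an empty list with a warning.

    ``onset_smooth`` (seconds, default off) locates onsets on a moving
    average of the trace instead of the raw samples -- useful when broadband
    noise rivals the 20% level and would otherwise drag onsets toward the
    peak; if the smoothed trace never crosses the level, the raw trace is
    consulted before clamping.
    """
    from .util import moving_average

    x = trace.samples
    x_onset = x
    if onset_smooth > 0:
        span = max(1, int(round(onset_smooth * trace.sampling_rate)))
        x_onset = moving_average(x, span)
    sd = float(x.std())
    if sd == 0.0:
        warnings.warn("constant trace: no bursts detectable", stacklevel=2)
        return []
    peaks, props = find_peaks(x, prominence=prominence_factor * sd)
    peaks = _merge_refractory(peaks, x, max(1, int(round(refractory * trace.sampling_rate))))
    if peaks.size == 0:
        return []
    # recompute prominences for the merged peak set
    from scipy.signal import peak_prominences

    prominences = peak_prominences(x, peaks)[0]

    bursts: list[Burst] = []
    prev_peak_idx = 0
    for peak_idx, prom in zip(peaks, prominences):
        if baseline_mode == "local":
            baseline = _local_baseline(trace, prev_peak_idx, int(peak_idx))
        elif baseline_mode == "absolute":
            baseline = 0.0
        else:
            raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
        level_ref = x  # peak height measured on the raw trace
        onset_idx, clamped = _locate_onset_idx(
            x_onset, int(peak_idx), onset_fraction, baseline, prev_peak_idx,
            level_from=level_ref,
        )
        if clamped and x_onset is not x:
            onset_idx, clamped = _locate_onset_idx(
                x, int(peak_idx), onset_fraction, baseline, prev_peak_idx
            )
        onset_time = trace.time_at(onset_idx)
        shape, padded = extract_shape(trace, onset_time, shape_window)
        bursts.append(
            Burst(
                onset_time=onset_time,
                peak_time=trace.time_at(int(peak_idx)),
                peak_amplitude=float(x[peak_idx]),
                prominence=float(prom),
                baseline=baseline,
                shape=shape,
                shape_padded=padded,
                onset_clamped=clamped,
            )
        )
        prev_peak_idx = int(peak_idx)
    return bursts


def reject_artifacts(
    bursts: list[Burst],
    trace: Trace | None = None,
    amp_factor: float = 75.0,
    min_rise: float = 0.150,
) -> list[Burst]:
    """Flag and drop artifact bursts.

    A burst is an artifact when its amplitude (above local baseline) exceeds
    ``amp_factor`` times the mean amplitude of all detected bursts, or when
    it reached its peak in less than ``min_rise`` seconds.  Flagged bursts
    keep ``artifact=True`` so callers retain them for audit; the returned
    list contains only the surviving bursts.
    """
    if not bursts:
        return []
    mean_amp = float(np.mean([b.amplitude for b in bursts]))
    kept: list[Burst] = []
    for b in bursts:
        too_large = mean_amp > 0 and b.amplitude > amp_factor * mean_amp
        too_fast = b.rise_time < min_rise
        b.artifact = bool(too_large or too_fast)
        if not b.artifact:
            kept.append(b)
    return kept
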
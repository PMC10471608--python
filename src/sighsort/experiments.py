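"""Reproducible benchmark experiments on synthetic recordings.

Each function here generates labeled synthetic data, runs the relevant
pipeline stage end-to-end, and scores the result against the planted
ground truth.  They are the backbone of the validation suite and of
``scripts/acceptance.py``; problem sizes are chosen so a full sweep runs
in minutes on one core (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import calcium
from .classifier import (
    INTUITIVE_FEATURES,
    classify_evoked,
    fit_feature_prior,
    fit_shape_prior,
)
from .detection import detect_bursts, reject_artifacts
from .features import features_table
from .invivo import classify_emg_trace
from .synthetic import (
    EVOKED_LATENCY_S,
    SynthParams,
    emg_params,
    generate_emg_trace,
    generate_evoked_sweeps,
    generate_population_trace,
    generate_roi_traces,
)

__all__ = [
    "match_events",
    "detection_benchmark",
    "artifact_benchmark",
    "evoked_classification_experiment",
    "evoked_classification_benchmark",
    "invivo_benchmark",
    "rhythmicity_null_fp",
    "rhythmicity_power",
    "sta_null_pvalues",
    "sta_power",
    "drug_activity_experiment",
]

MATCH_TOL_S = 0.7  # detected peak within this of a planted peak counts as a match


def _derive_seed(seed: int, salt: int) -> int:
    """Stable 31-bit child seed."""
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31 - 1))


def match_events(
    detected_times: np.ndarray,
    label_times: np.ndarray,
    tol: float = MATCH_TOL_S,
) -> tuple[int, int, int]:
    """(true positives, false negatives, false positives).

    Sensitivity uses one-to-one greedy matching of labels to detections;
    precision counts any detection within ``tol`` of some planted event as
    correct (a biphasic sigh may legitimately yield two nearby peaks).
    """
    det = np.sort(np.asarray(detected_times, dtype=float))
    lab = np.sort(np.asarray(label_times, dtype=float))
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for t in lab:
        free = np.flatnonzero(~used)
        if free.size == 0:
            break
        j = free[np.argmin(np.abs(det[free] - t))]
        if abs(det[j] - t) <= tol:
            used[j] = True
            tp += 1
    fn = lab.size - tp
    fp = int(np.sum([np.min(np.abs(lab - t)) > tol for t in det])) if lab.size else det.size
    return tp, fn, fp


def detection_benchmark(
    n_seeds: int = 10,
    snr: float = 5.0,
    duration: float = 220.0,
    seed: int = 0,
) -> dict:
    """Detection sensitivity/precision against planted labels.

    ``snr`` is the mean eupneic amplitude over the white-noise SD.
    Artifact-free traces; scoring runs after artifact rejection, i.e. on
    the full detection pipeline.
    """
    tp = fn = fp = 0
    n_planted = 0
    for i in range(n_seeds):
        p = SynthParams(
            duration=duration,
            noise_sd=1.0 / snr,
            seed=_derive_seed(seed, 1000 + i),
        )
        trace, labels = generate_population_trace(p)
        bursts = reject_artifacts(detect_bursts(trace), trace)
        det_peaks = np.array([b.peak_time for b in bursts])
        lab_peaks = np.array([e.peak_time for e in labels if e.kind in ("eupnea", "sigh")])
        n_planted += lab_peaks.size
        a, b, c = match_events(det_peaks, lab_peaks)
        tp, fn, fp = tp + a, fn + b, fp + c
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "n_planted": n_planted,
    }


def artifact_benchmark(n_seeds: int = 100, seed: int = 0) -> dict:
    """Artifact-rejection correctness on traces with planted artifacts.

    An artifact counts as removed when no *kept* detection at its time
    remains, other than one matching a genuine planted burst (a spike that
    happens to land on a real burst produces no spurious detection for the
    rules to remove).  A true burst counts as removed when a detection
    matching a planted event but no artifact is flagged.
    """
    n_art = removed_art = removed_true = 0
    for i in range(n_seeds):
        p = SynthParams(
            duration=60.0,
            artifact_rate=0.05,
            seed=_derive_seed(seed, 2000 + i),
        )
        trace, labels = generate_population_trace(p)
        bursts = detect_bursts(trace)
        kept = reject_artifacts(bursts, trace)
        art_times = np.array([e.time for e in labels if e.kind == "artifact"])
        true_times = np.array([e.peak_time for e in labels if e.kind != "artifact"])
        n_art += art_times.size
        for t in art_times:
            spurious = [
                b for b in kept
                if abs(b.peak_time - t) <= 0.1
                and (not true_times.size or np.min(np.abs(true_times - b.peak_time)) > 0.35)
            ]
            if not spurious:
                removed_art += 1
        for b in bursts:
            if not b.artifact:
                continue
            near_artifact = art_times.size and np.min(np.abs(art_times - b.peak_time)) <= 0.1
            near_true = true_times.size and np.min(np.abs(true_times - b.peak_time)) <= 0.35
            if near_true and not near_artifact:
                removed_true += 1
    return {
        "n_artifacts": n_art,
        "artifacts_removed_fraction": removed_art / n_art if n_art else float("nan"),
        "true_bursts_removed": removed_true,
    }


# ---------------------------------------------------------------------------
# evoked classifier


def _burst_records(trace, bursts):
    """(shape, feature-vector, amplitude) per non-artifact burst."""
    feats = features_table(bursts, trace)
    live = [b for b in bursts if not b.artifact]
    out = []
    for b, row in zip(live, feats.itertuples(index=False)):
        vec = np.array([row.amplitude, row.fwhm_s, row.post_burst_interval_s])
        out.append((b, b.shape, vec))
    return out


def evoked_classification_experiment(
    seed: int = 0,
    n_sweeps: int = 25,
    p_eupnea: float = 0.45,
    p_sigh: float = 0.45,
    stim_time: float = 6.0,
    spontaneous_duration: float = 400.0,
    params: SynthParams | None = None,
    n_restarts: int = 50,
) -> pd.DataFrame:
    """Full unsupervised sigh-attempt classification run on synthetic data.

    Fits shape and intuitive-feature priors on the bursts of a sigh-free
    spontaneous recording segment (the prior must represent expected
    eupnea), then classifies each sweep's evoked burst.  Returns one row
    per evoked burst with the truth and predicted label.
    """
    base = params if params is not None else SynthParams()
    spont_params = replace(
        base,
        duration=spontaneous_duration,
        sigh_interval_mean=float("inf"),
        seed=_derive_seed(seed, 31),
    )
    trace, _ = generate_population_trace(spont_params)
    bursts = reject_artifacts(detect_bursts(trace), trace)
    records = _burst_records(trace, bursts)
    shapes = np.array([s for _, s, v in records if np.all(np.isfinite(v))])
    featmat = np.array([v for _, s, v in records if np.all(np.isfinite(v))])
    amps = featmat[:, 0]
    shape_prior = fit_shape_prior(shapes, seed=_derive_seed(seed, 32), n_restarts=n_restarts)
    feature_prior = fit_feature_prior(featmat, seed=_derive_seed(seed, 33), n_restarts=n_restarts)

    sweep_params = replace(base, seed=_derive_seed(seed, 34))
    traces, labels = generate_evoked_sweeps(
        sweep_params, n_sweeps=n_sweeps, stim_time=stim_time,
        p_eupnea=p_eupnea, p_sigh=p_sigh,
    )
    rows = []
    for i, sweep in enumerate(traces):
        truth = [e for e in labels if e.sweep == i and e.provenance in ("evoked", "failure")]
        if not truth or truth[0].kind == "failure":
            continue
        ev = truth[0]
        sbursts = reject_artifacts(detect_bursts(sweep), sweep)
        cands = [
            rec for rec in _burst_records(sweep, sbursts)
            if stim_time <= rec[0].onset_time <= stim_time + EVOKED_LATENCY_S + 0.5
        ]
        if not cands:
            continue
        b, shape, vec = cands[0]
        label = classify_evoked(shape_prior, feature_prior, amps, [(shape, vec)])[0]
        rows.append(
            {
                "sweep": i,
                "true_kind": ev.kind,
                "predicted": label,
                "amplitude": vec[0],
            }
        )
    return pd.DataFrame(rows)


def evoked_classification_benchmark(
    n_seeds: int = 10, seed: int = 0, n_sweeps: int = 25, p_eupnea: float = 0.45,
    p_sigh: float = 0.45, **kwargs,
) -> dict:
    """Aggregate sensitivity / false-positive rate of the dual-gate classifier."""
    frames = []
    for i in range(n_seeds):
        frames.append(
            evoked_classification_experiment(
                seed=_derive_seed(seed, 4000 + i), n_sweeps=n_sweeps,
                p_eupnea=p_eupnea, p_sigh=p_sigh, **kwargs,
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df = df[df["predicted"] != "unclassified"]
    sighs = df[df["true_kind"] == "sigh"]
    eups = df[df["true_kind"] == "eupnea"]
    return {
        "sensitivity": float((sighs["predicted"] == "sigh_attempt").mean()) if len(sighs) else float("nan"),
        "false_positive_rate": float((eups["predicted"] == "sigh_attempt").mean()) if len(eups) else float("nan"),
        "n_evoked": int(len(df)),
    }


def invivo_benchmark(n_seeds: int = 10, duration: float = 600.0, seed: int = 0) -> dict:
    """Rolling-MAD sigh rule vs planted EMG labels."""
    tp = fn = fp = 0
    for i in range(n_seeds):
        p = emg_params(duration=duration, seed=_derive_seed(seed, 5000 + i))
        trace, labels = generate_emg_trace(p)
        out = classify_emg_trace(trace)
        sigh_onsets = out.loc[out["label"] == "sigh", "onset_s"].to_numpy(float)
        planted = np.array([e.time for e in labels if e.kind == "sigh"])
        a, b, c = match_events(sigh_onsets, planted, tol=MATCH_TOL_S)
        tp, fn, fp = tp + a, fn + b, fp + c
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "n_planted_sighs": tp + fn,
    }


# ---------------------------------------------------------------------------
# calcium benchmarks


def rhythmicity_null_fp(n_traces: int = 1000, n_samples: int = 300, seed: int = 0) -> float:
    """Fraction of white-noise traces the rhythmicity rule flags."""
    rng = np.random.default_rng(seed)
    flagged = 0
    for _ in range(n_traces):
        x = rng.normal(size=n_samples)
        res = calcium.autocorrelation_ci(x, sampling_rate=1.0)
        if calcium.detect_rhythmic(res).is_rhythmic:
            flagged += 1
    return flagged / n_traces


def rhythmicity_power(
    n_traces: int = 100,
    period: float = 10.0,
    snr: float = 2.0,
    duration: float = 300.0,
    sampling_rate: float = 1.0,
    seed: int = 0,
) -> dict:
    """Power and lag accuracy for a planted sinusoidal rhythm.

    ``snr`` is the sine amplitude over the white-noise SD.
    """
    rng = np.random.default_rng(seed)
    n = int(duration * sampling_rate)
    t = np.arange(n) / sampling_rate
    detected = 0
    lag_ok = 0
    for _ in range(n_traces):
        phase = rng.uniform(0, 2 * np.pi)
        x = snr * np.sin(2 * np.pi * t / period + phase) + rng.normal(size=n)
        res = calcium.detect_rhythmic(calcium.autocorrelation_ci(x, sampling_rate=sampling_rate))
        if res.is_rhythmic:
            detected += 1
            if abs(res.lag - period) <= 0.1 * period:
                lag_ok += 1
    return {
        "power": detected / n_traces,
        "lag_within_10pct": lag_ok / max(detected, 1),
    }


def sta_null_pvalues(
    n_roi: int = 500,
    duration: float = 600.0,
    sampling_rate: float = 5.0,
    sigh_interval: float = 20.0,
    windows: tuple[float, ...] = calcium.DEFAULT_STA_WINDOWS,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw sigh-triggered p-values when transients are independent of sighs."""
    rng = np.random.default_rng(seed)
    mat, _ = generate_roi_traces(
        n_roi=n_roi, sampling_rate=sampling_rate, duration=duration,
        frac_rhythmic=0.0, seed=_derive_seed(seed, 61),
    )
    n_sighs = int(duration / sigh_interval)
    sighs = np.sort(rng.uniform(max(windows), duration - max(windows), size=n_sighs))
    pre = mat.preprocess()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for roi in pre.roi_ids:
            for res in calcium.sigh_triggered_test(
                pre.data[roi].to_numpy(float), sampling_rate, sighs, windows
            ):
                if not res.degenerate:
                    rows.append({"roi_id": roi, "window_s": res.window, "p_raw": res.p_raw})
    return pd.DataFrame(rows)


def sta_power(
    n_seeds: int = 20,
    duration: float = 600.0,
    sampling_rate: float = 5.0,
    window: float = 2.0,
    seed: int = 0,
) -> float:
    """Fraction of runs with Bonferroni-significant sigh-locked transients.

    One ROI per run receives a calcium transient at every sigh onset; the
    matched window's corrected p-value must clear 0.05.
    """
    from .synthetic import _add_ramp_decay

    hits = 0
    n = int(duration * sampling_rate)
    for i in range(n_seeds):
        rng = np.random.default_rng(_derive_seed(seed, 7000 + i))
        sighs = np.sort(rng.uniform(15.0, duration - 15.0, size=25))
        y = rng.normal(0, 0.2, size=n)
        for t in sighs:
            _add_ramp_decay(y, sampling_rate, t, rng.gamma(9.0, 1 / 9.0), 0.5, 3.0)
        fz = calcium.zscore(y)
        res = calcium.sigh_triggered_test(
            fz, sampling_rate, sighs, windows=(window,), n_comparisons=4
        )
        if res and res[0].p_corrected < 0.05 and res[0].mean_post > res[0].mean_pre:
            hits += 1
    return hits / n_seeds


def drug_activity_experiment(
    n_roi: int = 30,
    drug_gain: float = 2.0,
    duration: float = 1200.0,
    drug_onset: float = 600.0,
    sampling_rate: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent SD change per ROI across a drug epoch, vs planted gain."""
    mat, truth = generate_roi_traces(
        n_roi=n_roi, sampling_rate=sampling_rate, duration=duration,
        frac_rhythmic=0.13, drug_onset=drug_onset, drug_gain=drug_gain,
        seed=seed,
    )
    pre = mat.preprocess()
    rows = []
    for roi in pre.roi_ids:
        ch = calcium.activity_change(
            pre.data[roi].to_numpy(float), sampling_rate,
            baseline_window=(0.0, 300.0),
            drug_window=(drug_onset, drug_onset + 300.0),
        )
        rows.append({"roi_id": roi, "percent_diff": ch.percent_diff})
    return pd.DataFrame(rows).merge(truth, on="roi_id")
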
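"""Ground-truth-labeled synthetic recordings.

This module generates the three kinds of data the analysis pipeline
consumes, with the statistical structure the analysis assumes, so that every
downstream stage is testable without a real recording:

* integrated preBotzinger-complex population traces: a fast eupneic burst
  rhythm with a much slower, larger-amplitude sigh rhythm superimposed
  (biphasic or monophasic sigh shapes, post-sigh apnea), optional
  fast-rising high-amplitude artifacts, and additive noise;
* optogenetically evoked 20-s sweeps whose stimulus outcome is an evoked
  eupneic burst, an evoked sigh, or a failure;
* ROI calcium-fluorescence matrices containing rhythmic and arrhythmic
  units and a drug-epoch change in transient amplitude.

Burst kernel
------------
Bursts are rendered as a linear ramp rise (duration ``0.4 x
eupnea_duration``) followed by an exponential decay (time constant ``0.3 x
eupnea_duration``).  The linear rise makes the 20%-of-peak onset exact in
closed form (onset + 0.2 x rise time), keeps genuine-burst rise times well
above the 150-ms fast-rise artifact cutoff, and leaves a slope
discontinuity at the peak so planted peak times are sharply defined under
noise.  Sigh kernels scale both time constants by ``sigh_duration_factor``.
A biphasic sigh is a eupnea-scale component whose decay runs into the ramp
of the following large component; the gap is chosen so the inter-peak
trough sits at ``exp(-0.4) ~ 67%`` of the small peak -- deep enough for the
two-peak shape rule, shallow enough that the 20%-of-peak onset walks back
through the trough to the foot of the small component.

The additive noise is white Gaussian with SD ``noise_sd``; the summed
signal+noise is then passed through a 50-ms centered moving average,
emulating the integration applied to raw recordings upstream of this
pipeline.  Artifacts are single-sample spikes of 80-100x the mean eupneic
amplitude (fast-rising by construction), exercising the rejection rules.

Randomness: one integer seed drives a :class:`numpy.random.SeedSequence`;
children are spawned in the documented order (event schedule, artifacts,
noise) -- or one child per sweep / per ROI -- so identical parameters give
bit-identical output and switching noise off does not move the events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trace import Trace
from .util import moving_average

__all__ = [
    "SynthParams",
    "EventLabel",
    "emg_params",
    "generate_population_trace",
    "generate_evoked_sweeps",
    "generate_emg_trace",
    "generate_roi_traces",
]

INTEGRATION_WINDOW_S = 0.05
RISE_FRACTION = 0.4  # rise time = RISE_FRACTION * eupnea_duration
DECAY_FRACTION = 0.3  # decay tau = DECAY_FRACTION * eupnea_duration
BIPHASIC_GAP_TAU = 0.4  # large-component ramp starts this many decay taus past the small peak
EVOKED_LATENCY_S = 0.05
ARTIFACT_AMP_RANGE = (80.0, 100.0)  # x mean eupneic amplitude


@dataclass
class SynthParams:
    """Generator parameters for integrated population / EMG traces.

    Defaults describe a regular, well-synchronized in vitro slice rhythm:
    a ~4-s eupneic period, sighs roughly every 2 minutes at 2.5x eupneic
    amplitude and 1.5x duration, a doubled post-sigh interval, and 78.5%
    biphasic sighs.  Amplitudes are in arbitrary units with mean eupneic
    amplitude 1.
    """

    sampling_rate: float = 200.0  # Hz
    duration: float = 1200.0  # s
    eupnea_period_mean: float = 4.0  # s
    eupnea_period_cv: float = 0.15
    eupnea_amp_mean: float = 1.0  # a.u.
    eupnea_amp_cv: float = 0.1
    eupnea_duration: float = 1.0  # s (nominal: ramp rise + ~2 decay taus)
    sigh_interval_mean: float = 120.0  # s; inf = no sighs
    sigh_amp_factor: float = 2.5  # sigh peak / eupnea peak
    sigh_duration_factor: float = 1.5
    post_sigh_apnea_factor: float = 2.0  # post-sigh interval / eupneic interval
    p_biphasic: float = 0.785
    noise_sd: float = 0.05  # a.u., white, before the integration filter
    artifact_rate: float = 0.0  # events / s
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "sampling_rate": self.sampling_rate,
            "duration": self.duration,
            "eupnea_period_mean": self.eupnea_period_mean,
            "eupnea_amp_mean": self.eupnea_amp_mean,
            "eupnea_duration": self.eupnea_duration,
            "sigh_interval_mean": self.sigh_interval_mean,
            "sigh_duration_factor": self.sigh_duration_factor,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.p_biphasic <= 1:
            raise ValueError("p_biphasic must be in [0, 1]")
        if not self.sigh_amp_factor > 1:
            raise ValueError("sigh_amp_factor must be > 1")
        if not self.post_sigh_apnea_factor >= 1:
            raise ValueError("post_sigh_apnea_factor must be >= 1")
        for name, v in (
            ("eupnea_period_cv", self.eupnea_period_cv),
            ("eupnea_amp_cv", self.eupnea_amp_cv),
            ("noise_sd", self.noise_sd),
            ("artifact_rate", self.artifact_rate),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    # kernel geometry ------------------------------------------------------
    @property
    def rise_time(self) -> float:
        return RISE_FRACTION * self.eupnea_duration

    @property
    def decay_tau(self) -> float:
        return DECAY_FRACTION * self.eupnea_duration


@dataclass
class EventLabel:
    """Ground-truth record of one planted event.

    ``time`` is the exact onset (start of the rising ramp); ``peak_time``
    the exact peak of the (larger, for biphasic sighs) component.
    ``kind`` is eupnea / sigh / artifact, plus the extra value ``failure``
    for evoked sweeps in which the stimulus evoked nothing (such labels
    carry no burst).  ``shape_class`` is n/a except for sighs.
    """

    time: float
    kind: str
    peak_time: float = 0.0
    shape_class: str = "n/a"
    provenance: str = "spontaneous"
    amplitude: float = 0.0
    sweep: int | None = None


def emg_params(**overrides) -> SynthParams:
    """Defaults for in vivo-like integrated diaphragm EMG.

    In vivo, sighs are distinguished chiefly by amplitude and area: 3x the
    eupneic amplitude and 2x the duration (AUC ratio ~6x), a milder
    post-sigh pause, and mostly single-peaked shapes.
    """
    base = dict(
        sigh_amp_factor=3.0,
        sigh_duration_factor=2.0,
        post_sigh_apnea_factor=1.3,
        p_biphasic=0.3,
    )
    base.update(overrides)
    return SynthParams(**base)


# ---------------------------------------------------------------------------
# kernel rendering


def _add_ramp_decay(
    y: np.ndarray, fs: float, onset: float, amp: float, rise: float, decay: float
) -> float:
    """Add a ramp-rise / exp-decay kernel to ``y`` in place.

    Returns the exact peak time.  The kernel is rendered to 8 decay taus.
    """
    n = y.size
    i0 = int(math.ceil(onset * fs - 1e-9))
    i1 = min(n, int(math.ceil((onset + rise + 8 * decay) * fs)))
    if i0 >= n:
        return onset + rise
    t = np.arange(i0, i1) / fs - onset
    k = np.where(t < rise, t / rise, np.exp(-(t - rise) / decay))
    np.clip(k, 0.0, None, out=k)
    y[i0:i1] += amp * k
    return onset + rise


def _render_events(
    events: list[EventLabel],
    params: SynthParams,
    duration: float,
    rng_noise: np.random.Generator,
) -> np.ndarray:
    """Noisy, integration-filtered signal for a list of planted events."""
    fs = params.sampling_rate
    n = int(round(duration * fs))
    y = np.zeros(n)
    rise_e, tau_e = params.rise_time, params.decay_tau
    rise_s = rise_e * params.sigh_duration_factor
    tau_s = tau_e * params.sigh_duration_factor
    for ev in events:
        if ev.kind == "eupnea":
            _add_ramp_decay(y, fs, ev.time, ev.amplitude, rise_e, tau_e)
        elif ev.kind == "sigh":
            if ev.shape_class == "biphasic":
                a_small = ev.amplitude / params.sigh_amp_factor
                small_peak = _add_ramp_decay(y, fs, ev.time, a_small, rise_e, tau_e)
                big_onset = small_peak + BIPHASIC_GAP_TAU * tau_e
                _add_ramp_decay(y, fs, big_onset, ev.amplitude, rise_s, tau_s)
            else:
                _add_ramp_decay(y, fs, ev.time, ev.amplitude, rise_s, tau_s)
        elif ev.kind == "artifact":
            idx = int(round(ev.time * fs))
            if 0 <= idx < n:
                y[idx] += ev.amplitude
        # "failure" labels carry no burst
    if params.noise_sd > 0:
        y = y + rng_noise.normal(0.0, params.noise_sd, size=n)
    span = max(1, int(round(INTEGRATION_WINDOW_S * fs)))
    return moving_average(y, span)


def noiseless_signal(events: list[EventLabel], params: SynthParams, duration: float | None = None) -> np.ndarray:
    """Exact kernel sum for a label list (no noise, no integration filter).

    The independent reconstruction used by tests: onsets/peaks of the
    returned signal are the planted ones to machine precision.
    """
    dur = params.duration if duration is None else duration
    fs = params.sampling_rate
    y = np.zeros(int(round(dur * fs)))
    rise_e, tau_e = params.rise_time, params.decay_tau
    rise_s = rise_e * params.sigh_duration_factor
    tau_s = tau_e * params.sigh_duration_factor
    for ev in events:
        if ev.kind == "eupnea":
            _add_ramp_decay(y, fs, ev.time, ev.amplitude, rise_e, tau_e)
        elif ev.kind == "sigh":
            if ev.shape_class == "biphasic":
                a_small = ev.amplitude / params.sigh_amp_factor
                small_peak = _add_ramp_decay(y, fs, ev.time, a_small, rise_e, tau_e)
                _add_ramp_decay(y, fs, small_peak + BIPHASIC_GAP_TAU * tau_e, ev.amplitude, rise_s, tau_s)
            else:
                _add_ramp_decay(y, fs, ev.time, ev.amplitude, rise_s, tau_s)
    return y


# ---------------------------------------------------------------------------
# spontaneous traces


def _biphasic_peak_time(onset: float, params: SynthParams) -> float:
    small_peak = onset + params.rise_time
    return (
        small_peak
        + BIPHASIC_GAP_TAU * params.decay_tau
        + params.rise_time * params.sigh_duration_factor
    )


def _schedule_spontaneous(params: SynthParams, rng: np.random.Generator) -> list[EventLabel]:
    """Plant eupneic cycles with sighs replacing cycles at the sigh interval."""
    cv = max(params.eupnea_period_cv, 1e-9)
    shape_p = 1.0 / cv**2
    amp_cv = max(params.eupnea_amp_cv, 1e-9)
    shape_a = 1.0 / amp_cv**2

    def draw_period() -> float:
        return rng.gamma(shape_p, params.eupnea_period_mean / shape_p)

    def draw_amp() -> float:
        return rng.gamma(shape_a, params.eupnea_amp_mean / shape_a)

    events: list[EventLabel] = []
    t = rng.uniform(0.2, 0.8) * params.eupnea_period_mean
    if math.isinf(params.sigh_interval_mean):
        next_sigh = math.inf
    else:
        next_sigh = rng.exponential(params.sigh_interval_mean)
    t_stop = params.duration - params.eupnea_duration
    while t < t_stop:
        a = draw_amp()
        if t >= next_sigh:
            biphasic = rng.random() < params.p_biphasic
            shape_class = "biphasic" if biphasic else "monophasic"
            peak = (
                _biphasic_peak_time(t, params)
                if biphasic
                else t + params.rise_time * params.sigh_duration_factor
            )
            events.append(
                EventLabel(
                    time=t,
                    kind="sigh",
                    peak_time=peak,
                    shape_class=shape_class,
                    amplitude=params.sigh_amp_factor * a,
                )
            )
            next_sigh = t + rng.exponential(params.sigh_interval_mean)
            t += draw_period() * params.post_sigh_apnea_factor
        else:
            events.append(
                EventLabel(time=t, kind="eupnea", peak_time=t + params.rise_time, amplitude=a)
            )
            t += draw_period()
    return events


def _schedule_artifacts(params: SynthParams, rng: np.random.Generator) -> list[EventLabel]:
    n_art = rng.poisson(params.artifact_rate * params.duration)
    out = []
    for _ in range(n_art):
        t = rng.uniform(0, params.duration)
        amp = rng.uniform(*ARTIFACT_AMP_RANGE) * params.eupnea_amp_mean
        out.append(EventLabel(time=t, kind="artifact", peak_time=t, amplitude=amp))
    return sorted(out, key=lambda e: e.time)


def _generate_trace(params: SynthParams, channel: str) -> tuple[Trace, list[EventLabel]]:
    if params.duration < params.eupnea_period_mean:
        raise ValueError("trace too short")
    ss = np.random.SeedSequence(params.seed)
    rng_events, rng_art, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))
    events = _schedule_spontaneous(params, rng_events)
    events = sorted(events + _schedule_artifacts(params, rng_art), key=lambda e: e.time)
    y = _render_events(events, params, params.duration, rng_noise)
    return Trace(y, params.sampling_rate, channel=channel), events


def generate_population_trace(params: SynthParams) -> tuple[Trace, list[EventLabel]]:
    """Integrated preBotC population trace: eupnea + sighs (+ artifacts).

    Returns the trace and the ground-truth labels of every planted event,
    in time order.  Identical ``params`` (including the seed) give
    bit-identical output.
    """
    return _generate_trace(params, channel="preBotC")


def generate_emg_trace(params: SynthParams | None = None) -> tuple[Trace, list[EventLabel]]:
    """Integrated diaphragm-EMG trace with in vivo-like burst statistics.

    Defaults come from :func:`emg_params`: sighs at 3x amplitude and 2x
    duration (AUC ratio ~6x eupnea).
    """
    if params is None:
        params = emg_params()
    return _generate_trace(params, channel="dia-EMG")


# ---------------------------------------------------------------------------
# evoked sweeps


def generate_evoked_sweeps(
    params: SynthParams,
    n_sweeps: int,
    stim_time: float = 10.0,
    p_eupnea: float = 0.5,
    p_sigh: float = 0.25,
    sweep_duration: float = 20.0,
) -> tuple[list[Trace], list[EventLabel]]:
    """Continuous stimulation sweeps with eupnea / sigh / failure outcomes.

    Each sweep carries background spontaneous eupnea plus, at
    ``stim_time`` (+50 ms latency), an evoked eupneic burst with
    probability ``p_eupnea``, an evoked (monophasic) sigh with probability
    ``p_sigh``, or nothing (a failure).  Spontaneous bursts are held out of
    a +-1-s guard window around the stimulus so the evoked outcome is
    unambiguous.  Labels carry the 0-based sweep index; failure labels have
    ``kind="failure"`` and no planted burst.
    """
    if p_eupnea < 0 or p_sigh < 0:
        raise ValueError("probabilities must be >= 0")
    if p_eupnea + p_sigh > 1 + 1e-12:
        raise ValueError("p_eupnea + p_sigh must be <= 1")
    if not 0 < stim_time < sweep_duration:
        raise ValueError("stim_time outside sweep")
    sweep_params = replace(params, duration=sweep_duration)
    ss = np.random.SeedSequence(params.seed)
    traces: list[Trace] = []
    labels: list[EventLabel] = []
    cv = max(params.eupnea_period_cv, 1e-9)
    shape_p = 1.0 / cv**2
    amp_cv = max(params.eupnea_amp_cv, 1e-9)
    shape_a = 1.0 / amp_cv**2
    for i, child in enumerate(ss.spawn(n_sweeps)):
        rng = np.random.default_rng(child)

        def draw_period() -> float:
            return rng.gamma(shape_p, params.eupnea_period_mean / shape_p)

        def draw_amp() -> float:
            return rng.gamma(shape_a, params.eupnea_amp_mean / shape_a)

        events: list[EventLabel] = []
        t = rng.uniform(0.2, 0.8) * params.eupnea_period_mean
        while t < stim_time - 1.0 - params.eupnea_duration:
            events.append(
                EventLabel(
                    time=t, kind="eupnea", peak_time=t + params.rise_time,
                    amplitude=draw_amp(), sweep=i,
                )
            )
            t += draw_period()
        u = rng.random()
        t_ev = stim_time + EVOKED_LATENCY_S
        if u < p_eupnea:
            events.append(
                EventLabel(
                    time=t_ev, kind="eupnea", peak_time=t_ev + params.rise_time,
                    amplitude=draw_amp(), provenance="evoked", sweep=i,
                )
            )
            t = t_ev + draw_period()
        elif u < p_eupnea + p_sigh:
            a = draw_amp()
            events.append(
                EventLabel(
                    time=t_ev, kind="sigh",
                    peak_time=t_ev + params.rise_time * params.sigh_duration_factor,
                    shape_class="monophasic", amplitude=params.sigh_amp_factor * a,
                    provenance="evoked", sweep=i,
                )
            )
            t = t_ev + draw_period() * params.post_sigh_apnea_factor
        else:
            events.append(
                EventLabel(time=stim_time, kind="failure", peak_time=stim_time,
                           provenance="failure", sweep=i)
            )
            t = stim_time + max(draw_period(), 1.5)
        while t < sweep_duration - params.eupnea_duration:
            events.append(
                EventLabel(
                    time=t, kind="eupnea", peak_time=t + params.rise_time,
                    amplitude=draw_amp(), sweep=i,
                )
            )
            t += draw_period()
        rng_noise = np.random.default_rng(child.spawn(1)[0])
        y = _render_events(events, sweep_params, sweep_duration, rng_noise)
        traces.append(Trace(y, params.sampling_rate, channel=f"sweep{i:03d}"))
        labels.extend(events)
    return traces, labels


# ---------------------------------------------------------------------------
# ROI calcium traces


def generate_roi_traces(
    n_roi: int,
    sampling_rate: float = 5.0,
    duration: float = 1200.0,
    frac_rhythmic: float = 0.13,
    rhythm_period: float = 10.0,
    drug_onset: float | None = None,
    drug_gain: float = 1.0,
    seed: int = 0,
    event_rate: float = 0.05,
    transient_rise: float = 0.5,
    transient_decay: float = 3.0,
    amp_mean: float = 1.0,
    amp_cv: float = 0.3,
    noise_sd: float = 0.1,
    period_jitter_cv: float = 0.05,
    drift_amp: float = 0.15,
):
    """ROI fluorescence matrix with rhythmic/arrhythmic units and a drug epoch.

    Each ROI is a slow sinusoidal baseline drift plus calcium transients
    (ramp rise ``transient_rise`` s, exponential decay ``transient_decay``
    s) occurring either as a Poisson process at ``event_rate`` Hz
    (arrhythmic) or every ``rhythm_period`` s with Gaussian jitter
    (rhythmic), plus white noise.  After ``drug_onset`` the transient
    amplitudes are scaled by ``drug_gain``, emulating a bath-applied
    modulator that raises calcium activity.

    Returns ``(ROIMatrix, truth)`` where ``truth`` is a DataFrame with one
    row per ROI: ``roi_id``, ``rhythmic`` flag and the sign of the true
    activity change (``0`` when ``drug_gain == 1`` or no drug epoch).
    """
    from .calcium import ROIMatrix

    if not 0 <= frac_rhythmic <= 1:
        raise ValueError("frac_rhythmic must be in [0, 1]")
    if drug_onset is not None and not 0 <= drug_onset < duration:
        raise ValueError("drug_onset must fall inside the recording")
    ss = np.random.SeedSequence(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    shape_a = 1.0 / max(amp_cv, 1e-9) ** 2
    cols = {}
    rows = []
    for j, child in enumerate(ss.spawn(n_roi)):
        rng = np.random.default_rng(child)
        rhythmic = rng.random() < frac_rhythmic
        # event times
        times = []
        if rhythmic:
            tt = rng.uniform(0, rhythm_period)
            while tt < duration:
                times.append(tt)
                tt += rhythm_period * max(0.1, 1.0 + rng.normal(0, period_jitter_cv))
        else:
            tt = rng.exponential(1.0 / event_rate)
            while tt < duration:
                times.append(tt)
                tt += rng.exponential(1.0 / event_rate)
        y = np.zeros(n)
        for tt in times:
            amp = rng.gamma(shape_a, amp_mean / shape_a)
            if drug_onset is not None and tt >= drug_onset:
                amp *= drug_gain
            _add_ramp_decay(y, sampling_rate, tt, amp, transient_rise, transient_decay)
        y += drift_amp * np.sin(2 * np.pi * t / 200.0 + rng.uniform(0, 2 * np.pi))
        y += rng.normal(0, noise_sd, size=n)
        roi_id = f"roi{j:04d}"
        cols[roi_id] = y
        change = 0 if (drug_onset is None or drug_gain == 1.0) else int(np.sign(drug_gain - 1.0))
        rows.append({"roi_id": roi_id, "rhythmic": rhythmic, "change_sign": change})
    rng_xy = np.random.default_rng(ss.spawn(1)[0])
    xy = pd.DataFrame(
        rng_xy.uniform(0, 580, size=(n_roi, 2)), columns=["x_um", "y_um"], index=list(cols)
    )
    data = pd.DataFrame(cols, index=pd.Index(t, name="time_s"))
    return ROIMatrix(data=data, sampling_rate=sampling_rate, roi_xy=xy), pd.DataFrame(rows)
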
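# Methods

This note documents the models, rules and numerical conventions the
package implements, the design choices made where several readings were
defensible, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Signals and conventions

All operations act on uniformly sampled single-channel traces (integrated
preBötC population activity or rectified+integrated diaphragm EMG) in
arbitrary amplitude units.  Times are seconds from the trace origin,
sample indexing is 0-based, and windows are half-open `[start, end)`.
Tables are tab-delimited text with a fixed `%.10g` float format so
deterministic stages reproduce byte-identically.

## Burst detection

* **Threshold.** A burst is a local maximum whose topographic prominence
  exceeds `prominence_factor` (default 2.5) times the standard deviation
  of the *whole* trace — the literal, simplest reproducible reading of an
  "SD of the integrated activity" rule.  Consequence worth knowing: any
  aberrantly large event in the trace (e.g. a 90× artifact spike) inflates
  that SD and can temporarily raise the bar above genuine bursts.  The
  artifact *rejection* rules below are unaffected, but detection
  sensitivity on artifact-laden desk-scale traces degrades; the
  sensitivity guarantees quoted by the test suite are measured on
  artifact-free traces.
* **Refractory merge.** Peaks closer than 200 ms are merged keeping the
  larger, suppressing double detections on noisy peaks (config-exposed).
* **Local baseline.** Peak height is measured above the median of the
  segment between the previous peak and the current one, trimmed by ~1 s
  on each side so burst flanks do not contaminate it; `baseline_mode=
  "absolute"` (baseline 0) is available for recordings with a known zero
  line.
* **Onset.** The latest time the trace reaches 20% of the peak height
  above the local baseline, walking back from the peak; an instantaneous
  rise yields one sample before the peak, and an onset that never crosses
  is clamped to the search start and flagged.  `onset_smooth` optionally
  locates the crossing on a moving-averaged copy (peak height still read
  from the raw trace, raw fallback if the smoothed copy never crosses) for
  traces whose broadband noise rivals the 20% level.
* **Artifacts.** A burst is discarded as noise when its amplitude exceeds
  75× the mean amplitude of all detected bursts, or its onset-to-peak time
  is under 150 ms.  Flagged bursts are retained with `artifact=True` for
  audit.  The `~>75×` cutoff is implemented as an exact configurable
  threshold.
* **Shape.** A fixed-length vector over `[onset, onset + 1.5 s)`,
  zero-padded (and flagged) past the trace end.

## Burst features and shape classes

Amplitude (peak above local baseline), duration (onset-level crossing to
the symmetric return crossing after the peak — the 20% level reused, since
the literature does not define burst duration operationally), FWHM (linear
interpolated half-height crossings), trapezoidal area above baseline over
the duration, post-burst interval (burst end → next onset) and inter-event
interval (onset → next onset).  The last burst's intervals are missing,
never zero.  A sigh shape is **biphasic** when the shape vector contains
two local maxima, each ≥ 20% of the global peak, separated by a trough
≥ 20% below the smaller of the two — evaluated over *all* pairs of
qualifying maxima, since measurement noise sprinkles minor local maxima
between the two genuine components.  The shape classifier is only applied
to bursts already identified as sighs; doublets of eupneic activity are
never auto-labeled sighs.  Epoch summaries report counts normalized to a
20-min window plus per-class mean features and the sigh:eupnea amplitude
ratio.

## Evoked sigh-attempt classifier

1. PCA on mean-centered spontaneous (non-evoked) burst shapes; keep the
   smallest number of leading components with cumulative explained
   variance ≥ 95%.  Scores are *not* whitened — the robust scatter absorbs
   scale.
2. Minimum covariance determinant on the scores: FAST-MCD with
   `h = ⌈0.75 n⌉`, 500 seeded elemental starts, concentration steps to
   convergence, the Croux–Haesbroeck consistency correction, and the
   standard 97.5% chi-square reweighting finish (raw MCD location alone is
   too inefficient; the reported `support` remains the raw
   minimal-determinant subset so it can be verified against exhaustive
   search on small problems).  `support_fraction = 1` returns the
   classical estimates exactly.
3. Mahalanobis distance of every burst to the robust eupnea location;
   threshold `median + 4 × IQR` of the spontaneous distances, with
   quartiles by linear interpolation between order statistics
   (the threshold is convention-sensitive; this one gives exactly 11 for
   distances {1,2,3,4,100}).
4. A second, identical gate on (amplitude, FWHM, post-burst interval).
   A burst missing its post-burst interval (last of a sweep) is returned
   `unclassified` rather than imputed.
5. Final criterion: a sigh attempt must also exceed the 90th percentile of
   spontaneous amplitudes.

Because z-scores of distance are self-referential (the threshold derives
from the same spontaneous distances), the whole classifier is invariant to
uniform amplitude rescaling of the recording; this is covered by tests.
The priors should be fit on activity that genuinely represents eupnea —
the benchmark fits them on a sigh-free spontaneous segment.

## In vivo MAD rule

For each burst of the integrated EMG, the up-to-20 bursts before and after
(excluding itself, minimum 5 at the edges, else default eupnea) supply a
median and MAD for amplitude and area.  A sigh requires strict exceedance
on *both*: `|value − median| > 6 × MAD`.  Raw values and MADs live on
different scales, so the deviation-from-median form is the default
reading; `mode="literal"` compares raw values to `6 × MAD` directly.  The
MAD carries no 1.4826 consistency factor unless configured.  Labels are
deterministic, scale-invariant, and unaffected by removing non-neighbor
bursts.

## Calcium pipeline

* z-score each ROI; smooth (10-sample centered moving average, truncated
  edges) only when the sampling rate exceeds 20 Hz, mirroring the
  restriction to resonance-mode acquisitions.
* Activity change: percent difference of the preprocessed signal SD
  between a 5-min baseline window and a 5-min post-drug window.
* Rhythmicity: sample autocorrelation (statsmodels, FFT) with per-lag
  Bartlett 95% confidence intervals, `max_lag` defaulting to a third of
  the trace.  An ROI is rhythmic when, scanning lags upward, the upper CI
  bound first drops below zero and the lower bound later crosses above
  zero; the reported lag maximizes the acf within that positive excursion.
  **Band choice:** the crossing rule scanned over ~100+ lags with a
  pointwise band fires on white noise with probability near one, so the
  detector rescales the band to a Šidák-adjusted simultaneous level across
  the scanned lags (`simultaneous=False` restores the pointwise band).
  This keeps the family-wise false-positive rate at ~α while retaining
  full power for genuine rhythms (measured: 0 false flags in 1000
  white-noise traces; power 1.0 with lag error < 10% for 10-s sinusoidal
  rhythms at SNR 2).  On *transient-train* rhythms whose kernel decay
  (~3 s) is wide relative to the half-period, the trough is shallow and
  the rule is conservative (~0.7 power at the generator's defaults) — a
  rhythmic-fraction estimate from it is a lower bound.
* Sigh-triggered tests: per window size w ∈ {1, 2, 5, 10} s, a two-sided
  paired t-test across sighs of the mean signal in `[t − w, t)` vs
  `[t, t + w)` (the onset sample belongs to post).  Sighs whose windows
  leave the trace are dropped with a warning; fewer than 3 usable sighs
  yields no result; an all-constant difference is flagged degenerate.
  Bonferroni `m` defaults to #ROIs × #windows in the batch runner
  (config-exposed: windows only, ROIs only, or both).

## Synthetic data

The generator plants events with exact onset/peak labels and renders them
with a linear-ramp rise (0.4 × the nominal burst duration, i.e. 0.4 s for
the 1-s default) followed by an exponential decay (τ = 0.3 × duration).
The ramp makes the 20% onset exact in closed form, keeps genuine rise
times (~0.32 s) safely above the 150-ms artifact cutoff, and leaves a
slope discontinuity at the peak so planted peak times survive noise.
Sighs scale amplitude by 2.5× and both time constants by 1.5×; the burst
after a sigh is delayed by the post-sigh apnea factor (2× in vitro).  A
biphasic sigh (probability 0.785 by default — a documented default, not a
constant) is a eupnea-scale component whose decay meets the large
component's ramp 0.4 decay-constants past the small peak, putting the
inter-peak trough at e⁻⁰·⁴ ≈ 67% of the small peak: deep enough for the
two-peak rule, shallow enough that the 20% onset walks back through it to
the foot of the small component.  EMG defaults make sighs 3× in amplitude
and 2× in duration (area ratio ~6×), the regime where amplitude and area
are the discriminating features.  Eupneic periods and amplitudes are
gamma-distributed (defaults: 4 s, CV 0.15; amplitude 1 a.u., CV 0.1 —
plausible order-of-magnitude choices for control slices, exposed in
config).  Artifacts are single-sample spikes of 80–100× the mean eupneic
amplitude (fast-rising by construction).  `noise_sd` is the SD of additive
white noise *before* a 50-ms moving-average that emulates the upstream
integration of raw recordings; benchmark SNR = eupneic amplitude /
`noise_sd`.  ROI traces are transient trains (ramp 0.5 s, decay 3 s,
rate 0.05 Hz arrhythmic or a jittered 10-s period when rhythmic) on a slow
sinusoidal drift; a drug epoch scales transient amplitudes by
`drug_gain`.

One integer seed drives a `SeedSequence`; children are spawned in the
documented order (event schedule, artifacts, noise; per-sweep and per-ROI
children for those generators), so outputs are bit-reproducible and
disabling noise does not move the planted events.

**What the synthetic tests do not show.** The generator's bursts are
stereotyped kernels with stationary statistics; real recordings carry
slow drift, amplitude run-down, burstlets, irregular rhythms and
non-Gaussian noise.  Passing recovery benchmarks here demonstrates the
rules are implemented correctly and behave as designed under their own
assumptions — not that those thresholds (2.5 × SD, 6 × MAD, 4 × IQR) are
optimal for any particular rig.

## Problem sizes

The validation suite and `scripts/acceptance.py` use 10 seeds × ~220-s
traces (≈ 520 planted bursts) for detection, 100 × 60-s traces for
artifact rejection, 10 seeds × 25 sweeps (≈ 200 evoked bursts) for the
classifier, 10 × 600-s EMG traces (≈ 47 sighs) for the MAD rule, 1000
white-noise and 100 sinusoid traces for the rhythmicity rule, and 500 null
ROIs for the sigh-triggered statistics — sizes at which the binomial error
of the reported rates is a few percent and a full run takes seconds to
minutes on one core.

## Known limitations

* Whole-trace SD detection is not robust to extreme artifacts (above).
* The 90th-percentile amplitude criterion presumes the spontaneous pool is
  overwhelmingly eupneic; a spontaneous pool rich in sighs would raise the
  cut.
* The MAD rule needs ≥ ~5 neighbors; the first and last few bursts of a
  short recording default to eupnea.
* The rhythmicity rule is a detector, not a spectral estimator: its lag is
  the acf-maximizing lag of one excursion and can sit on a harmonic for
  strongly non-sinusoidal rhythms.
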
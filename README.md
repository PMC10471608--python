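# sighsort

Analysis of sigh and eupnea rhythms in preBötzinger-complex (preBötC)
recordings: burst detection and characterization on integrated population
or diaphragm-EMG traces, an unsupervised classifier separating
optogenetically evoked "sigh attempts" from eupneic bursts, a rolling
robust-outlier sigh rule for in vivo EMG, and an ROI calcium-fluorescence
pipeline (z-scoring, drug-epoch activity change, rhythmicity detection,
sigh-triggered statistics).

The package is aimed at respiratory neurophysiologists working with slice
or anesthetized-preparation recordings in which a fast eupneic burst
rhythm (period ~4 s in vitro) carries a much slower, larger-amplitude sigh
rhythm.  Because sighs vary in shape (biphasic: a eupneic burst merged
into a larger one; monophasic: a single large burst) and not every large
burst is a sigh, ad hoc labeling is error-prone; every rule here is
explicit, deterministic, and testable.  A synthetic-data generator with
exact ground-truth labels stands in for real recordings throughout the
test suite.

## Methods at a glance

**Burst detection.** Peaks in the integrated trace with topographic
prominence > 2.5 × SD(trace).  Onset = the latest time the trace reaches
20% of the peak height above a local baseline.  Bursts that are aberrantly
large (> 75 × mean burst amplitude) or very fast rising (peak in < 150 ms)
are discarded as noise.  Shapes are extracted over [onset, onset + 1.5 s].

**Evoked sigh-attempt classification.** Spontaneous (non-evoked) burst
shapes are decomposed by PCA; the first *n* components explaining ≥ 95% of
the variance feed a minimum-covariance-determinant (MCD) estimator, giving
a robust location μ and scatter Σ of "expected eupnea".  Each burst's
Mahalanobis distance is

&nbsp;&nbsp;&nbsp;&nbsp;D = √((x − μ)ᵀ Σ⁻¹ (x − μ)),&nbsp;&nbsp;
D_thresh = median(D_spont) + 4 · IQR(D_spont).

An evoked burst is a **sigh attempt** iff it is an outlier
(D > D_thresh) in *both* the shape-space gate and an identical gate fit on
the intuitive features (amplitude, FWHM, post-burst interval), *and* its
amplitude exceeds the 90th percentile of the spontaneous bursts.

**In vivo sighs.** On rectified, integrated diaphragm EMG, a burst is a
sigh when both its amplitude and its area deviate from the median of the
20 bursts before and after it by more than 6 × the neighbors' median
absolute deviation (MAD).

**Calcium ROIs.** Signals are z-scored (F_z = (F − F̄)/σ_F; 10-sample
moving average for > 20 Hz acquisitions); drug responses are the percent
difference of the signal SD between 5-min baseline and post-drug windows;
an ROI is rhythmic when the autocorrelation's upper 95% CI bound first
drops below zero and the lower bound later crosses above zero; and
sigh-triggered changes are paired t-tests of the mean signal in windows of
1, 2, 5 and 10 s before vs after each sigh onset, Bonferroni-corrected.

## Worked example

```python
from sighsort import (SynthParams, generate_population_trace, detect_bursts,
                      reject_artifacts, features_table, label_sighs_simple,
                      summarize_epochs, classify_shape)

params = SynthParams(duration=600.0, seed=1)       # 10-min slice recording
trace, truth = generate_population_trace(params)

bursts = reject_artifacts(detect_bursts(trace), trace)
feats = features_table(bursts, trace)
feats["kind"] = label_sighs_simple(feats)

sighs = feats[feats["kind"] == "sigh"]
shapes = [classify_shape(b.shape, baseline=b.baseline)
          for b, k in zip(bursts, feats["kind"]) if k == "sigh"]
print(f"{len(feats)} bursts detected, {len(sighs)} labeled sighs "
      f"({shapes.count('biphasic')} biphasic / {shapes.count('monophasic')} monophasic)")
summary = summarize_epochs(feats, [("baseline", 0.0, 600.0)], window=1200.0)
print(summary[["epoch", "eupnea_per_window", "sigh_per_window",
               "sigh_eupnea_amp_ratio"]].to_string(index=False))
```

Output:

```
145 bursts detected, 6 labeled sighs (5 biphasic / 1 monophasic)
   epoch  eupnea_per_window  sigh_per_window  sigh_eupnea_amp_ratio
baseline              278.0             12.0               2.613743
```

The detector found all 145 planted bursts; six of the eight planted sighs
pass the conservative amplitude + post-burst-interval labeling heuristic.
The counts are normalized to events per 20-min window; the sigh:eupnea
amplitude ratio reflects the generator's planted 2.5× factor.

The same stages are available from the shell:

```bash
sighsort simulate population --seed 1 --out run/
sighsort features --trace run/trace.tsv --out run/bursts.tsv
sighsort classify-invivo --trace emg.tsv --out labels.tsv
sighsort calcium --roi roi.tsv --out ca/
sighsort run --seed 1 --out run/        # end-to-end with a JSON manifest
```

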
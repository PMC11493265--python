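# dpxdyn

Statistical analysis of preparatory vs adaptive cognitive control in
DPX / AX-CPT EEG experiments, with a fully seeded synthetic-data generator.

In the Dot Pattern Expectancy (DPX) task a cue (A or B) is followed 2.5 s
later by a probe (X or Y); a target response is required only for A→X pairs,
which make up ~70% of trials. Because the dominant pair creates a prepotent
target tendency, B cues allow full preparation of the response in advance
(preparatory / proactive control), while Y probes after an A cue force a
rapid adjustment (adaptive / reactive control). `dpxdyn` implements the
statistical machinery used to characterise these processes from epoched
multichannel EEG:

- **Two-level mass-univariate regression** (`dpxdyn.glm`): per subject, the
  GLM `Y = Xβ + ε` is solved at every channel × time sample via the
  Moore-Penrose pseudo-inverse (`β = X⁺Y`, SVD); condition-specific
  coefficient maps are then contrasted across subjects with a paired
  *t*-test, and family-wise error over all channel-time points is controlled
  with the bootstrap **F-max** procedure: condition maps are grand-mean
  centred (imposing H₀), whole subjects are resampled with replacement, the
  maximum F = t² over all points is stored per resample, and effects are
  significant where the observed F exceeds the (1 − α) quantile of the B
  stored maxima (defaults α = 0.01, B = 2000).
- **Temporal-generalisation decoding** (`dpxdyn.decoding`): a linear
  support-vector classifier per time sample (C = 1, class weights inversely
  proportional to class frequency, 5-fold stratified CV), scored at every
  other time sample with fold-averaged ROC-AUC, yielding the
  train-time × test-time (GAT) matrix; group significance by one-sample
  *t*-tests against chance (0.5) with Bonferroni correction.
- **Signal-detection behavioural indices** (`dpxdyn.behaviour`):
  `d'context = Z(AX correct) − Z(BX incorrect)` (reliance on cue
  information) and `A-cue bias = ½[Z(AX correct) + Z(AY incorrect)]`
  (the response bias induced by predictive A cues), with the 1/(2N) edge
  correction; RT exclusion (100–1000 ms), Cousineau-Morey within-subject
  confidence intervals, and whole-scalp moderation regression of contrast
  maps on behavioural scores.
- **Synthetic datasets with ground truth** (`dpxdyn.simulate`): the exact
  trial mix (blocks of 129 pairs at 90/13/13/13), evoked condition effects
  (transient occipital-parietal, sustained parietal, late fronto-central),
  spatially correlated band-limited 1/f noise, and lognormal RT / Bernoulli
  error behaviour — all reproducible bitwise from a single seed, with masks
  marking where every effect was injected.

## Worked example

```python
from dpxdyn import (make_dataset, select_window, condition_beta_stacks,
                    group_contrast, filter_rt, sdt_scores, paired_t_sample_size)
from dpxdyn.glm import cluster_summary
import pandas as pd

print("subjects needed (paired t, d=0.5, power=0.80, alpha=0.01):",
      paired_t_sample_size(0.5, 0.80, 0.01))

subjects, truth = make_dataset(n_subjects=52, seed=42, sfreq=64.0)
scores = pd.DataFrame(
    [sdt_scores(filter_rt(s.trials), s.subject_id) for s in subjects]
)
print(f"mean d'context: {scores['dprime_context'].mean():.2f}  "
      f"mean A-cue bias: {scores['a_cue_bias'].mean():.2f}")

cue_epochs = [select_window(s, -0.5, 2.5) for s in subjects]
b_maps, a_maps = condition_beta_stacks(cue_epochs, by="cue", levels=("B", "A"))
res = group_contrast(b_maps, a_maps, alpha=0.01, B=2000, seed=0, contrast="B-A")
print(f"F-max threshold: {res.f_crit:.1f}")
print(f"significant points: {int(res.mask.sum())} of {res.mask.size}")
clusters = cluster_summary(res, subjects[0].channels.labels,
                           cue_epochs[0].timeaxis.times)
peak = clusters.loc[clusters['peak_t'].abs().idxmax()]
print(f"largest effect: channel {peak['channel']}, "
      f"{peak['tmin']:.3f}-{peak['tmax']:.3f} s, peak t = {peak['peak_t']:.2f}")
```

prints

```
subjects needed (paired t, d=0.5, power=0.80, alpha=0.01): 51
mean d'context: 3.85  mean A-cue bias: 0.56
F-max threshold: 31.2
significant points: 393 of 6176
largest effect: channel Pz, 0.422-0.734 s, peak t = 13.66
```

Reading the output: a medium effect (d = 0.5) needs ~50 subjects at the
conservative α = 0.01; the generated cohort relies strongly on cue
information (d'context ≈ 3.9) with a modest A-cue bias; and the B-vs-A cue
contrast survives family-wise correction exactly where the generator placed
the sustained parietal positivity — peaking at Pz inside 0.40–0.75 s — while
97% of the 32 × 193 channel-time points stay below threshold.

The same analysis runs end to end from a YAML config via the CLI:

```sh
dpxdyn all --config cfg.yaml --out results/ --seed 42
```

where `cfg.yaml` can be as small as `seed: 42`. Stages
(`simulate | behaviour | massuni | decode | report | all`) write HDF5 maps,
CSV summaries and a markdown report into the output directory.

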
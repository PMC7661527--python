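# seesaw

Resting-state fMRI analysis of the "seesaw" between the default-mode network
(DMN) and the task-positive network (TPN): per-frame dominance of one network
over the other, how long each dominance state persists, how often the brain
switches, and how those dynamics relate to self-reported anxiety and
depression and to right fronto-insular cortex (RFIC) BOLD variability.

## Who this is for

Researchers working with resting-state BOLD data who want a tested,
scriptable implementation of the dominance-dynamics analysis — from temporal
preprocessing of 4-D NIfTI volumes through network extraction to cohort-level
inference — plus a fully seeded synthetic-data generator that makes every
stage verifiable without real scans.

## The statistic at its core

For one subject, let `d(t)` and `p(t)` be the mean BOLD timeseries of the DMN
and the TPN after nuisance correction. Define the dominance indicator

```
I(t) = 1  if d(t) > p(t)   (DMN-dominant frame)
I(t) = 0  otherwise        (TPN-dominant frame; ties count as TPN)
```

From `I` the package derives, per subject:

- **dominance index** `Σ_t I(t)` — number of DMN-dominant frames;
- **state transitions** — number of frames where `I` changes, equivalently
  zero crossings of the difference series `D(t) = d(t) − p(t)`;
- **mean dwell time** — mean run length of each state before a switch
  (frames, and seconds = frames × TR);
- **AD confounds** — mean |d|, mean |p|, mean |D| (activation magnitude) and
  the DMN–TPN Pearson anticorrelation.

Cohort-level inference then runs partial correlations of mean DMN dwell time
with anxiety (SAS) and depression (SDS) scores controlling age and gender
(df = n − 2 − k, Bonferroni over the two-test family), sensitivity models
adding the AD confounds, comorbidity-partialled models, a rank-based
extreme-group 2 × 2 ANOVA, and a permutation max-|r| small-volume test of the
association between transition count (or dwell time) and voxelwise BOLD SD
inside an RFIC box mask (MNI 27 ≤ x ≤ 48, 0 ≤ y ≤ 28, −19 ≤ z ≤ 15).

## Worked example

```python
import seesaw
from seesaw.simulate import GeneratorConfig, simulate_cohort

cfg = GeneratorConfig(n_subjects=287, behavior_coupling=0.3, seed=42)
cohort, pairs, truth = simulate_cohort(cfg)
results = seesaw.BrainBehaviorModel(cohort.to_dataframe()).fit()
print(results.summary())
```

prints

```
Brain-behavior association results
==================================================
metric: mean_dwell_dmn    n = 287

Headline partial correlations (age, gender; Bonferroni m=2):
  anxiety     r(283) = +0.432, p = 2.356e-14, p_adj = 4.712e-14
  depression  r(283) = +0.308, p = 1.167e-07, p_adj = 2.334e-07
Activation-magnitude controlled (AD + anticorr covariates):
  anxiety     r(279) = +0.431, p = 3.602e-14
  depression  r(279) = +0.305, p = 1.776e-07
Comorbidity (SAS vs SDS): r(285) = +0.551, p = 3.72e-24
Comorbidity-partialled models:
  anxiety_ctrl_depression    r(278) = +0.332, p = 1.281e-08
  depression_ctrl_anxiety    r(278) = +0.092, p = 0.1247
Extreme-group 2x2 ANOVA on the metric:
  A    F(1,128) = 27.59, p = 6.063e-07
  B    F(1,128) = 6.25, p = 0.01372
  A:B  F(1,128) = 0.03, p = 0.8644
```

Read: the partial correlation of mean DMN dwell time with anxiety in this
287-subject synthetic cohort is r(283) = 0.43 (283 = 287 − 2 − 2 degrees of
freedom for the two covariates; one seeded draw scatters around the planted
coupling), surviving the family-of-two Bonferroni correction. Controlling
for depression leaves the anxiety association intact while controlling for
anxiety removes the depression one — exactly the dissociation the generator
planted, since depression relates to dwell only through its 0.60 correlation
with anxiety. The extreme-group ANOVA error df is 128 (132 subjects, 4
cells, no covariates).

The full imaging pipeline (temporal preprocessing → network masks → dominance
→ behavior and RFIC stages, in both the global-signal-regression and no-GSR
streams) runs from a single YAML config:

```bash
seesaw run --config run.yaml
seesaw report --manifest seesaw_run/manifest.json
```

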
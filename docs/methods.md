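# Methods

## Analysis model

The package treats resting-state brain activity as alternating between two
macro-states: DMN dominance (the default-mode network's mean BOLD signal
exceeds the task-positive network's) and TPN dominance. The per-frame
dominance indicator is a deterministic function of the two network mean
timeseries; all dynamics statistics (dominance index, transition count, mean
dwell times) are functions of that binary sequence. No latent-state
estimation is performed on real data — the indicator *is* the state. The
cohort-level question is whether between-subject variation in these dynamics
covaries with self-reported anxiety/depression and with RFIC BOLD
variability.

### Temporal preprocessing (`seesaw.prep`)

Pipeline order is discard → linear detrend → band-pass → nuisance
regression. The literature this analysis descends from lists filtering
before nuisance regression but is not explicit about the order; the default
follows that listing and the order is configurable. Details:

- **Frame discard**: default 10 frames (magnetisation equilibration), so a
  242-volume session yields 232 analysed frames.
- **Band-pass**: an ideal frequency-domain boxcar on the DFT, band edges
  0.01–0.08 Hz inclusive, the 0-Hz mean removed. This is the REST-toolkit
  style filter; it is idempotent and exactly testable on bin-aligned
  sinusoids, unlike IIR designs.
- **Nuisance regression**: OLS residual on [intercept, confounds]. Confounds
  are used as given (no orthogonalisation among them); an intercept is always
  included, so any constant padding elsewhere is absorbed. The global-mean
  column is toggled off for the no-GSR stream. Rank deficiency is an error
  that names the collinear columns.
- **Friston-24**: column order R(t), R(t−1), R(t)², R(t−1)², lags zero-padded
  at the first frame (the common SPM/DPARSF convention; the padding constant
  is absorbed by the intercept).
- WM/CSF masks are supplied by the user (or the synthetic generator); no
  tissue segmentation is implemented. Gaussian smoothing (σ = FWHM/(2√(2 ln 2)),
  isotropic voxels only) is provided as an optional utility; the temporal
  pipeline never calls it.

### Network identification (`seesaw.networks`)

Two routes, matching the two analysis streams:

- **Seed-derived (GSR stream)**: combined mPFC + PCC seed (6-mm spheres,
  sphere rule = voxel centre within radius, boundary inclusive), reference =
  mean of per-seed means (ROI-wise, not pooled-voxel). Per-subject Pearson
  maps are Fisher z-transformed (|r| = 1 clamped at 1 − 1e−7), then a group
  one-sample t-test per voxel (two-sided p compared to 1e−6, the sign of t
  assigning DMN vs TPN), followed by a cluster-extent threshold of 20 voxels
  (inclusive) using 26-connectivity (configurable to 6/18). Two-sidedness and
  connectivity are defaults chosen to match standard SPM-family practice.
- **Predefined ROIs (no-GSR stream)**: twelve literature 6-mm spheres (six
  per network); each network's timeseries is the mean of per-ROI means.

### Dominance dynamics (`seesaw.dynamics`)

- Ties (DMN = TPN exactly) are assigned to TPN per the strict "greater than"
  rule; transitions are defined on the indicator, which makes
  indicator-change counting and zero-crossing counting of the difference
  series consistent by construction.
- Mean dwell time includes the censored first and last runs by default
  (simplest faithful reading of "mean lifetime"); `include_censored=False`
  enables a sensitivity analysis. A state that never occurs yields a flagged
  NaN, not an exception. Dwell is reported in frames, with seconds =
  frames × TR alongside.
- RFIC analysis: per-voxel temporal SD (n−1 denominator), then across-subject
  Pearson (partial if covariates are given) correlation of a dynamics metric
  with voxel SD inside the RFIC box mask. Family-wise error within the mask
  is controlled by a seeded max-|r| permutation test (default 5000
  permutations; corrected p = (1 + #{null ≥ observed})/(n_perm + 1)), a
  distribution-free stand-in for parametric random-field small-volume
  correction that is exactly reproducible. Because the source analyses name
  *transition count* in one place and *dwell time* in another, the metric is
  configurable and the pipeline runs both by default, privileging neither.

### Behavioral inference (`seesaw.inference`, `seesaw.model`)

- Partial correlation residualises both variables on [intercept, covariates];
  df = n − 2 − k exactly, p two-sided from the t distribution.
- Raw SAS/SDS sums (20 four-point items, reverse-keyed items scored
  5 − response) are used, not ×1.25 index scores; reverse-key sets are
  configurable since item keys vary by translation. Gender enters covariate
  models as a 0/1 indicator.
- Extreme groups: subjects ranked ascending on each scale (average ranks for
  ties, boundary ties broken by id). Draw order HH → LL → LH → HL without
  replacement; LH maximises rank(SAS) − rank(SDS) and HL is defined
  symmetrically (the only non-arbitrary completion, since no explicit HL rule
  exists in the source analyses). The 2 × 2 ANOVA is type III with
  sum-to-zero contrasts via statsmodels OLS; the default model omits
  age/gender covariates because the reported error df (128 for 132 subjects)
  is only consistent with the covariate-free model, and a flag adds them
  (error df 126).
- The comorbidity-partialled models keep the activation-magnitude (AD)
  confounds when available, giving 7 covariates in total — this matches the
  reported df of 278 at n = 287.
- Bonferroni is applied to the family of two headline tests (dwell vs SAS,
  dwell vs SDS): p_adj = min(1, 2p).

## Synthetic data (`seesaw.simulate`)

The generator emulates the statistical structure the analysis assumes, not
raw fMRI physics:

- **Latent process**: two-state first-order Markov chain, initial state
  Bernoulli(0.5), stay probabilities default 0.9 per state (mean geometric
  dwell 10 frames, a realistic mid-range for 0.01–0.08 Hz-band dynamics at
  TR = 2 s). A fixed-dwell (semi-Markov) mode stress-tests dwell estimation.
- **Timeseries**: dmn = +a·s̃ + ε₁, tpn = −a·s̃ + ε₂ with s̃ ∈ {±1},
  amplitude a = 1, and independent AR(1)+white noise (total SD 0.3 split
  evenly between the AR(1) and white components, AR coefficient 0.3).
- **Cohort**: 287 subjects × 232 frames at TR = 2 s by default. Anxiety =
  ρ·z(dwell) + √(1−ρ²)·noise with planted ρ = 0.3; depression correlates
  0.60 with the anxiety latent (the observed comorbidity), so its dwell
  correlation arises only through anxiety — the dissociation the partialled
  models should recover. Scores are affinely mapped to means/SDs of 34/6.7
  (SAS) and 31/6.0 (SDS) — the reported cohort values — clipped to the 20–80
  scale range and rounded; this discretisation slightly attenuates realized
  correlations, which the recovery tolerances absorb.
- **Volumes**: 24 × 24 × 18 voxels at 3 mm (the grid covers the RFIC box but
  not whole-brain MNI); disjoint spherical DMN, TPN, RFIC, WM and CSF blobs;
  the RFIC blob is white noise with SD = 0.5 + 0.02 × (subject's transition
  count); background noise SD 0.2. Motion files are small-amplitude Gaussian
  rp-style text.

What the generator does **not** emulate: hemodynamic response convolution,
physiological (cardiac/respiratory) noise, scanner drift beyond a linear
trend, spatial autocorrelation, registration error, or realistic anatomy.
Passing recovery tests therefore shows the *estimators* are correct and
calibrated under the assumed data model, not that the scientific conclusions
transfer to any real cohort.

## Numerical choices

- All regressions via `numpy.linalg.lstsq`; orthogonality of residuals to
  confounds holds to |r| < 1e−8 in tests.
- Fisher z clamps |r| ≥ 1 to 1 − 1e−7 so degenerate synthetic voxels stay
  finite.
- Sphere and box masks are inclusive at the boundary with a 1e−9 tolerance
  against floating-point coordinate jitter.
- Every stochastic routine takes an explicit seed; generator outputs are pure
  functions of (config, seed) via `numpy` `SeedSequence` spawning.

## Problem sizes used by the acceptance checks

Chosen to give stable statistics at interactive runtimes on one CPU: null
calibration uses 2000 white-noise subjects; dwell recovery 500 chains;
planted-correlation recovery one cohort of 5000; type-I calibration 2000
cohorts of 287; the planted RFIC effect 100 volumetric subjects with 1000
permutations, and its null control 20 repeats of 40 subjects with 500
permutations (the null property is independent of cohort size).

## Known limitations

- The pipeline's full-volume route is exercised end to end on synthetic
  grids; real-data runs assume spatially preprocessed, MNI-normalised input
  (slice timing, realignment and normalisation are out of scope).
- The predefined-ROI route requires grids that actually contain the
  literature coordinates; the synthetic pipeline substitutes planted-blob
  ROIs for its small grid.
- Cluster-extent thresholding operates on binary maps only; no
  cluster-level p-values are computed beyond the extent rule.
- The permutation small-volume correction is exact only under
  exchangeability of subjects; covariates are handled by residualising
  before permuting, an approximation standard for this design.
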
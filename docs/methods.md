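# Methods

This note documents the statistical model behind `pisckit`, the
generative model used for validation, the numerical choices, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The pISC model

The unit of analysis is a scene-level spatial pattern: a voxel vector per
subject, ROI and scene. At encoding this is the temporal mean of the run
z-scored BOLD series within the scene window; at recall it is the
least-squares-separate (LSS) beta of the scene's verbal-recall event.
Given a target subject pattern `x_s` and a reference group, the pISC for
scene `s` is the Pearson correlation between `x_s` and the reference
group's average pattern for `s`, computed leave-one-out whenever the
subject belongs to the reference group so that every comparison is across
subjects. Correlations are Fisher-z transformed *per scene*, then
averaged across the analysed scenes; the fixed averaging order is
r → z → mean-over-scenes → difference-of-references. The z transform is
variance-stabilizing and makes scene averages and group differences well
behaved near |r| → 1.

Directed contrasts are per-subject differences `z_A − z_B` between two
reference groups. The interaction index for a twist-group subject is the
encoding contrast minus the recall contrast, both oriented as (no-twist
reference − spoiled reference); it is positive when the subject's recall
patterns sit closer to the spoiled group than their encoding patterns
did. Five analyses are packaged (`enc_enc`, `rec_rec`, `interaction`,
`enc_rec_a`, `enc_rec_b`); their predicted one-tailed directions are
described in `pisckit.model`.

### Inference

Per-ROI hypothesis tests are permutation-based with the `(1 + k)/(B + 1)`
p-value convention (no zero p is ever reported, and `p ≥ 1/(B+1)`):

- **Sign-flip test** for per-subject difference values: the null flips
  each subject's sign independently (`B = 1000` by default); an exact
  enumeration over all `2^n` patterns is available for `n ≤ 20`.
- **Group-label shuffle** for two-sample comparisons, preserving group
  sizes.
- **Scene-shuffle null** for scene specificity: scene labels inside the
  analysed subset are permuted within each subject (independently per
  subject by default; one shared permutation per group as an option) and
  the entire interaction pipeline is recomputed per iteration. This
  destroys event-level scene correspondence while preserving any
  scene-generic group structure, so only genuinely scene-specific effects
  survive it.
- **BH-FDR** across the ROI family (delegated to
  `statsmodels.stats.multitest`, cross-checked in the test suite against
  an independent step-up implementation).

When the `enc_rec_b` comparison's two encoding references differ in
effective size, the larger one is randomly subsampled to match
(`match_n`), and the drop is redrawn at every permutation iteration from
a seeded stream.

Two parametric control analyses are included. The univariate control is
a mixed 3 (group, between) × 2 (condition, within) ANOVA on subject-level
mean activations, computed from explicit sums of squares (split-plot
decomposition with the subject-within-group mean square as the
denominator for the group effect) so the analysis is self-contained and
directly testable. The reliability control computes leave-one-out
within-group pISC per group, phase and ROI and submits the values to an
omnibus OLS ANOVA (statsmodels `anova_lm`).

### A calibration caveat for the sign-flip test

The per-subject difference values share the two reference-group mean
patterns, so they are positively correlated across subjects; sign
flipping subjects independently treats them as exchangeable and therefore
slightly underestimates the null variance of their mean. On null
synthetic data at the study's group sizes this produces a mildly
anticonservative test (empirical rejection a point or two above the
nominal 5%; the acceptance suite measures it within [0.03, 0.07] over
2000 null datasets). The effect grows as patterns get cleaner (small
reference groups, high signal-to-noise) because the shared reference
noise then dominates the subject-specific variability. A global
(all-subjects-simultaneously) sign flip would be exact for the
reference-exchange null but tests a different hypothesis; the per-subject
flip is retained as the field-standard procedure, with this caveat.

## The generative model

The synthetic generator exists so that every analysis has an input with
known ground truth. Each ROI has a latent basis of unit-norm, zero-mean
voxel components: one shared pattern per scene, Doctor/Ghost
interpretation patterns that differ only on critical scenes, and a pair
of scene-generic interpretation vectors. A subject's pattern for scene
`s` with Ghost-weight `mix` is

```
a_scene · scene_s + a_interp · [(1−mix)·D_s + mix·G_s]
           + a_generic · [(1−mix)·g_D + mix·g_G] + N(0, sigma_noise²)
```

Encoding uses `mix = 0` for the twist and no-twist groups and `mix = 1`
for spoiled; recall uses `mix = 1` for spoiled, `0` for no-twist, and a
per-twist-subject update fraction drawn from a Beta distribution centred
on `update_fraction` (concentration `update_concentration`; the endpoints
0 and 1 are degenerate and yield a constant). Interpretation amplitudes
are expressed only in `planted_rois`, so signal-free control ROIs coexist
with planted ones in a single dataset. Components are demeaned across
voxels before normalization so they carry no univariate signal — the
univariate control ANOVA is calibrated by construction, as in the data
the analysis is designed for.

Defaults are the study conditions: groups of 18/19/20 subjects
(spoiled/twist/no-twist), 18 scenes of which 7 are critical, TR 1.5 s,
scene durations averaging ~2 minutes. `sigma_noise = 2.0` against
`a_scene = 1.0` puts the pairwise same-scene intersubject pattern
correlation near 0.2 (leave-one-out reliability ~0.4), the range
scene-level naturalistic fMRI patterns actually show, and makes contrast
magnitudes of order 0.01–0.1 — the realistic regime. `a_interp = 1.0`
(half the noise SD) and `update_fraction = 0.7` encode moderate, partial
updating; strong-effect validation conditions set `a_interp = sigma_noise`
and `update_fraction = 1`.

Behavioral twist scores are generated per rater on the 1–5 scale:
`1 + 4·level + N(0, rater_sd)`, clipped to the scale, where a twist
subject's level on critical scenes is a coupled version of their update
fraction — a Gaussian mixture `rho·z_u + sqrt(1−rho²)·eps` on the
standardized updates, rescaled and clipped to [0, 1] — so that
`corr(update, score) ≈ behavior_coupling`. With noiseless raters a purely
Doctor recall scores exactly 1 and a purely Ghost recall exactly 5.
Recall misses are i.i.d. with `recall_miss_prob` and propagate as masked
scenes, never as zeros.

The recall-run simulator produces BOLD series as HRF-convolved event
boxcars whose per-voxel amplitudes are the scene's noiseless pattern,
plus cue epochs with a higher shared mean intensity (emulating the
audiovisual/verbal intensity difference that motivates LSS) and white
noise. The HRF is a canonical double gamma (positive lobe peaking near
5 s, undershoot near 15 s at ratio 1/6, zero at t = 0, peak-normalized),
evaluated on a 16× oversampled grid before downsampling to the TR.

What the generator does **not** emulate: spatial autocorrelation and
haemodynamic noise structure, head motion, physiological confounds,
between-ROI correlations, rater idiosyncrasies beyond i.i.d. noise, and
any preprocessing residue. Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under the stated
generative assumptions, not robustness to real-data artifacts.

## Numerical and design choices

- **Correlation clamp.** Correlations are clamped to `±(1 − 1e-7)` before
  `arctanh`, so noiseless data (r = 1 exactly) keeps a finite z.
- **Z-scoring** uses the population (1/N) SD by default (`ddof`
  configurable); constant voxels raise with the voxel index named, where
  "constant" tolerates float-rounding residue relative to the data scale.
- **TR-to-scene assignment** is half-open `[onset, offset)` on TR start
  times, a partition with no double counting; `lag_tr` (default 0) shifts
  windows for haemodynamic delay — a common lag cancels in group
  contrasts, so 0 is a safe default.
- **LSS nuisance structure**: target event + pooled other events + pooled
  cues + intercept by default; `lss_other="separate"` keeps one column
  per remaining event, which spans the true signal exactly and is used
  for exact-recovery validation. Rank deficiency raises with the design
  named.
- **Zero-variance patterns** in a correlation are skipped with a logged
  warning; a subject with no usable scene raises.
- **Degenerate statistics** are reported, not propagated: a paired
  t-test on a zero-variance difference is flagged
  (`zero-variance difference`), flat twist-score vectors yield NaN
  correlations, an all-zero sign-flip input returns p = 1 with a warning.
- **Seeding.** Every subject draws from an independent `SeedSequence`
  substream of the master seed (keyed by group, subject, phase), so
  changing one group's size never reshuffles other subjects' data;
  model fitting derives per-analysis, per-ROI permutation seeds the same
  way. Fixed spec ⇒ bit-identical datasets.

## Monte-Carlo problem sizes

Validation suites simulate full cohorts at the study's group sizes with
40–60 voxels per ROI and 1–2 ROIs — large enough that every contrast has
its predicted sign structure and small enough that hundreds of cohorts
run in minutes. The acceptance script uses 300 null cohorts for
calibration, 150 for power/sign structure, 60 per condition for the
scene-shuffle discrimination, 100 draws for LSS bias and per coupling
level; the test suite uses 2000 null cohorts for the type-I estimate
(Monte-Carlo se ≈ 0.005), 200 cohorts for power and coupling recovery,
and 100 per condition for the scene-shuffle discrimination.

## Limitations

- ROI-level analysis only: no voxelwise/searchlight inference, no
  cluster correction, no time-point ISC.
- The sign-flip anticonservativeness described above is a property of the
  procedure, inherited by design.
- The LSS pooled-nuisance variant is an approximation whenever event
  regressors overlap; the separate variant is exact but uses more
  degrees of freedom.
- Real-data ingestion (NIfTI + parcellation) assumes fully preprocessed,
  confound-regressed inputs; no motion, slice-timing or smoothing
  handling is provided.
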
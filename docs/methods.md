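# Methods

`icalink` implements a two-sided decomposition of a brain–behavior study:
independent *personality profiles* on the behavioral side, independent
*temporal functional modes* on the imaging side, and a family-aware
permutation test linking the two. This note describes the model, the
estimation choices, the synthetic-data generator used to validate the
chain, and the known limitations.

## The model

**Personality profiles.** The five NEO-FFI domain scores (neuroticism N,
extraversion E, openness O, agreeableness A, conscientiousness C; integer
scores 0–48) are treated as a noisy linear mixture of five statistically
independent latent traits: `x_i = A s_i + ε_i`, with `s_i` non-Gaussian.
Each factor column is z-scored (mean 0, sample SD 1 with denominator
n−1), and full-rank FastICA estimates the 5×5 unmixing `W`; each row of
the resulting weight matrix is a "personality profile" over the original
factors, and `ℓ_i = W z_i` gives subject *i*'s loading on each profile.
The training means/SDs travel with the profile set so held-out subjects
are projected through the *training* transform — this is what makes
single-subject leave-one-out projection well defined.

**Temporal modes.** Each subject contributes a timepoints × 12 matrix of
mean time series from 12 regions of interest (bilateral amygdala and
hippocampus, sgACC, mPFC, dACC, PCC, precuneus, dlPFC, insula, OFC).
Every region's series is z-scored within subject — without this,
between-subject amplitude differences dominate the group decomposition
and contaminate engagement with global scale — the standardized series
are concatenated along time, standardized once more at the group level,
and full-rank temporal ICA (time as samples, regions as channels) yields
12 spatial weight patterns, the temporal modes. Projecting a subject's
standardized series through the mode unmixing gives subject-specific mode
time series; on a training subject this reproduces that subject's rows of
the group source matrix to machine precision.

**Engagement.** A subject's engagement of mode *m* is the sample variance
(denominator n−1) of their mode-*m* time series over all their
timepoints: a non-negative scalar summarizing how strongly the
co-activation pattern is expressed. Variance is computed over the
subject's full concatenated series; per-run handling is the caller's
concern.

**Association.** Every profile–mode pair (5 × 12 = 60 cells) is tested
with the partial Pearson correlation after residualizing *both* the
loading and the engagement on an intercept plus covariates (typically a
gender indicator). Inference is by Freedman–Lane permutation: the outcome
is residualized on the covariates, residuals are permuted, the covariate
fit is re-added, and the statistic recomputed; the two-sided p-value uses
the add-one convention `p = (1 + #{|r*| ≥ |r|}) / (m + 1)`, so p is never
zero and its resolution floor is `1/(m+1)` for `m` sampled permutations.
Permutations respect family structure: members of a family may be
reordered within their block, and whole blocks may be exchanged only with
blocks of the same size — twins are never separated. If the total number
of such permutations is small enough they are enumerated exhaustively;
otherwise they are sampled uniformly from a seeded generator with the
identity always first. Benjamini–Hochberg FDR (via
`statsmodels.stats.multitest.multipletests`) is applied once across all
60 cells — the stricter global reading — and cells with adjusted p below
q = 0.05 are flagged.

## Estimation choices

* **FastICA**: parallel (symmetric) fixed-point updates with symmetric
  decorrelation `W ← (WWᵀ)^(−1/2) W` each iteration; logcosh contrast
  (a = 1) by default, `exp` and `cube` available. Whitening is by
  eigendecomposition of the sample covariance with a relative eigenvalue
  floor of 1e-10 used to detect numerically deficient input (a duplicated
  region, say, is rejected with the measured rank). Convergence when the
  maximal change in weight-vector alignment falls below `tol = 1e-6`
  (default), up to `max_iter = 1000` iterations; because the fixed point
  can oscillate just above a strict tolerance at small sample sizes, up
  to 5 differently-initialized attempts (all derived deterministically
  from the seed) are made and the first converged one kept.
  Non-convergence is never silent: the decomposition carries
  `converged=False`, a warning is emitted, and the resampling machinery
  excludes such folds with a count in its report.
* **Canonical form**: ICA is order- and sign-ambiguous, so every
  decomposition is normalized — components sorted by descending variance
  explained (squared mixing-column norm), each mixing column signed so
  its largest-magnitude entry is positive. Canonicalization is
  idempotent; repeated runs with one seed are bit-identical.
* **Component comparison**: two solutions are matched with the Hungarian
  algorithm maximizing summed absolute Pearson correlation between weight
  columns, signs chosen to make matched correlations non-negative. The
  Amari index of `P = A⁻¹B` (row- and column-normalized misassignment
  mass, scaled by `2k(k−1)` into [0, 1]) is zero iff the two mixings
  agree up to order/sign/scale.
* **Reproducibility machinery**: leave-one-out refits the decomposition
  (normalization included) with each subject removed and aligns every
  fold to the full-sample solution (not chained fold-to-fold, which
  drifts); split-half does the same over random halves that never split a
  family. The out-of-sample association learns both decompositions
  without the held-out subjects, aligns them to the full-sample
  reference so loadings are comparable across folds, projects the
  held-out subjects, and runs the association on purely out-of-sample
  pairs; grouped (leave-k-out) folds with families kept intact are
  available as a faster alternative to strict leave-one-out.

## The synthetic generator

The generator (`icalink.synthetic`) emulates a twin-cohort study with
known ground truth so every stage is testable by parameter recovery.
Defaults mirror the emulated cohort: 471 subjects, family composition
237 singletons / 71 MZ pairs / 46 DZ pairs, 58.8% female, 4800 timepoints
per subject, and NEO domain scores centered at the published cohort means
and SDs (N 16.4 ± 7.15, E 30.6 ± 6.12, O 28.1 ± 6.11, A 32.1 ± 4.89,
C 34.8 ± 5.73), rounded to integers and clipped to 0–48.

* Latent personality sources are centered unit-variance exponentials —
  strongly skewed, because ICA identifiability requires non-Gaussianity.
  MZ twins share latent sources with weight 0.8, DZ with 0.5
  (conventional heritability-flavored values), making the family-block
  permutation machinery consequential.
* Latent mode time series are i.i.d. Laplace by default (temporal ICA
  does not rely on autocorrelation, and i.i.d. keeps variance targets
  analytic); an AR(1) option with variance renormalization exists.
* Couplings are planted multiplicatively: for a pair (profile k, mode m,
  ρ), subject *i*'s mode-*m* series is scaled so that its log-variance is
  linear in loading k with cross-subject correlation ≈ ρ. Engagement is a
  variance, so log-linear coupling keeps it positive. The log-engagement
  SD is 0.5 (≈ ±1.6-fold engagement spread across subjects — moderate,
  realistic inter-subject variability).
* Measurement noise: Gaussian SD 0.2 on standardized scores
  (test–retest-scale noise) and SD 0.3 on ROI series in units of the
  unit-variance mode signal (≈ 10:1 signal-to-noise in power).
* Random ground-truth mixing matrices have unit-norm columns and a
  geometric singular spectrum capped at condition number 4 — components
  overlap but stay well separated, matching the moderate inter-factor
  correlations seen in five-factor data.

What the generator does **not** emulate: hemodynamics, autocorrelated
noise, motion artifacts (beyond an optional scalar nuisance column),
scanner drift, voxel-level structure, age/sex effects on scores. Passing
recovery tests therefore demonstrates correctness of the estimation
chain under the stated generative model, not robustness to everything
real resting-state data can do.

## Evaluation design

The test suite and `scripts/acceptance.py` measure, at desk scale:

* **Profile recovery** — n = 500, 20 seeds; Amari index and per-component
  matched |r| against the planted mixing mapped onto the standardized
  scale (standardization rescales the mixing rows, so the raw mixing is
  not the right comparison target). Recovery experiments use the
  generator's *linear-model* configuration — continuous scores,
  independent subjects — because integer rounding/clipping and twin
  source-sharing perturb the effective mixing away from the planted one,
  making "recovery of the known mixing" ill-posed under the full realism
  layers. Those layers are exercised by the calibration, FDR, and
  determinism experiments instead.
* **Mode recovery** — 50 subjects × 600 timepoints, matched spatial
  weights ≥ 0.9.
* **Coupling power** — ρ = 0.4 planted on (profile 5, mode 2), n = 300,
  160 timepoints, 1,000 permutations, 50 replicates, full estimate path.
* **Calibration** — null rejection rate at α = 0.05 over 500 replicates
  of 64 subjects with family blocks (1,000 permutations each), with a
  hard block-preservation assertion on every permutation; FDR control
  with 6 couplings planted directly at the loading/engagement level
  (where "false discovery" is unambiguous), empirical FDR ≤ 0.08.
* **Reproducibility** — LOO at n = 200 and family-respecting split-half
  at n = 400 (mean matched |r| ≥ 0.9); out-of-sample recovery of the
  planted coupling with grouped leave-20-out folds and 2,000
  permutations.
* **Determinism** — the full pipeline rerun from one config reproduces
  every numeric artifact byte for byte.

## Known limitations

* **Permutation-resolution floor vs. FDR.** With `m` permutations the
  smallest possible add-one p-value is `1/(m+1)`; BH across 60 tests then
  bounds the smallest adjusted p at `60/(m+1)`. With 1,000 permutations
  that floor is ≈ 0.06 — a *single* true effect can rarely be flagged at
  q < 0.05 no matter how strong it is. Use at least ~2,000 permutations
  (floor ≈ 0.03), or the 10,000 default, whenever a lone association is
  plausible.
* **Normalization-induced compensation.** Because each subject's series
  is variance-normalized per region, a subject in whom one mode is loud
  has slightly depressed estimated engagement of *all other* modes.
  A strong positive profile–mode coupling therefore drags small genuine
  negative associations into the other cells of the same profile's row
  (observed r ≈ −0.1 to −0.3 at ρ = 0.4). This is a property of any
  relative-amplitude engagement measure, not an inference error; read
  engagement as "share of expressed variance", not absolute amplitude.
* **Convergence at small n.** Below ~200 subjects (profiles) the
  fixed-point iteration sometimes cannot reach the strict 1e-6 alignment
  tolerance; such runs are flagged, and resampling reports count excluded
  folds. Loosening `tol` to 1e-4 (the common default elsewhere) trades
  reproducibility sharpness for convergence.
* The block-exchange scheme treats all size-2 families as exchangeable
  regardless of zygosity — a conservative simplification of a full
  multi-level exchangeability tree.
* Engagement ignores temporal structure entirely: a subject briefly very
  loud and one steadily moderate can have equal variance. State-based
  models (e.g. hidden Markov) are out of scope here.
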
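# Methods

This note documents the models and procedures implemented in `lesionkit`,
the parameter choices that matter, what the synthetic cohorts do and do not
emulate, and the numerical conventions.

## Data model

A cohort is an ordered set of binary 3D lesion masks sharing one volume
geometry (shape + affine, checked at load time; non-binary masks are
rejected rather than thresholded), aligned with a per-participant behavior
table.  Lesion size is the nonzero-voxel count times the voxel volume,
reported in cc.  All voxelwise statistics are restricted to the **analysis
mask**: voxels lesioned in at least `min_frequency` (default 10%) of
participants, which guarantees nonzero variance for every tested voxel at
any realistic sample size.

**dTLVC** (direct total lesion volume control): the participants × in-mask
design matrix has entry 0 for an intact voxel and `1/√V_i` for a lesioned
one, `V_i` being participant *i*'s *whole-lesion* voxel count — including
voxels outside the analysis mask, since total lesion volume is a
whole-lesion quantity.  Volume is counted in voxels; the unit constant
cancels in all correlation-based statistics, while lesion size as a
regression predictor is in cc (z-scored inside the regressions, so F and
partial-r are scale-free).

## Mass-univariate mapping (VLSM)

Per voxel, the t statistic of the simple-regression slope of score on
damage (identical to the Pearson-r t transform, n−2 df).  Deficit scores
are coded higher = better, so the default test is one-sided toward damage
predicting lower scores (negative t); a two-sided option exists.
Zero-variance voxels are dropped with a warning; |r| = 1 voxels are capped
at t = ±1e6 and flagged.

**Generalized (continuous) FWER of order v.**  For each of B permutations
of the score vector, all voxel statistics are recomputed and the v-th most
extreme value in the deficit direction recorded; the critical value is the
(1−α) *nearest-rank* quantile of these B values, and observed voxels at or
beyond it (ties included, the conservative-reproducible choice) survive.
This bounds P(≥ v false-positive voxels) at α; v = 1 is classical
max-statistic FWER.  Permutations resample the behavior side only,
preserving the lesion covariance structure.  Because an order like v = 100
is conventionally quoted for whole-brain masks of ~1.5×10⁵ voxels, the
effective order is rescaled as `v_eff = max(1, round(v · p / 150000))` for
a p-voxel mask (a fixed v = 100 on a ~1,000-voxel desk-scale mask would be
structurally liberal); rescaling can be disabled.

## Sparse multivariate mapping

A single weight vector `w` with at most `k = round(s·p)` nonzero entries
and ‖w‖₂ = 1, chosen so the projection `Xw` correlates maximally with the
score.  The solver is a truncated-projection (hard-thresholding-pursuit
style) iteration: initialize from the score gradient, truncate to the k
largest-magnitude entries, then alternate (a) least-squares projection of
the score onto the current support's column span and (b) re-ranking voxels
by the gradient against that projection, until the support stabilizes
(≤ 100 iterations; no internal randomness).  Voxel columns are
standardized inside the solver, so the ranking is by score *correlation*
rather than covariance: on dTLVC data, covariance ranking preferentially
retains high-variance (frequently lesioned, central) voxels and measurably
degrades recovery of planted critical regions.  Weights are oriented so
the projection correlates negatively with the score (damage → deficit);
downstream stages use only the support.  Least-squares coefficients were
evaluated as prediction weights and rejected: with tens of correlated
columns they overfit badly at these sample sizes, while gradient weights
track held-out scores well.

**Sparseness selection.**  The quality of a solution at sparseness s is
the *CV correlation*: participants are split into k = 4 folds, the map is
fit on each training set, and the Pearson correlation between pooled
held-out projections and observed scores is computed (pooling rather than
per-fold averaging is stabler with small folds).  The default grid is
{0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0}; the CV
correlation is averaged over 3 repeated fold splits (single-split selection
is noticeably jittery at n ≈ 128), and the *smallest* s within a tolerance
(0.02) of the best mean CV correlation is selected — the bias toward
sparser solutions.  Focal associations therefore end at small s; diffuse,
size-like associations end at large s, where the retained region
approaches the whole lesion territory and the projection is effectively a
lesion-size proxy.  The binary template is the full nonzero support
(a magnitude threshold and an optional 26-neighborhood majority filter
exist, both off by default).

## Factor analysis of test batteries

Measures are z-scored; the correlation matrix is eigendecomposed;
components with eigenvalue > 1 are retained (Kaiser rule, or an explicit
count) and the retention is applied *before* rotation; retained loadings
are varimax-rotated with Kaiser row normalization.  Rotation preserves
per-measure communalities and total retained variance (checked to 1e-8).
Factor scores use the regression (Thurstone) method,
`Z · R⁻¹ · Λ`, which preserves the rank ordering the downstream mapping
needs; the score method is a convention choice, not a fitted quantity.
Factor sign and order are indeterminate, so all recovery comparisons align
by the sign/permutation maximizing summed absolute Tucker congruence
(Hungarian assignment), and downstream consumers are tested to be
invariant to sign flips.

## Prediction pipeline (location beyond size)

Participants are split into k = 8 balanced random folds (sizes differ by
at most 1).  Per fold and deficit, the analysis mask, dTLVC matrix and LSM
template are computed from the *training* participants only (mask
rebuilding per fold is the default, strict no-leakage reading; a
fixed-full-sample-mask toggle exists); for the sparse method the
per-deficit sparseness is optimized once on the full sample and held fixed
across folds so templates stay comparable.  Each held-out participant's
**template lesion load** is `|lesion ∩ template| / |template|`.  An empty
training template (common for size-driven deficits under dTLVC, where no
voxel survives correction) yields load 0 with a warning rather than
dropping participants, keeping the design balanced.

Per deficit, three OLS models are compared — score ~ size, score ~ load,
score ~ size + load — with the nested F test of ΔR² = R²(both) − R²(size)
on (1, n−3) df and the partial correlation of load with score controlling
for size (residual-residual correlation).  "Stepwise regression" is
realized as this explicit hierarchical comparison because those are the
three models of interest; no automated entry/exit search.  Significance is
α = 0.05 per deficit × method cell with no cross-cell correction.  A more
conservative *behavior-side* control residualizes the score on lesion size
before mapping; on size-driven deficits this empties the maps almost
completely.

## Synthetic cohorts

The generator emulates a chronic left-hemisphere stroke sample at desk
scale (default 32³ grid, 2 mm voxels; a cohort simulates in ~1 s):

* **Territory**: an ellipsoidal Gaussian probability field with compact
  support (center (10,16,16), semi-axes (10,12,12) voxels ≈ 6,000-voxel
  support), standing in for the middle-cerebral-artery territory where
  aphasia-causing lesions concentrate.
* **Lesions**: stochastic region growing — seed sampled ∝ territory
  probability, frontier voxels added ∝ territory probability in chunks
  (≤ 25% of the frontier per step, for speed), 26-connected, grown to an
  exact target size.  Growth from a common territory produces the
  size-location coupling (larger lesions cover more of any critical
  region) that the analyses are designed to untangle.
* **Sizes**: truncated lognormal fitted to a real chronic-stroke sample
  (mean 100.97 cc, SD 82.76 cc → μ = 4.358, σ = 0.717 on the log-cc scale,
  truncated to 5.38–376.12 cc), mapped to grid voxels by a linear
  `size_scale` (default 0.03).  The scale is the one free desk-scale
  choice: it sets the mean lesion to ~5% of the territory, which keeps the
  focal deficit only weakly size-coupled (r ≈ −0.2) — the regime of a
  genuinely localized deficit, whose real-data analogue correlates with
  size at r ≈ −0.04.  The full Table-style size range cannot fit a 32³
  grid, so the distribution's *shape*, not its absolute scale, is
  preserved.
* **Deficits**: `score = −w_size·z(size) − w_focal·z(load) + ε`,
  ε ~ N(0, noise_sd), where load is the damaged fraction of a planted
  critical region (default: a 33-voxel ball at (12,21,16), ~3% of the
  analysis mask — the smallest ball robustly inside the 10% mask).  With a
  single unit-weight driver and noise_sd = 1 the generative R² is 0.5.
* **Batteries**: `measures = F·Λᵀ + diag(uniqueness)·noise` with one
  planted damage region per factor; the raw per-region loads are z-scored
  and ZCA-whitened (default) so the planted factors are orthogonal while
  each remains maximally tied to its own region.  The default battery is
  17 measures on 3 factors (6+6+5 simple structure, loadings 0.8,
  uniqueness SD 0.6).

All randomness descends from one integer seed through a splittable
SeedSequence with per-participant child streams, so cohorts are
bit-identical across reruns.

What the simulations do **not** capture: real lesion morphology (vascular
sub-territories, white-matter anisotropy, mass effect), registration and
segmentation error, behavioral floor/ceiling effects, non-Gaussian score
noise, and bilateral or purely subcortical lesions.  Passing recovery
tests shows the *statistics* behave as claimed under their own generative
assumptions — it does not certify anatomical conclusions on real data.

## Validation experiments and problem sizes

`lesionkit.experiments` packages the standing experiments; the test suite
runs them at: FWER null calibration on a 20³ grid (n = 60, B = 500, 200
null runs), planted-region recovery over 20 cohorts (n = 128),
sparseness adaptivity over 5 matched cohort pairs, the ΔR² dissociation
over 40 replicate cohorts per scenario (8 folds, B = 300), behavior-side
control over 20 runs, and factor recovery at n = 128.
`scripts/acceptance.py` re-runs the same experiments with reduced
replicate counts (10–20) chosen to finish in a few minutes on one CPU.

## Numerical conventions and edge cases

* Permutation quantiles use the nearest-rank rule; threshold ties count as
  survivors.
* Voxel coordinates are 0-based C-order flat indices; the NIfTI affine
  defines the world mapping.
* Constant score vectors or constant predictors degrade gracefully
  (no survivors / R² = 0) with warnings rather than errors inside
  pipelines; hard contract violations (geometry mismatch, non-binary
  masks, empty analysis masks, zero-voxel sparseness) raise.
* Region-overlap summaries report percent of each *region* covered by
  default; the denominator is switchable to the template because either
  convention appears in practice.
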
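# Methods note

This note describes the statistical and numerical methods implemented in
`dwisurv`, the modelling choices behind them, and the synthetic data
generator used to validate the pipeline end to end.

## 1. Setting

The package targets longitudinal diffusion-weighted MRI (DWI) of tumours
imaged repeatedly over a course of fractionated radiotherapy — one
multi-b-value scan before each treatment fraction — together with
overall-survival follow-up. The scientific question is whether the
evolution of the tumour's diffusion signal over treatment carries
prognostic information beyond baseline imaging and clinical covariates.

The pipeline has five stages:

1. **Preprocessing** — slice cross-talk smoothing and a physical safety
   margin around the gross tumour volume (GTV);
2. **ADC mapping** — a closed-form apparent diffusion coefficient per
   voxel, summarised per fraction and over time;
3. **Signal decomposition** — monotonous-slope non-negative matrix
   factorization (msNMF) of pooled voxel decay curves into a small set of
   cohort-level components with per-voxel weights;
4. **Feature extraction** — percentile summaries of the weight maps per
   fraction, reduced to a value-at-fraction-one and a linear time-trend
   per feature, joined with clinical covariates and standardized;
5. **Survival modelling** — Cox proportional-hazards regression with
   best-subset selection scored by bootstrap cross-validation, plus
   Kaplan-Meier summaries, bootstrap confidence intervals and risk-group
   calibration.

## 2. Preprocessing

**Slice cross-talk.** Interleaved 2D acquisitions excite neighbouring
slices slightly, producing alternating slice intensities. Each slice is
replaced by `0.25*previous + 0.5*current + 0.25*next`, independently per
b-value volume. At the stack edges the kernel is renormalised over the
in-volume taps so that constant stacks pass through unchanged — a
property the tests assert exactly.

**GTV margin.** The delineated GTV is expanded by a physical margin
(default 5 mm) to absorb motion and DWI geometric distortion. A voxel
enters the expanded mask when its centre lies within the margin of any
GTV voxel centre, computed with a Euclidean distance transform that
honours anisotropic voxel spacing (`scipy.ndimage.distance_transform_edt`
with `sampling=spacing`). The tests verify the result against a brute-force
pairwise-distance check on an anisotropic grid.

## 3. ADC mapping

The apparent diffusion coefficient uses the mono-exponential model
`S(b) = S0 * exp(-b * ADC)` evaluated in closed form from exactly two
b-values:

    ADC = ln( S(b_low) / S(b_high) ) / (b_high - b_low)

with the convention b = 150/500 s/mm² on the primary 5-point sequence and
the two highest available b-values otherwise. Two-point evaluation avoids
perfusion contamination at low b and is robust on noisy data. Negative
ADC values (noise can make signal increase with b) are *retained* so that
within-GTV medians are not biased upward; non-positive signals, where the
logarithm is undefined, are marked invalid and excluded from statistics.

Per patient, the within-mask median ADC is tracked over fractions and
reduced by ordinary least squares to `ADC_frac1` (the observed fraction-1
value) and `ADC_time-trend` (the OLS slope per fraction). If fraction one
is missing, the fitted line at index 1 substitutes, with a warning.

## 4. msNMF decomposition

### Model

All masked voxels of all fractions of all patients on the shared b-grid
are pooled into one matrix `X` (rows: voxels; columns: b-values), and
factorized as `X ≈ W C` with `W ≥ 0` and each row of `C` constrained to
the cone of physically admissible decay curves:

* non-negative,
* non-increasing in b,
* with non-decreasing (monotonous) discrete slope — i.e. convex in b.

Any non-negative mixture of exponential decays satisfies these
constraints, so the cone encodes "this looks like a diffusion decay
curve" without committing to a parametric form.

### Algorithm

Alternating minimisation of `||X - W C||_F²`:

* **Weight step** — exact non-negative least squares per voxel row. For
  the small k used here (≤ 10) all candidate active sets are enumerated
  and solved in batch over all rows: the NNLS optimum restricted to its
  support satisfies that support's unconstrained normal equations, so the
  best feasible candidate over all supports is the exact solution. This
  vectorises the per-row solve into a handful of matrix products.
* **Component step** — HALS-style per-component row updates. For each
  component, the unconstrained row optimum is a weighted residual
  average; the constraint enters as an **exact Euclidean projection onto
  the cone**. The cone is reparametrised as the non-negative span of a
  constant vector plus hinge functions `max(b_j - b, 0)` (kinks at the
  interior grid points), which turns the projection into a small NNLS
  problem. The projection is therefore idempotent, and because both
  half-steps solve their subproblem exactly, the objective is
  non-increasing by construction — both properties are asserted by tests.

Convergence is declared when the per-iteration decrement of the residual
sum of squares falls below `tol * ||X||_F²` (default `tol = 1e-8`).
Measuring the decrement against the data norm rather than the current
residual keeps the rule meaningful in the noiseless limit, where the
residual itself vanishes. Multiple random restarts (exponential curves
with log-uniform random rates) guard against local minima; the lowest
residual wins.

The scale/permutation ambiguity of NMF is fixed by normalising each
component to value 1 at the smallest b (weights absorb the scale) and
ordering components by area under the curve, slowest decay first (C1).

Patients acquired with a different DWI sequence do not enter the pooled
fit; the fitted components are linearly interpolated onto their b-grid and
their weights obtained by NNLS projection. Interpolation never
extrapolates — grids extending beyond the fitted b-range raise an error.

### Features

For each component and each fraction, the 10th and 90th percentiles of
the within-mask weight distribution are computed (linear interpolation
between order statistics). Each percentile series over fractions is
reduced, exactly as for ADC, to a fraction-1 value and an OLS slope:
`Component{j}_prc{10,90}_{frac1,time-trend}` — 12 parameters for k = 3.
With the 2 ADC parameters and 6 clinical covariates (age, GTV volume,
time from diagnosis to radiotherapy, sex, performance status ≥ 1, prior
local recurrence) the feature table has 20 columns. Continuous columns
are standardized to mean 0, SD 1 over the cohort (constants stored, so
effects read per SD and the transform is invertible); binary indicators
stay 0/1.

## 5. Survival modelling

All survival machinery is implemented from first principles (the
bootstrap cross-validation below needs the partial likelihood evaluated
at *fixed* coefficients on *held-out* data, which off-the-shelf estimator
APIs do not expose). An independent library is used in the test suite as
a cross-checking oracle only.

**Cox regression.** Newton-Raphson on the partial log-likelihood from
`β = 0`, with step-halving; Breslow tie handling by default (Efron
available). Hot loops are `numba`-compiled: the best-subset search at
realistic sizes performs on the order of 10⁶ small Cox fits. Convergence
requires the score's max-norm below 1e-8. Two degeneracy guards raise
`ConvergenceError`: coefficients escaping |β| > 50 during iteration, and
a converged fit whose observed information collapses relative to its
natural scale (events × covariate variance) — the signature of a
monotone likelihood (separation) that plateaus at finite β.

**Concordance.** Harrell's C: over comparable pairs (the shorter time
has an event; equal times excluded), the fraction in which the patient
with the lower linear predictor survives longer, ties counting 1/2.

**Kaplan-Meier.** Product-limit estimator with Greenwood variance and
log(−log)-transformed 95% bands. The median is the first time the curve
drops to ≤ 0.5; its CI bounds are the first times the confidence bands
do. Median potential follow-up uses the reverse Kaplan-Meier (event and
censoring roles swapped).

**Model selection.** All parameter subsets up to size 3 are scored by
bootstrap cross-validation: patients are resampled with replacement, the
in-boot patients fit β, and the out-of-boot partial log-likelihood at
that β — normalised per out-of-boot patient, since the out-of-boot count
varies — is averaged over 50 bootstrap iterations. The same draws are
reused for every subset (common random numbers), so subset ranking is not
blurred by resampling noise, a subset's score does not depend on which
other subsets are in the race, and the whole search is deterministic
given data and seed. Draws degenerate for any subset (no out-of-boot
patients, zero in- or out-of-boot events) are rejected at generation;
subset-specific failures (constant in-boot column, non-convergence) retry
on deterministic extra draws and are excluded if persistent. Ties break
toward the smaller subset, then lexicographically. The winner is
refitted on the full cohort; percentile CIs for its coefficients come
from 2000 further bootstrap refits. A Verweij–van Houwelingen variant of
the cross-validated likelihood (full-data minus in-boot likelihood, both
at the in-boot β) is available via `cv_loglik="vvh"`.

**Calibration.** Patients split at the 25th/75th percentiles of the
linear predictor into low/medium/high risk; each group's Kaplan-Meier
curve is compared with the mean of its members' model survival curves
derived from the Breslow baseline cumulative hazard.

## 6. Synthetic cohort generator

Real MR-Linac DWI with linked survival is not publicly shareable, so the
package ships a generator whose *ground truth is known*, enabling honest
recovery tests at every stage.

Per voxel the generative model is exactly the mixture the decomposition
assumes: `S(b) = s0 * Σ_j w_j C_j(b)` plus Gaussian noise (Rician
optional), with

* components: two exponential decays (0.8 and 3.0 ×10⁻³ mm²/s) plus a
  b=0-driven spike component;
* ellipsoidal GTV masks with volumes ~N(21.6, 15.8²) cm³ on a
  24×24×12 grid at 3×3×5 mm spacing;
* smooth (Gaussian-filtered) per-component weight fields inside the mask,
  giving realistic spatial heterogeneity;
* per-fraction multiplicative weight drift `max(0, 1 + slope·(f−1))`,
  slope ~N(0, 0.04) per component — the longitudinal signal;
* noise σ = 5 at s0 = 100 (SNR 20).

Defaults emulate a 45-patient cohort: 39 patients on the primary b-grid
{0, 30, 80, 150, 500} s/mm², 6 on a second sequence ({0, 20, 60, 100,
300}, kept inside the primary b-range so component projection never
extrapolates), 5 fractions with two patients missing some.

Survival is exponential proportional hazards on *standardized ground-truth
imaging features* (baseline 90th percentile of the fast component's
weight field, and the slow component's drift slope) with hazard ratio 2
per SD each (opposite signs) and baseline rate `ln 2 / 15.5` per month,
so the cohort median survival at the average feature value is 15.5
months. Censoring is independent exponential with rate `h0 · r/(1−r)`
(r the target censored fraction, default 0.2), which yields a censored
fraction of exactly r under the null. Clinical covariates are drawn from
distributions typical of a locally advanced pancreatic cancer cohort
(age ~N(67.5, 10.1), 42% male, 62% performance status ≥ 1, 18% prior
recurrence, lognormal time from diagnosis to radiotherapy around 6.5
months) and are prognostically null by construction — useful as negative
controls in selection tests.

Limitations: no imaging artefacts beyond additive noise (no motion,
ghosting, susceptibility distortion), masks are ellipsoids, weight drift
is linear in fraction number, and clinical covariates carry no true
hazard. These are deliberate: the generator's job is validation with
known truth, not realism for its own sake.

## 7. Numerical and reproducibility choices

* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning, so cohort generation, msNMF
  restarts and every bootstrap layer are independently reproducible.
* Feature/selection outputs are written with fixed numeric formatting
  (`%.12g`, sorted JSON keys); the same cohort, configuration and seed
  produce byte-identical files, which a test asserts.
* The Newton step solves the score equation with a tiny relative ridge
  (1e-10 of the mean information diagonal) purely for numerical
  solvability of the linear step; it does not regularise the estimate.
* Exactness over iteration: per-row NNLS (active-set enumeration) and
  the cone projection (hinge-basis NNLS) are exact, so msNMF's monotone
  objective is a theorem, not a hope — and is tested.

## 8. Validation problem sizes

The test suite validates, among others: ADC recovery to 1e-10 relative
error; msNMF recovery on 20,000-voxel problems (variance explained
≥ 0.999 noiseless, median component cosine ≥ 0.95 at SNR 20 over 10
seeds); Cox estimates against an independent implementation and
brute-force likelihood maximisation; β = ln 2 recovery within ±0.15 at
n = 500 with 2000-bootstrap CI coverage between 90% and 99% over 100
replicates; best-subset recovery of 2 informative features among 20
(n = 200) in ≥ 80% of replicates with null held-out concordance near 0.5;
hand-computed Kaplan-Meier fixtures; and byte-identical end-to-end runs.
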
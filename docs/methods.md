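# Methods

This note documents the models, estimators and design decisions in the
`freewater` package: what is computed, why it is computed that way, and
which behaviours are assumptions rather than guarantees.

## 1. Signal model

Each voxel's diffusion-weighted signal is modelled as a two-compartment
(bi-tensor) mixture:

    S_i = s0 · [ (1 − f) · exp(−b_i gᵢᵀ D gᵢ) + f · exp(−b_i · d_w) ]

with tissue tensor `D` (symmetric positive semi-definite, packed as
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)), free-water fraction `f ∈ [0, 1]`, and a
fixed isotropic free-water diffusivity `d_w = 3.0e-3 mm²/s` (water at body
temperature). `s0` is estimated as the mean of the b=0 volumes.
Acquisitions are single-shell: one or more b=0 volumes plus ≥ 6 directions
at one b-value (default 1 b=0 + 30 directions at b = 1000 s/mm², with a
32-direction variant), laid out on a golden-angle hemisphere spiral.

## 2. Single-tensor (uncorrected) fit

`fit_single_tensor` is conventional DTI: weighted linear least squares on
the log signal with the rank-7 design `[ln s0, D…]`. Two passes — OLS,
then weights equal to the squared predicted signal (the standard WLS
approximation to the log-transformed noise). Non-positive signals get zero
weight; voxels with more than 25% non-positive signals are flagged
`invalid`. Output eigenvalues are clamped at zero.

## 3. Single-shell identifiability and the free-water estimator

**The core difficulty.** At a single shell, the pair (f, tissue MD) is
*exactly* non-identifiable in an isotropic voxel: the attenuation
`(1−f)·exp(−b·MD) + f·exp(−b·d_w)` depends on the parameters only through
its value at the one acquired b, so a continuum of (f, MD) pairs produces
identical data. Anisotropy breaks the degeneracy in principle (the tissue
compartment modulates with direction, the free-water compartment does
not), but at SNR 30 with 30 directions the curvature it contributes is far
too weak to estimate f reliably in low-FA tissue. Any single-shell
free-water method is therefore a *regularised/MAP* estimator whose
accuracy in near-isotropic tissue is inherited from its initialisation and
priors — ours makes that explicit rather than hiding it in optimizer
behaviour.

**Initialisation.** For each voxel the single-tensor apparent MD is placed
between a tissue reference decay and the free-water decay at the shell
b-value:

    f₀ = (e^{−b·MD_app} − e^{−b·MD_ref}) / (e^{−b·d_w} − e^{−b·MD_ref}),

clipped to [0.05, 0.95]. The tissue tensor is initialised by re-fitting
the single-tensor model to the signal with the estimated free-water
component subtracted, projected into the eigenvalue box.

**Data-driven tissue reference (`md_tissue="auto"`, the default).** A
fixed reference (e.g. the generic 0.6e-3 mm²/s) cannot track the large
between-subject tissue-MD differences this pipeline is meant to detect —
in a hypoxic-injury cohort, tissue MD *is* the signal. The reference is
instead estimated per subject from the subject's own data using two
physiological priors: (i) voxels with high measured FA (≥ 0.35) carry
little free water (free water suppresses FA), so their apparent MD —
corrected for a nominal 5% free-water fraction — estimates the
white-matter tissue MD; (ii) grey-matter tissue diffusivity sits a fixed
factor (1.07) above white matter. High-FA voxels get the WM reference, the
rest the GM one; fallbacks (all plausible-MD voxels, then 0.6e-3) cover
degenerate inputs. *Assumption, not guarantee:* this is invalid on data
where high-FA voxels carry substantial free water (e.g. a uniform phantom
with f = 0.3 everywhere); pass an explicit `md_tissue_init` there.

**Optimisation.** Levenberg–Marquardt on (f, Cholesky factor of D),
vectorised over all in-mask voxels, minimising

    ‖S/s0 − model‖² + λ_reg Σ_edges w_e (f_u − f_v)²
                    + w_prior (f − f₀)² + λ_tensor Σ_edges w_e ‖R_u − R_v‖²

- **Edge-preserving weights** `w_e = exp(−(Δf₀/0.1)² − (ΔMD_app/1.5e-4)²)`
  keep the smoothness penalties from bleeding across CSF/parenchyma and
  lesion/tissue boundaries (measured: without them, f was biased +0.01 to
  +0.02 near boundaries).
- **λ_reg** defaults to `"auto"`: 1% of the mean data cost over the mean
  weighted edge penalty at the init.
- **f prior.** A Gaussian prior centred at the init with sd 0.1, weighted
  by the estimated noise variance: `w_prior = σ̂²/sd²`. σ̂² is first taken
  from the median per-voxel data cost at the init, then — because the init
  residual includes model misfit, not just noise — re-estimated at the
  stage-1 solution and the LM re-run with the corrected weight when it
  drops materially (iteratively reweighted MAP). Consequence: on
  noise-free data the prior vanishes and the fit is pure maximum
  likelihood (oracle recovery from the default init); on noisy data the
  weight equals the noise floor and the prior carries the non-identifiable
  directions.
- **λ_tensor** (smoothness on the Cholesky factors) defaults to **0**:
  with the auto weight it traded FA variance for a measurable MD bias
  (+4.6% at f = 0.5, FA = 0.7) with negligible cohort-level benefit.
- Eigenvalues are projected into [0.1e-3, 2.5e-3] mm²/s every 10
  iterations and at the end. Convergence: per-voxel relative cost
  improvement ≤ tol, damping saturation, or negligible parameter motion
  (Jacobi neighbour exchange can keep nominal cost improvements alive long
  after the estimates stop moving).

**Noise-debiased FA.** Eigenvalue dispersion under noise inflates FA
(measured +0.035 at the study SNR). Both fitters also return `fa_debiased`
computed from the moment form FA² = (3/2)·‖D − MD·I‖²_F / ‖D‖²_F with the
plug-in Gauss–Newton covariance of the tensor estimate subtracted from
both quadratic terms. Residual bias ≈ −0.007 at study conditions. With a
zero covariance the expression reduces exactly to the standard FA.

## 4. Scalar maps and subject summaries

Per subject, three whole-brain metrics: mean MD, mean FA, and %MD450 (the
percentage of in-mask voxels with MD strictly below 450e-6 mm²/s).

- **Uncorrected maps:** an ADC artifact/CSF filter removes voxels with
  apparent MD outside [200, 2000]e-6 mm²/s (inclusive bounds) before
  summarising.
- **Corrected maps:** exclude voxels with fitted f ≥ 0.9 (tissue tensor
  unidentifiable), voxels flagged invalid, and voxels whose *apparent*
  (uncorrected) MD falls outside the same ADC window. The window must be
  evaluated on the apparent MD: after free-water subtraction, a CSF
  voxel's corrected MD looks tissue-like, so the corrected map itself
  cannot identify CSF. (Measured: without this, ~20% of pure-CSF rim
  voxels finished just below the f = 0.9 cut and biased whole-brain mean
  MD by +40..60e-6.)

## 5. Synthetic cohort generator

A layered spherical phantom on a cubic grid (default 24³, 2 mm voxels): a
WM core (default 50% of tissue volume, FA from the subject draw, free
water U[0.02, 0.10]), a GM shell (FA 0.15, free water U[0.20, 0.40]), and
a one-voxel CSF-border rim (f = 1). Mild log-normal voxelwise MD
heterogeneity; a smoothly varying principal-axis field. Poor-outcome
subjects get contiguous lesion blobs (cytotoxic oedema: MD U[300, 430]e-6,
FA ≈ 0.15, free water U[0.02, 0.08] — injured tissue has *reduced*
extracellular water); good-outcome subjects a scattered low-MD voxel tail.
Non-lesion tissue MD is scaled so the whole-mask mean hits the subject
target within 2%.

Cohort calibration reproduces published group summaries: per-group
three-point (quartile-atom) distributions for tissue MD and %MD450 coupled
through one severity draw, Gaussian FA targets (0.30 ± 0.03 good,
0.28 ± 0.03 poor), and clinical covariates (age, sex, resuscitation
duration, shockable rhythm, lactate, EEG category) matched to the printed
group distributions. The WM FA needed to hit a subject's whole-brain FA
target is solved from the WM/GM mixture *after removing the lesion share*
(lesions carry FA ≈ 0.15; ignoring them made heavily lesioned subjects
undershoot their target by up to 0.03). Noise is Rician (two Gaussian
channels in quadrature) with σ = s0/snr_b0, default snr_b0 = 30.

`sample_cohort_metrics` draws the subject-level metrics table directly
from the same calibrated distributions (no imaging), for prediction-layer
simulations where only the table matters.

**Realism limits.** The phantom is a sphere with two tissue classes and an
axisymmetric tensor field; no gyri, no partial-volume gradients beyond the
rim, no registration error (subjects share a grid by construction), no
scanner/vendor effects, and the ground-truth free-water fractions are
uniform draws rather than anatomically structured. Group differences are
driven by the calibrated MD/%MD450/FA distributions, not by anatomy.

## 6. Group statistics

- `cohens_d`: pooled-SD Cohen's d with a normal-approximation 95% CI (from
  group means/SDs; medians/IQRs are not convertible and are not used).
- `compare_groups`: per-variable two-group tests — Shapiro–Wilk screen
  (α = 0.05 in both groups) choosing Student t vs Mann–Whitney U for
  continuous variables, chi-squared without continuity correction for
  categorical ones — with publication-style summaries and effect sizes.
- `voxelwise_permutation_test`: FWE-controlled two-group comparison of
  aligned maps by the permutation distribution of the maximum |t|
  (default) or of the maximum two-sided TFCE score (E = 0.5, H = 2,
  dh = 0.1, 26-connectivity — FSL's conventional constants).
  p_FWE = (1 + #{perm max ≥ observed}) / (1 + n_perm); when fewer distinct
  permutations exist than requested they are enumerated exactly.

## 7. Outcome prediction

Four logistic models (clinical; DTI-only; clinical+MD+FA;
clinical+FA+%MD450) with stratified 10-fold cross-validation on shared
folds: per fold, continuous covariates standardised on the training
portion, EEG category dummy-coded against reference III, a small ridge
penalty (α = 0.01) for separation robustness. Predictions are pooled
out-of-fold (each subject exactly one predicted probability). Reported:
AUC (Mann–Whitney form, ties counted half), maximal sensitivity for poor
outcome among thresholds with 100% specificity, and sensitivity for good
outcome at ≥ 90% specificity, each with stratified-bootstrap 95% CIs.

## 8. Pipeline and formats

Stages simulate → fit → metrics → stats → predict, each persisting its
artifacts (NIfTI-1 volumes; FSL-dialect bval/bvec; tab-separated tables;
JSON manifest keyed by a configuration hash). `--resume` skips stages
marked complete under the same config hash. All thresholds and defaults
(ADC window 200/2000e-6, %MD450 threshold 450e-6, d_w 3.0e-3, α = 0.01,
10 folds, 2000 bootstrap resamples) live in `PipelineConfig`.

## 9. Known behaviour and caveats

- Free-water f and corrected MD in near-isotropic, low-SNR voxels are
  prior-dominated; their accuracy depends on the tissue-MD reference being
  appropriate for the subject (Section 3).
- Parameter-recovery guarantees (|bias(f)| < 0.05, |bias(MD)|/MD < 5%
  at snr 30) hold when the tissue reference is correctly specified; the
  auto reference achieves comparable accuracy on the calibrated cohort
  geometry.
- The corrected whole-brain summaries depend on the apparent-MD ADC
  exclusion; summarising corrected maps without it re-admits partial CSF.
- `fa_debiased` can underestimate FA in voxels whose covariance estimate
  saturates (flagged-invalid or f ≈ 1 voxels); such voxels are excluded by
  the analysis masks.
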
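# Methods

## The estimand and its inference

The unit of effect size throughout is the squared partial correlation R²
between ROI lesion load (mean fuzzy abnormality over the region of
interest) and the target behavioural score, adjusting both for k = 5
covariates: the four other behavioural scores and total lesion size. Both
variables are residualised on `[1, covariates]` by OLS; the Pearson
correlation r of the residuals is tested with

    t = r sqrt(df / (1 - r^2)),  df = n - 2 - k,

two-sided. This df convention propagates everywhere: the voxelwise GLM has
df = n - 7 (intercept + 6 regressors), and the closed-form significance
floor is R²_crit(n, α) = t_crit² / (t_crit² + df) with t_crit the
two-sided α quantile at df = n - 2 - k. With k = 5 this floor reproduces
0.16 / 0.07 / 0.05 / 0.03 / 0.02 at n = 30…180 (α = .05) and 0.38 at
n = 30, α = .001.

Interval, power and sign-error calculations all use the Fisher-z
approximation for a partial correlation: ẑ = atanh(r̂) is treated as
Normal with standard error 1/√(n − k − 3).

* **Credible interval.** Under a flat prior, the posterior of z is
  N(atanh r̂, 1/(n−k−3)); the equal-tailed interval is mapped back through
  tanh and squared. If the r-interval straddles 0 the R² interval is
  [0, max(bound²)]. At r̂² = 0.11, n = 360 this gives (0.056, 0.177),
  i.e. 0.06–0.18 at two decimals. The construction is a normal
  approximation to the flat-prior posterior, not an exact small-sample
  posterior for ρ; at these sample sizes (n ≥ 30, |r| ≤ 0.9) the two agree
  to well under a percentage point of coverage.
* **Power.** power(ρ², n, α) = Φ(z̄/SE − z_{1−α/2}) + Φ(−z̄/SE − z_{1−α/2})
  with z̄ = atanh(√ρ²). The exact noncentral-F power for the multiple
  regression is deliberately not implemented; the Fisher-z form is within
  ±0.03 of simulation at every (ρ², n) combination the tests probe.
* **Sign error.** P(wrong direction) = Φ(−z̄ √(n−k−3)); ρ² = 0 returns 0.5
  with a warning (direction undefined).

Resample significance calls use the two-sided p; effect direction is
tracked separately through the sign of r, never by excluding records.

## Synthetic cohort generator

The generator emulates a stroke cohort in which one ROI's abnormality
drives a deficit in the target score:

1. **Latent layer.** (lesion-load z, four nuisance-score z's, log lesion
   size z) are joint standard Gaussian. Defaults: nuisance scores
   inter-correlate at 0.4 and correlate −0.35 with log lesion size;
   lesion load correlates 0.65 with log size and −0.30 with the nuisance
   scores. The published covariance of the real behavioural battery is
   unknown; these are plausible documented defaults, configurable via
   `covariate_corr`, and positive-definiteness of the joint matrix is
   validated at construction.
2. **Observed layer.** Nuisance scores are 50 + 10z clipped to [10, 90]
   (±4 SD, so truncation changes the SD by ≪ 2%); lesion size is a
   lognormal moment-matched to mean 85.7 / SD 87.6 cm³ and clipped to
   [1.5, 386.2] cm³ (positivity plus a heavy right tail; the configured
   minimum may not fall below 1.5 cm³, mirroring the cohort inclusion
   rule); lesion load is 0.35 + 0.15z clipped to [0.005, 0.995] (never
   exactly zero, so every patient has a renderable lesion).
3. **Target score.** y* = β·(standardised load) + γ·Σ(standardised
   nuisance scores) + ε, y = 50 + 10y* clipped. γ = 0.15 gives the target
   realistic correlations with the other scores. β and Var(ε) are solved
   in closed form from the constraint pair {population partial R² of load
   given the 5 covariates = target, Var(y*) = 1}, using the
   observed-variable correlation matrix estimated once from a 400,000-draw
   Monte-Carlo with a fixed internal seed — calibration is therefore a
   deterministic function of the configuration, exact to ~1e-3 in R²
   (clipping and the lognormal transform make a closed form on the latent
   scale insufficient). Effect direction defaults to −1: more damage,
   poorer score.

Because a bootstrap study resamples one *fixed* cohort, the sample R² of
that cohort — not the population value — is what all resampling numbers
revolve around. `fix_sample_partial_r2` therefore rotates the lesion-load
vector inside the residual space of the covariates (decompose the
residualised load along/orthogonal to the residualised target, rescale the
two components, preserve the total residual norm) so the in-sample partial
R² equals the target to ~1e-16. The operation is a fixed point when the
requested value equals the current one, and an affine remap (which cannot
change a partial correlation) restores [0, 1] bounds if needed.

### Lesion volumes

Each patient's lesion is one smooth blob: abnormality 1.0 inside a core
radius, decaying linearly to 0 over a ramp of width w (default 24 mm).
Three constraints fix its geometry:

* **Volume.** The binary lesion is exactly `fuzzy ≥ 0.3` (the toolbox
  threshold is unpublished; 0.3 is a configurable default). Its radius is
  calibrated against the actual voxel-centre lattice so the binary voxel
  count reproduces the patient's lesion size to within half a voxel.
* **Load.** The blob centre is placed at a distance from the ROI centre
  (random direction, bisection on the distance) such that the mean fuzzy
  value over the true-ROI voxels equals the patient's latent load within
  0.01. When even a centred blob is too faint (small lesion, high load)
  the ramp is steepened instead. Radius calibration and placement are
  iterated to joint convergence.
* **Containment.** Centres are clamped so the binary sphere stays inside
  the grid; several candidate directions are tried when a low-load
  patient with a large lesion needs room to move away from the ROI.

The default grid is 40×48×40 voxels at 4 mm (a desk-scale standard-space
brain bounding box; 2 mm is configurable), with a spherical true ROI of
radius 6 mm (19 voxels) at the grid centre. The 24 mm ramp is deliberately
shallow relative to the ROI: across the ROI the profile is then locally
planar, so each single voxel's fuzzy value tracks the ROI-mean load
tightly and the region is discoverable by the voxel-level GLM — a
contract of the generator (with default load distribution and n ≥ 90,
every true-ROI voxel is damaged in ≥ 5 patients; the generator warns if a
draw violates this).

What the generator does **not** emulate: spatial heterogeneity of real
vascular lesions (single spherical blobs, single ROI), segmentation and
normalisation artefacts, multimodal lesion-size distributions, missing
data, or any nonlinear lesion-deficit relationship. Passing tests
therefore demonstrate the sampling behaviour of the *statistics* under a
faithful effect-size calibration — not robustness to real-data pathology.

## Voxelwise GLM and FWE correction

All in-mask voxels share one design (intercept, 5 scores, lesion size), so
the OLS hat matrix is computed once and the t map for the target
coefficient is a single matrix product. The analysis mask keeps voxels
damaged (binary) in ≥ 5 patients. The ROI contrast is one-tailed negative
by default — the hypothesised direction — with a two-tailed option.

Random-field-theory FWE is not implemented: it requires smoothness
estimation orthogonal to what this package studies. FWE control comes
from either

* **Freedman–Lane max-|t| permutation** (default): residualise the data on
  the nuisance-only design, permute those residuals, add back the nuisance
  fit, refit, record the max statistic over voxels; the threshold is the
  conservative finite-sample (1−α) quantile ((⌈(1−α)(n_perm+1)⌉)-th order
  statistic). Because the nuisance fit is orthogonal to the residualised
  target regressor, each permutation reduces to one (k+2)×n · n×V matrix
  product. n_perm ≥ 500 and n_perm ≥ 1/α are enforced. The attained
  family-wise error is verified by simulation (200 null cohorts on a
  216-voxel grid) to sit at 0.05 ± 0.03.
* **Bonferroni** (deterministic fallback): the per-voxel t quantile at
  α / n_voxels.

Degenerate voxels with zero residual variance get t = 0 when the target
coefficient is also zero (pure-nuisance fit) and a ±1e6 sentinel
otherwise; both are counted, warned about, and — having the wrong sign or
being excluded — never contaminate the ROI in practice. This only arises
in noiseless synthetic data.

## Resampling study

6000 resamples per size (30, 60, 90, 120, 180, 360 — each dividing the
360-patient cohort evenly), drawn with replacement by default. Each
record's indices come from an independent substream keyed by
(master seed, size, replicate), so any single record is reproducible in
isolation; the batch path and the isolated path are tested to agree.
Rank-deficient resamples (condition number > 1e10) are redrawn from a
child substream; more than 1% redraws aborts, since that signals a
degenerate cohort rather than bad luck.

Decile selection is nearest-rank (rank ⌈q·B/100⌉, minimum 1) on the R²
distribution with ties broken toward the lowest replicate index — actual
resamples, never interpolated values. Table cells with no members render
as a dash; displayed values are rounded to two decimals while full
precision is kept internally.

The per-voxel power summary for a selected resample converts each ROI
voxel's GLM t into an observed R² (t²/(t²+df)), evaluates Fisher-z power
at the Bonferroni-corrected α, and reports the percentage of voxels with
power ≥ 0.80. The original power-map tool's internal algorithm is not
published; this proxy is the package's own defined summary and is treated
as qualitative.

## Problem sizes used by the test suite

The suite runs the full tabular study at production scale (360 patients,
6000 replicates × 6 sizes — about two seconds, since the batched
partial-correlation path is a handful of einsums). Imaging tests use a
26×32×26 grid at 6 mm — the same physical extent as the default grid, so
even 386 cm³ lesions fit — with 120–360 patients and 600–800
permutations. Null-calibration checks use 5000 replicates (p-value
uniformity), 10,000 (power accuracy) and 200 null cohorts (family-wise
error).

## Known limitations

* The Fisher-z constructions are approximations; they are accurate at the
  studied sample sizes but not exact for n < ~15 or |r| → 1.
* Without-replacement resampling of m of N patients carries a
  finite-population correction of (1 − m/N) on sampling variance that the
  with-replacement bootstrap lacks; near the steep part of the power
  curve (m = 90, N = 360) this produces a systematic ~3-percentage-point
  higher significance rate for subsampling. The two modes agree closely
  everywhere else.
* Cluster-extent inference, anatomical labelling, multivariate
  lesion-symptom mapping and RFT are out of scope.
* The generator's single-blob lesions make the voxelwise analysis mask
  unrealistically compact around the ROI; mask sizes (and hence Bonferroni
  severity) are of the right order of magnitude but not matched to any
  real template.
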
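# lesionboot

How reproducible is a voxel-based lesion-deficit mapping study? `lesionboot`
is a Python toolkit for answering that question end to end: it identifies a
brain region whose structural abnormality predicts a behavioural deficit
across stroke patients, quantifies the effect size with a credible
interval, and then — by bootstrap resampling at a ladder of sample sizes —
measures how often the effect replicates, how badly small significant
samples overestimate it (the winner's curse), and how often they invert its
direction. A calibrated synthetic cohort generator lets every stage run
without any patient data.

It is written for researchers in lesion-symptom mapping, clinical
neuroimaging and biostatistics who want to study or teach the sampling
behaviour of mass-univariate lesion analyses.

## The model

Each of *n* patients contributes five behavioural T-scores (population
mean 50, SD 10) — nonword repetition (the target), written picture naming,
semantic associations, recognition memory, auditory word-to-picture
matching — a lesion size in cm³, and a *fuzzy lesion image*: a voxel map of
structural abnormality on a continuous scale from 0 (normal) to 1
(completely abnormal).

**Analysis 1 (ROI discovery).** Within voxels damaged in at least 5
patients, the fuzzy value is regressed on a 7-column design
(intercept, 5 scores, lesion size). Voxels where the nonword-repetition
coefficient is negative (greater abnormality ⇒ poorer score) and survives
family-wise error correction (Freedman–Lane max-|t| permutation, or
Bonferroni) form the region of interest. Per patient, *lesion load* is the
mean fuzzy value over the ROI.

**Effect size.** The effect is the partial correlation *r* between lesion
load and nonword repetition given the k = 5 covariates (the four other
scores and lesion size):

- t = r·√(df / (1 − r²)), df = n − 2 − k;
- R² = r² is the proportion of variance explained uniquely by lesion load;
- a flat-prior credible interval for R² comes from the Fisher-z posterior
  z ~ N(atanh r, 1/(n − k − 3));
- the closed-form significance floor is R²_crit = t²_α / (t²_α + df), the
  smallest R² that can reach p < α at sample size n.

**Analysis 2 (reproducibility).** The fixed cohort is resampled with
replacement (B = 6000 per size, sizes 30–360); each resample's (R², p,
sign) is recorded and summarised by significance splits, position against
the full-cohort credible interval, and decile selections of the R²
distribution.

The synthetic generator draws (latent ROI lesion load, nuisance scores,
log lesion size) from a joint Gaussian and solves the effect coefficient in
closed form so the population partial R² equals a target (default 0.11);
an exact orthogonal adjustment then pins the in-sample R² of the fixed
cohort to that target to machine precision. Lesion volumes are rendered as
smooth blobs whose thresholded volume reproduces each patient's lesion
size and whose mean abnormality over a designated "true" ROI equals the
latent lesion load.

## Worked example

```python
from lesionboot import (GeneratorConfig, calibrate_generator, generate_cohort,
                        fix_sample_partial_r2, LesionDeficitModel)

config = calibrate_generator(0.11, GeneratorConfig(n_patients=360))
cohort, load = generate_cohort(config, seed=11)
load = fix_sample_partial_r2(cohort, load, 0.11, sign=-1)

results = LesionDeficitModel.from_dataframe(cohort, lesion_load=load).fit()
print(results.summary())

study = results.bootstrap_study(sizes=(30, 90), B=6000, seed=5)
sig = study.proportion_significant()
print(f"significant at p<.05:  N=30: {sig[30]:.1%}   N=90: {sig[90]:.1%}")
```

prints

```
ROI lesion-deficit effect on score_repn
=======================================
                              value
---------------------------------------
n patients                          360
covariates (k)                        5
partial r                       -0.3317
R2 (variance explained)          0.1100
t statistic                      -6.605
degrees of freedom                  353
p (two-sided)                  1.46e-10
95% credible interval (R2) [0.06, 0.18]
---------------------------------------
significant at p<.05:  N=30: 38.6%   N=90: 88.2%
```

The full cohort shows a highly significant effect explaining 11% of the
variance, with a credible interval of 0.06–0.18. Yet only ~39% of size-30
resamples of this same cohort reach p < 0.05 — and those that do
overestimate the effect badly (mean significant R² 0.26, median 0.24,
more than twice the truth), while ~4% of size-30 resamples point in the
wrong direction entirely. At N = 90 the effect replicates in ~88% of
resamples. Closed-form counterparts are available directly:
`critical_r2(30, 5, 0.05)` → 0.157 (no size-30 sample can "significantly"
explain less), `analytic_power(0.11, 30, 5, 0.05)` → 0.366,
`sign_error_probability(0.11, 30, 5)` → 0.053.

The imaging pipeline (volume rendering, overlap mask, voxelwise GLM,
permutation FWE, ROI extraction) runs end to end with

```bash
lesionboot run-all --out study_output --seed 3 --n-boot 600
```

or, stage by stage, via `lesionboot simulate-cohort`, `identify-roi`,
`effect-size`, `bootstrap-study`, `power` and `report`.

## Layout

- `src/lesionboot/effects.py` — partial correlation, significance floors,
  Fisher-z power / sign-error / credible interval
- `src/lesionboot/synthetic.py`, `volumes.py` — calibrated cohort and
  lesion-volume generator
- `src/lesionboot/lesion_io.py` — NIfTI I/O, overlap maps, analysis masks
- `src/lesionboot/glm.py` — voxelwise GLM, permutation/Bonferroni FWE, ROI
- `src/lesionboot/bootstrap.py` — resampling study and table summaries
- `src/lesionboot/model.py` — `LesionDeficitModel` / results objects
- `src/lesionboot/report.py`, `cli.py` — orchestration, tables, figures, CLI

See `docs/methods.md` for the statistical details and design choices.
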
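# Methods

## Model

At each masked voxel, gray-matter density is modeled as a two-level
hierarchical (mixed-effects) linear system over a cohort of `S` subjects:

* **Level 1 (within subject).**  Subject `i`'s trajectory is a polynomial
  in time, default order 1: `y_ij = b_i0 + b_i1 t_ij + e_ij`, with time in
  fractional years since that subject's *first* scan, so the intercept is
  the subject's baseline density.  Scan noise is i.i.d. Gaussian with one
  shared variance across scans and subjects (the smallest identifiable
  basis; a per-subject noise would not be estimable from 2–5 scans).
* **Level 2 (between subjects).**  The stacked trajectory parameters are
  a group mean plus subject-covariate contributions.  Total intracranial
  volume — recorded per image — is reduced to a per-subject mean and
  standardized to zero mean/unit SD across subjects; it enters on every
  trajectory coordinate.  Level 2 is subject-level, so a per-subject
  summary is the only consistent placement for a per-image nuisance
  covariate; the covariate list is configurable (including empty).

Priors on the random effects (`eps(2)`) and on the second-level
coefficients (`theta(2)`) enter the estimation as pseudo-observations of
zero, giving a single augmented least-squares system whose error
covariance is block diagonal:

```
C_eps = blockdiag( lambda_0 I_N,                  scan noise
                   diag per subject of (lambda_int, lambda_slope),
                   c_flat I_q2 )                  second-level prior
```

`c_flat` is fixed at `1e6 ×` the sample variance of the voxel's data —
effectively flat, so the fixed effects are essentially unregularized and
the marginal-likelihood objective behaves like a restricted (REML)
criterion for the variance components, avoiding the downward bias of
plain ML with few subjects.  The random-effect covariance is diagonal
(independent intercept and slope variances shared across subjects); an
intercept–slope covariance component is not implemented.

## Hyperparameter estimation

The three estimable scales `(lambda_0, lambda_int, lambda_slope)` are
estimated by EM on the marginal likelihood: the E-step computes the
Gaussian posterior at the current scales; the M-step re-estimates each
scale as the expected squared augmented error on its support, divided by
the support size.  This update is positive by construction and ascends
the evidence monotonically.  Convergence: relative change in
log-evidence `< 1e-6`, or 128 iterations (dense path; the voxelwise
batch path defaults to 64 and the pipeline passes 128).  Scales are
floored at `1e-10 ×` the data variance to keep the error covariance
nonsingular.

Two implementations share this fixed point:

* a **dense path** operating on one augmented system (the reference used
  in tests and for arbitrary diagonal component bases), and
* a **batched voxel path** that exploits the block structure: each
  subject's `p × p` precision block is inverted analytically (closed
  form for `p = 2`) and the small second-level block is handled by a
  Schur complement, all vectorized across voxels.  Cost per voxel scales
  with `S p^3` instead of the cube of the full parameter count.  Because
  plain EM crawls geometrically when a component approaches zero, the
  batch path lengthens the log-space EM step by an adaptive factor
  (guarded over-relaxation): whenever an extrapolated step decreases the
  evidence, the voxel falls back to the stored plain-EM target, whose
  ascent is guaranteed.  Initial values come from per-subject OLS
  moments (pooled residual variance; between-subject coefficient spread
  minus its estimation noise).  Voxels with constant (e.g. all-zero)
  signal are skipped and flagged.

Within the pipeline, successive participants of interest are fitted
against the same control set; each fit warm-starts from the previous
fit's per-voxel scales, which changes iteration counts but not fixed
points.

## Prediction and deviation scoring

The group posterior is collapsed to subject `i` through the linear map
`theta1_i = X2_i theta(2) + eps(2)_i`.  The posterior predictive at a new
time is Gaussian with mean `X_hat eta1` and variance
`lambda_0 + X_hat C1 X_hat'` — never below the scan-noise floor, and
growing with extrapolation distance.  The deviation score is
`erf(z / sqrt(2))` of the standardized residual `z`; under a correct
model it is the probability-integral transform of a standard normal
(uniform score coverage), which the calibration test checks end to end.
The printed form of the scoring integral in the source material is
typographically corrupted; the implementation uses the unique reading
consistent with its stated [−1, 1] bounds and sign behavior.

Cluster volume at threshold `T < 0` counts voxels with `score <= T`
(inclusive — a voxel exactly at the threshold belongs to the cluster)
times the voxel volume, in cc, with no connected-component filtering.
Growth rates are plain difference quotients between consecutive scans;
the first post-model scan's rate is taken against volume 0 at the last
modeled scan (configurable off), and negative rates are allowed.
Default thresholds: −0.7, −0.8, −0.9, −0.95, −0.99, −0.999.

## Outcome models

Cluster measures are z-scored with the `n−1` SD over all pooled records
of the participants of interest.  The group-by-time model
`V_ij = a0_i + a1_i D_j + e_ij` uses time-to-last-event `D_j` (0 at
conversion for converters, 0 at the last visit otherwise, negative
before) and decomposes `a1_i = b10 + b11 G + u1_i`; it is fitted as a
Gaussian random-intercept/random-slope model via statsmodels MixedLM
(REML), with per-group rates `b10 + b11` and `b10` and delta-method CIs.
Rate tables use raw cc so coefficients read in cc/year; hazard models use
z-scores.  A robust (M-estimating) variant of this fit is not
implemented.

Conversion is defined from the CDR: the first visit with global score
≥ 1; visits with missing CDR are ignored for outcomes but retained for
imaging.  Time-varying Cox models are fitted with lifelines'
`CoxTimeVaryingFitter` (Efron ties): one interval per consecutive pair
of post-model scans, predictor measured at the interval start, event at
the conversion visit, censoring at the last observation, and age at
interval start plus sex (0 = F, 1 = M) as covariates.  A fit that fails
to converge (typically separation at small event counts) is retried with
a small ridge penalty and flagged.

Amyloid positivity uses published tracer cutoffs (PIB 1.5, AV45 1.11,
FBB 1.08); a SUVR exactly at the cutoff counts as negative (strict
inequality, configurable), since a published cutoff is a threshold that
must be exceeded.  ROI measures integrate density over an atlas label
set (`HV`, cc), normalized by TIV (`HVT`), with between-scan differences
(`HR`, `HRT`).

## Synthetic cohorts

The generator emulates the longitudinal VBM setting the model targets:
spatially smooth per-subject intercept and slope fields (Gaussian white
fields smoothed with a 2-voxel kernel, so shrinkage is exercised on
structured signal), i.i.d. Gaussian scan noise, a TIV-like covariate
shifting baseline density, and irregular scan schedules.  Defaults
describe a desk-scale study: 16³ grid of 2 mm voxels, 40 controls (3–5
scans) and 20 participants of interest (6–8 scans) at ~1-year intervals,
density 0.55 ± 0.08 declining 0.005 ± 0.003/year, noise SD 0.02.

Converters (half of the interest group) lose an extra
0.05/year × U(0.6, 1.4) of density inside a ~1.4 cc spherical region
after a per-subject onset 2–3 years into follow-up (piecewise-linear
hinge; pre-onset scans are bit-identical to the unaccelerated draw).
Conversion visits are sampled from a post-onset hazard
`0.25 × exp(20 × true regional loss rate in cc/year)` per year applied
to *all* interest subjects, so a zero link makes conversion independent
of the injection; CDR steps 0 → 0.5 → 1 around the sampled conversion
and never touches the two modeled scans.  The background hazard and the
per-subject acceleration jitter are deliberate: a generator with a
near-deterministic injected-conversion link produces quasi-separated Cox
likelihoods with collapsed Wald tests, which is not the moderate
hazard-ratio regime (≈2–5 per SD) this method operates in on real
at-risk cohorts.

What the phantoms do **not** emulate: anatomy and atlas structure,
spatially correlated scan noise (optional smoothing is available but off
by default), scanner/site effects, registration/segmentation error, and
non-linear trajectories.  Passing tests therefore demonstrate
correctness of the estimation and inference machinery under the model's
own assumptions — not robustness to real-world preprocessing artifacts.

## Numerical choices and problem sizes

* Posterior solves use Cholesky factorizations of the precision; outputs
  are explicitly symmetrized; indefiniteness raises with a condition
  number report.
* The erf deviation of a non-finite observation is flagged (NaN) rather
  than propagated.
* Manifest ingestion sorts canonically by (subject, scan time) and
  converts dates to fractional years (365.25 days/year).
* Test problem sizes are chosen to finish on one CPU in minutes:
  hyperparameter recovery uses 60 subjects × 4 scans × 20 replicates;
  predictive calibration uses 50 subjects × 200 voxels (10,000 held-out
  draws); the end-to-end experiment runs 10 seeded replicates of the
  default 16³ cohort.

## Known limitations

* Diagonal random-effect covariance only; no intercept–slope covariance
  component.
* One shared noise variance across subjects (per-subject noise is a
  documented extension point, not implemented).
* No spatial regularization across voxels, and no multiple-testing
  control across thresholds (per-threshold reporting is intentional).
* Classical Gaussian mixed-model fits; no robust M-estimation.
* Wald confidence intervals for mixed-model fixed effects ignore
  variance-component uncertainty and can undercover slightly at small
  sample sizes.
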
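# Methods

## Latent change score models

All models are linear-Gaussian structural equation models over the
observed vector of baseline and follow-up volumes (mL), held internally
in a RAM form `v = m + A v + ζ`, `Cov(ζ) = S`, over observed plus
latent variables.  Each latent change is defined by fixed unit loadings
on its follow-up measurement; with the atrophy-positive convention the
follow-up loads +1 on the baseline and −1 on the change, so
`follow-up = baseline − change` and positive change is volume loss.
Negating the convention negates the change intercepts and all paths
into the changes while leaving the likelihood unchanged; this
equivalence is tested.

Three variants share one code path:

* **bivariate** — ΔThal and ΔHipp each regressed on both baselines
  (self-feedback β, cross-coupling γ), free baseline moments (μ, φHT),
  change intercepts α, and a free residual covariance block (ψT, ψH,
  ρHT).  14 parameters against 14 sample moments: just identified.
* **age-augmented** — baseline age added as an exogenous predictor of
  both changes (γAge→dH, γAge→dT) with free covariances to both
  baselines.  The between-scan interval is generated as a column but is
  not modelled as a latent change: it is deterministic given the scan
  dates, carries no extra information about the volume trajectories in
  this design, and its "change score" would simply equal the interval
  itself.  20 parameters, 20 moments: again just identified.
* **multigroup** — the same spec fitted per group with a joint
  likelihood; all parameters are free per group by default (matching
  how sex-stratified estimates are usually reported), with optional
  equality constraints across groups.

### Estimation

The complete-data fit minimises the normal-theory discrepancy
`F = ln|Σ(θ)| + tr(S Σ⁻¹) + (m̄−μ)ᵀΣ⁻¹(m̄−μ) − ln|S| − p` with the
sample covariance on the n−1 denominator and χ² = (n−1)·F_min.  The
optimizer (BFGS, gradient tolerance 1e-8, 500 iterations max) starts at
the closed-form solution obtained by regressing the observed difference
scores on the exogenous predictors via the sample moment matrix.  For
every just-identified variant that start *is* the ML optimum, so the
optimizer only has to confirm stationarity; the fit never returns a
discrepancy above the closed-form value.  Variances are optimized on
the log scale; covariances are unconstrained with a positive-definite
guard on the implied covariance — the guard is never active when
starting from the closed form, which keeps one code path across all
variants rather than per-block Cholesky factorizations.

**FIML.**  With missing follow-ups each row contributes the marginal
Gaussian log-density over its observed subset; rows are grouped by
missingness pattern so the objective costs O(#patterns) per evaluation.
Complete data are detected and delegated to the complete-data fit, so
FIML reduces to it exactly.  The FIML χ² against the saturated model is
computed on request (it is identically zero for just-identified
models).

**Standard errors.**  SEs come from the inverse Gaussian information
matrix at the optimum, assembled from central-difference derivatives of
the implied mean and covariance (step 1e-6, relative).  At a
just-identified optimum, where the implied moments equal the sample
moments, this equals the observed information.  Differentiating the
moment maps (first derivatives only) is numerically far more stable
than second-differencing the log-likelihood; a 500-replicate simulation
in the test suite confirms the reported SE of the key coupling matches
the Monte-Carlo SD of its estimates within 15%.  Wald z against the
standard normal gives two-sided p-values.  A singular information
matrix flags the SEs undefined without discarding the fit.

## Synthetic cohort generator

The generator emulates a UK-community aging-cohort structure: a
cross-sectional sample of n = 4348 adults over 60 and a longitudinal
subsample of n = 653 with a repeat scan after ~2.26 years
(IQR 0.33, normal, clipped at 1.5 y).

**Cross-sectional.**  Eleven regional/global volumes are drawn from a
multivariate normal with the preset means and SDs (thalamus
14.95 ± 1.34 mL, hippocampus 7.52 ± 0.85 mL, …, totals in litres) and a
structured correlation matrix whose thalamus–hippocampus entry is
pinned to the covariance 0.76 mL² (r = 0.667); other inter-regional
correlations are set to field-typical values (0.35–0.55) since full
covariance tables are rarely published.  The cognitive composite equals
a 15-term linear predictor (coefficients on the preset's published
scale; e.g. +0.069 per mL thalamus, −0.039 per year of age) plus a
Gaussian residual whose default SD is solved analytically so the
population R² equals 0.09.  DSST and TMT indicator scores are then
produced from the standardized composite through a one-factor
measurement model whose loadings are calibrated (scalar fixed point) so
that the rebuilt regression-score composite correlates 0.66 / −0.78 /
−0.93 with DSST / TMT-A / TMT-B.  TMT times are exponentiated
(log-normal, log-SD 0.12–0.15) to stay positive; the dispersion is kept
modest so the linear factor structure survives the transform — real
completion-time distributions are more strongly skewed.  The numeric
memory score is a weak volumetric signal (R² ≈ 0.027) rounded to the
2–12 digit range.  BMI and diabetes columns are uncalibrated stand-ins
that exist only to drive the propensity-score machinery.

**Longitudinal.**  Baseline pairs come from the preset baseline
moments; latent changes follow the LCS regressions with correlated
residuals; follow-up = baseline − change.  The preset couplings are
γT→dH = −0.048, γH→dT = 0.043, φHT = 0.76 mL², ρHT = 0.03 mL²; change
intercepts are calibrated so the mean changes equal 0.213 (thalamus)
and 0.155 (hippocampus) mL.  Sex-stratified generation overrides the
couplings per group (female −0.057 / 0.049, male −0.040 / 0.008; group
sizes 54.6% / 45.4% of n).  The age block draws (age, baselines)
jointly with covariances −1.63 and −1.10 mL·y, truncates age at 60 by
rejection, and adds γAge→dH = 0.013 mL/y (γAge→dT = 0, reflecting no
detectable age effect on thalamic change).

**Residual-variance calibration.**  A reported residual covariance of
0.03 mL² cannot coexist with change-score SDs of ~0.13 mL (it would
imply a residual correlation near 2).  When a preset is internally
inconsistent in this way the generator preserves the parameters the
recovery studies target — the couplings, covariances and change means —
and sets the residual variances to ψT = ψH = 0.033 mL², the smallest
round value keeping the residual correlation (0.91) safely inside the
unit disc.  The implied change-score SD is then ≈ 0.19 mL rather than
0.13 mL; marginal change dispersion is the one preset moment the
generator deliberately does not honour.  The self-feedback values
βT = βH = 0.02 are a package default (mild positive feedback: larger
structures lose slightly more volume), chosen once; recovery results do
not depend on them.

**Missingness.**  `apply_missingness` blanks all target columns jointly
per selected row — emulating a participant skipping the follow-up visit
— either MCAR or MAR with a logistic model in observed predictors whose
intercept is solved by root-finding so the expected rate matches the
request.  The realized rate is recorded on the output.

**What passing tests do and do not show.**  The generator matches the
analyses' distributional assumptions exactly (multivariate normality,
linear couplings, MCAR/MAR attrition).  Parameter recovery on it
validates the estimators, not the robustness of the original findings
to non-normal volumes, segmentation artefacts, informative attrition,
or practice effects on cognitive tests — none of which are simulated.

## Cross-sectional suite

OLS is solved by QR with classical SEs and two-sided t p-values on
n−k df (the conventional choice; a claimed coefficient/SE pair whose
printed p-value is inconsistent with its own z-ratio is *not*
reproduced — the suite always reports p-values consistent with its
estimates).  VIF_j = 1/(1−R²_j) with perfect collinearity reported as
infinity; the collinearity flag threshold is 5.  FDR control is
Benjamini–Hochberg step-up, order-stable and capped at 1.  The
two-timepoint session test is a REML random-intercept model
(volume ~ session + interval, random intercept per participant) fitted
via statsmodels MixedLM; in this balanced design the session effect
equals the mean within-participant difference, which the tests exploit
as a closed-form oracle.

## Factor composite

With three indicators the one-factor model is just identified, so the
Spearman closed form λ₁ = √(r₁₂r₁₃/r₂₃) (cyclic) is exact and an
iterative principal-axis fit serves as a cross-check in the tests.
Scores are Thomson regression scores λᵀR⁻¹z on indicators standardized
with the n−1 denominator, oriented so a higher composite means better
performance.  A negative radicand or a Heywood loading is rejected
rather than clipped.  The published "49.9% of total variance" figure
depends on unpublished indicator intercorrelations and is used only as
a calibration anchor, not asserted.

## Missing-data machinery

Propensity scores: logistic regression by IRLS (statsmodels GLM), with
perfect separation rejected.  Matching: greedy 1:1 nearest neighbour
without replacement over the smaller group in descending propensity
order (deterministic; order configurable), caliper applied on the
probability scale (default 0.001).  PMM: per imputation, a
normal-inverse-gamma posterior draw of the linear imputation model,
predictions for missing rows from the drawn coefficients and for
observed rows from the point estimates, each missing cell filled by a
uniformly drawn donor among the k = 5 nearest observed predictions
(k configurable; 5 is the common software default).  Imputation *i*
seeds its own generator with base seed + i.  Pooling follows Rubin's
rules with Barnard–Rubin degrees of freedom given the complete-data df.

## Agreement

Bland–Altman with differences (pipeline2 − pipeline1), limits of
agreement bias ± 1.96 SD, and the within-limits fraction; identical
inputs give degenerate limits and a fraction of 1 by convention.  The
paired-pipeline generator adds a constant bias (0.12 mL) plus Gaussian
noise (SD 0.25 mL) to emulate systematic segmentation disagreement.

## Problem sizes and numerical choices

Recovery studies use 200 replicates at the study's own cohort sizes
(n = 653 longitudinal, n = 4348 cross-sectional) and 100 replicates for
the FIML condition, sized so each study resolves its target well inside
the acceptance bands while a full run of the suite plus the recovery
script stays in the low minutes on a single CPU.  Degenerate inputs are
first-class: zero-rate missingness returns an identical table, n = 0
cohorts keep the full schema, constant columns are rejected by
standardization, and a saturated model fits any data with χ² = 0.

## Known limitations

* Volumes are generated unconditionally Gaussian; no floor effects,
  scanner batch effects, or segmentation failures.
* The measurement model links cognition indicators to a single factor;
  real DSST/TMT batteries show test-specific method variance.
* The multigroup engine supports equality constraints but no likelihood
  ratio machinery beyond the χ²/df/log-likelihood it reports; no
  CFI/RMSEA-style fit indices, by design.
* PMM assumes the imputation model's predictors are observed wherever
  targets are missing; nested missingness patterns need sequential
  imputation, which is out of scope.
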
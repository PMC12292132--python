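# Methods

## Model and estimation

Each biometric parameter is modelled marginally (records pooled across
subjects and visits) as a polynomial in gestational age, measured in raw
days. Coefficients are stored ascending (intercept first), matching the
basis expansion φ(x) = [1, x, …, x^d]; published quadratics written as
a·x² + b·x + c are therefore stored as (c, b, a), and I/O layers convert
explicitly.

Both estimators are closed-form. The implementation solves them through a
rank-revealing SVD-based least-squares factorisation (ridge via the
augmented system [Φ; √λ·P]θ = [y; 0]); algebraic equivalence to the
normal-equation forms (Φ'Φ)⁻¹Φ'y and (Φ'Φ+λI)⁻¹Φ'y is asserted by tests
against an independent iterative minimizer of the penalized cost rather
than assumed. Two deliberate, non-obvious choices:

- **The ridge penalty includes the intercept** (penalty matrix is the
  full identity). This is the estimator the reference equations were
  built with, so it is the default; `penalize_intercept=False` gives
  conventional ridge for users who want the intercept exempt.
- **Ages are not centered or rescaled**, so fitted coefficients are
  directly comparable to the published reference equations. The Gram
  matrix of a raw-day quadratic has condition number ≈ 2·10¹¹; the SVD
  path keeps full double-precision accuracy there (verified by the
  noiseless-recovery tests), and a warning is logged above 10¹⁰ because
  users fitting cubics over wide ranges should know they are near the
  edge.

Coefficient uncertainties are classical analytic standard errors:
√diag(s²(Φ'Φ)⁻¹) with s² = SSE/(n−d−1) for OLS, and the sandwich
√diag(s²(Φ'Φ+λP)⁻¹Φ'Φ(Φ'Φ+λP)⁻¹) for ridge, which reduces to the OLS
form at λ = 0. How the published coefficient SDs were computed is not
documented; the analytic covariance is this package's assumption, stated
rather than hidden.

### Degree and penalty selection

Degrees 1–3 are compared by training R²; `select_degree` returns the
smallest degree within ε = 0.005 of the best, formalising "the
improvement is minimal" as a parsimony rule. The default degree is 2
globally: five of the six parameters clearly prefer the quadratic, and
CRL — whose degree-wise pattern is irregular because first-trimester
measurement is noisy — is fitted quadratically for consistency with the
published charts. λ defaults to 0.1; `select_lambda_cv` picks from
{0.01, 0.1, 1, 10} by cross-validated RMSE when requested. Low-order fits
are weakly sensitive to λ, so ties resolve to the smallest candidate.

## Reference bands and flagging

The default band perturbs each fitted coefficient by ±2 of its standard
deviation (upper = θ + 2·SE coefficient-wise, lower the mirror). Because
every basis term x^k is nonnegative for x ≥ 0, lower ≤ mean ≤ upper holds
at every age in range — a property-tested invariant. This coefficient-wise
envelope is what the source charts draw; it is **not** a pointwise
prediction interval, and with large n it is far narrower than the spread
of individual measurements (coefficient SEs shrink as 1/√n). A
conventional constant-width alternative, mean ± 2·RMSE, is available as
`band_mode="rmse"` and is the appropriate choice when the band is meant
to cover individual measurements. Boundary values are classified normal:
only strict exceedance flags, the conservative clinical reading.

Per-day empirical summaries (mean ± 2·sample SD per gestational day) use
denominator n−1 and define the SD as 0 on singleton days so that every
observed day remains plottable.

## Validation protocol

- **Split.** Train size = floor(0.7·n) after a seeded uniform shuffle.
  Floor is the only rounding consistent with the published per-parameter
  train/test counts (e.g. 0.7·985 = 689.5 → 689), which the tests
  reproduce for all six parameters.
- **Cross-validation** runs on the full per-parameter dataset, shuffled
  and dealt into k folds with sizes differing by at most one. Test ages
  may fall outside a training fold's age span, so fold prediction
  explicitly allows extrapolation. A fold with a constant test response
  has undefined R² and is excluded from the mean with a warning.
- **Residual diagnostics.** Normality is summarised by moments
  (|skewness| < 0.5 and |excess kurtosis| < 1 by default) rather than a
  formality test, because with thousands of residuals any formal test
  rejects immaterial departures. Heteroscedasticity is assessed by the
  Spearman rank correlation between |residual| and age — robust, and
  sensitive to any monotone drift in spread — with homoscedasticity
  accepted when p ≥ 0.05. Note the verdict therefore has a 5% false-alarm
  rate by construction on truly homoscedastic data.

## Group comparison

Residuals (observed EFW − fitted mean) are grouped by maternal condition
(gestational diabetes, preeclampsia, control; unlabeled records join the
control group). The omnibus Kruskal–Wallis H uses pooled mid-ranks with
the standard tie correction 1 − Σ(t³−t)/(N³−N) and a chi-square reference
with (groups−1) degrees of freedom; Dunn's pairwise z uses the matching
tie-corrected variance. Whether the source analysis adjusted its pairwise
p-values is unknown; Holm is the default here (uniformly more powerful
than Bonferroni at the same validity), with Bonferroni and unadjusted
selectable.

## Synthetic cohort generator

The generator emulates what the analysis assumes about the data, not
fetal physiology:

- per-parameter quadratic mean curves (the published equations as
  defaults), ages uniform on integer days of each parameter's range
  (CRL 45–100, all others 80–294);
- homoscedastic Gaussian measurement noise, either given as an SD or
  calibrated from a target population R² via
  σ = √(Var(f(X))·(1−R²)/R²), with Var(f(X)) computed exactly by
  enumerating the integer days — defaults are the published quadratic
  determination levels;
- per-parameter record counts matching the source cohort (records are
  dealt to 980 subjects multinomially; a "scan" contributes several
  parameter records, which is why parameter records sum to more than the
  scan count);
- subject-level structure: an optional shared per-subject intercept
  (default SD 0, because the reference analysis pools records with no
  subject effect, and the R² calibration is exact only at 0);
- condition structure: subjects are GDM with probability 0.08, PE with
  0.04; EFW records are shifted by ±0.5 of the EFW noise SD (≈ ±127 g)
  for GDM/PE respectively. The source reports directions but no
  magnitudes or prevalences; these defaults produce the reported
  qualitative pattern at realistic prevalence and are configurable.
- positivity: draws ≤ 0 have their noise redrawn (age kept), up to 100
  retries, then generation fails naming the parameter and age.
  Resampling rather than clipping keeps the noise near-Gaussian away
  from the zero boundary.

Identical spec + seed reproduces the cohort byte-identically.

### What the generator does not emulate

Within-subject longitudinal correlation beyond a shared intercept, visit
scheduling (ages are independent across visits), age-dependent
(heteroscedastic) measurement error, digit preference and other real
ultrasound artefacts, and the EFW formula's deterministic dependence on
the other biometric measurements. Passing tests therefore demonstrate the
pipeline's statistical correctness under the stated generative model, not
clinical validity on real cohorts.

### Known limitation: positivity truncation of early-gestation EFW

The published EFW quadratic crosses zero near day 75, so at the lower end
of its 80–294-day range the mean (≈ 2 g at day 80) is far below the
calibrated homoscedastic noise SD (≈ 254 g at R² = 0.954). There nearly
half of all raw draws are nonpositive, and positivity resampling
truncates the noise distribution, lifting the conditional mean of
generated values to ≈ 210 g in early gestation. A quadratic refit on such
a cohort correctly tracks this conditional mean and therefore deviates
from the pre-truncation generating polynomial by ≈ 5–6% of the curve's
dynamic range (versus ≈ 0.4% when truncation is inactive); the
corresponding recovery check in the acceptance suite documents this
honestly and fails. Generating-curve recovery is instead demonstrated on
abdominal circumference, whose mean stays well above zero everywhere
(max deviation ≈ 0.05% of range at n = 5000). Users simulating
early-gestation EFW should prefer the optional age-dependent noise
multiplier or a later range start. Throughout, "relative deviation of the
predicted mean curve" means max|pred − true| divided by the generating
curve's dynamic range over the age span; pointwise normalisation is
ill-posed wherever the curve approaches zero.

## Problem sizes

Test and acceptance runs use cohorts of 400–5 639 records per parameter
(5 000 for the calibrated recovery checks, the full default cohort of
24 817 records for the end-to-end and group analyses), 10-fold CV, 60
random instances for the optimizer oracle and 100 seeded replicates for
the diagnostics calibration — sizes at which every Monte-Carlo check is
stable to well within its asserted tolerance while the whole suite runs
in seconds.
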
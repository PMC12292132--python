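# fetalgrowth

Population-specific fetal growth reference curves from routine prenatal
ultrasound: closed-form polynomial/ridge regression of six biometric
parameters against gestational age, ±2σ reference bands, real-time anomaly
flagging, validation (70:30 split, 10-fold cross-validation, residual
diagnostics) and rank-based comparison of fetal-weight residuals across
maternal conditions.

## Who this is for

Clinical data teams and biostatisticians building or auditing local growth
references for fetal biometry — abdominal circumference (AC), crown–rump
length (CRL), estimated fetal weight (EFW), head circumference (HC),
biparietal diameter (BPD) and femur length (FL) — where international
charts under- or over-flag the local population. Because clinical cohorts
are rarely shareable, the package includes a synthetic cohort generator
that reproduces the statistical structure of a Taiwanese hospital cohort
(980 pregnancies, 8350 scans), so every stage of the pipeline is testable
without patient data.

## The model

A biometric value $y$ at gestational age $x$ (days) is modelled as a
degree-$d$ polynomial $f(x;\theta)=\phi(x)^\mathsf{T}\theta=\sum_{k=0}^d
\theta_k x^k$, fitted by minimising $J(\theta)=\lVert y-\Phi\theta
\rVert_2^2$ (optionally $+\lambda\lVert\theta\rVert_2^2$) with the closed
forms

$$\hat\theta_{\text{OLS}}=(\Phi^\mathsf{T}\Phi)^{-1}\Phi^\mathsf{T}y,
\qquad
\hat\theta_{\text{ridge}}=(\Phi^\mathsf{T}\Phi+\lambda I)^{-1}\Phi^\mathsf{T}y,$$

solved through a stable least-squares decomposition. Quadratic curves
($d=2$, $\lambda=0.1$) are the default: they explain >95% of variance for
most parameters while staying interpretable. The reference band perturbs
each coefficient by ±2 of its standard deviation; a new measurement
falling strictly outside the band is flagged as a potential anomaly
(growth restriction below, macrosomia above). Model quality is reported
as $R^2 = 1-\mathrm{SS}_{\text{res}}/\mathrm{SS}_{\text{tot}}$ and
$\mathrm{RMSE}=\sqrt{\tfrac1n\sum_i(y_i-\hat y_i)^2}$, validated by a
70:30 split and 10-fold cross-validation. Condition effects are tested on
EFW residuals with a tie-corrected Kruskal–Wallis H test and Dunn's
pairwise post-hoc comparisons (Holm-adjusted).

## Worked example

```python
from fetalgrowth import (
    CohortSpec, GrowthCurveModel, Parameter, BiometricRecord,
    default_references, evaluate_bands, flag_anomaly, generate_cohort,
)

# 1. published reference band: abdominal circumference at day 280
ref = default_references()[Parameter.AC]
mean, lower, upper = evaluate_bands(ref, 280)
print(f"AC at day 280: mean {mean:.2f} cm, band [{lower:.2f}, {upper:.2f}] cm")

rec = BiometricRecord("patient-17", 280, Parameter.AC, 40.0)
print("status:", flag_anomaly(ref, rec).status)

# 2. refit a growth curve on a synthetic cohort
cohort = generate_cohort(CohortSpec(seed=1))
res = GrowthCurveModel.from_dataframe(cohort, Parameter.EFW, degree=2, lam=0.1).fit()
print(res.summary())
```

prints

```
AC at day 280: mean 33.73 cm, band [29.26, 38.21] cm
status: above_upper
Growth curve fit
==========================================================
parameter:      EFW (g)
degree:         2
lambda:         0.1
n obs:          5639
R-squared:      0.957384
RMSE:           233.900084
GA range:       [80, 294] days
----------------------------------------------------------
term                coef         std err
x^0           948.531871       30.098320
x^1           -16.465509        0.344936
x^2             0.090115        0.000913
==========================================================
```

The day-280 mean of 33.73 cm is the published quadratic evaluated at term;
the band is that curve with each coefficient shifted by ±2 standard
deviations, and 40.0 cm falls above it, so the record is flagged. The
refitted synthetic EFW curve explains ~96% of the variance, matching the
determination level the cohort was calibrated to. (The synthetic intercept
differs from the generating curve's because values are resampled to stay
positive where the mean approaches zero in early gestation; see
`docs/methods.md`.)

A command-line surface wraps the same operations:

```sh
fetalgrowth simulate --out cohort.csv --seed 1
fetalgrowth fit --records cohort.csv --parameter AC --out ac.json
fetalgrowth bands --model ac.json --records cohort.csv --out ac_ref.json
fetalgrowth flag --reference ac_ref.json --records cohort.csv --out flags.csv
fetalgrowth validate --records cohort.csv --parameter AC
fetalgrowth groupstats --records cohort.csv
fetalgrowth run --config config.json
```

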
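"""Published Taiwanese fetal-growth reference values used as package defaults.

These are the quadratic mean-growth equations, coefficient standard
deviations, degree-wise coefficients of determination and per-parameter
record counts from a hospital cohort of 980 pregnancies (8350 prenatal
scans). They seed the synthetic cohort generator and provide worked-example
reference bands without access to the original (non-deposited) data.

Coefficients are stored ascending — ``(c, b, a)`` for ``a·x² + b·x + c``
with ``x`` the gestational age in days — matching the basis-expansion
ordering used throughout the package.
"""

from __future__ import annotations

from .records import Parameter

#: Quadratic mean-curve coefficients, ascending (intercept first). Units:
#: cm for all parameters except EFW (grams); x in days.
REFERENCE_COEFFICIENTS: dict[Parameter, tuple[float, float, float]] = {
    Parameter.AC: (-10.973933, 0.209781, -0.000179),
    Parameter.CRL: (-4.886816, 0.097966, 0.000306),
    Parameter.EFW: (445.374781, -11.971466, 0.080322),
    Parameter.HC: (-15.160118, 0.289683, -0.000413),
    Parameter.BPD: (-3.928534, 0.076084, -0.000100),
    Parameter.FL: (-3.968641, 0.061229, -0.000073),
}

#: Standard deviations of the fitted coefficients, ascending (c, b, a).
REFERENCE_COEFFICIENT_SD: dict[Parameter, tuple[float, float, float]] = {
    Parameter.AC: (0.364211, 0.003891, 0.000010),
    Parameter.CRL: (0.626545, 0.015851, 0.000097),
    Parameter.EFW: (51.521103, 0.547088, 0.001388),
    Parameter.HC: (0.334808, 0.003567, 0.000009),
    Parameter.BPD: (0.096205, 0.001029, 0.000003),
    Parameter.FL: (0.078762, 0.000841, 0.000002),
}

#: Training-fit R² by polynomial degree {1: linear, 2: quadratic, 3: cubic}.
REFERENCE_R2_BY_DEGREE: dict[Parameter, dict[int, float]] = {
    Parameter.AC: {1: 0.9617, 2: 0.9650, 3: 0.9653},
    Parameter.CRL: {1: 0.7937, 2: 0.7876, 3: 0.8077},
    Parameter.EFW: {1: 0.9132, 2: 0.9539, 3: 0.9551},
    Parameter.HC: {1: 0.9482, 2: 0.9676, 3: 0.9682},
    Parameter.BPD: {1: 0.9549, 2: 0.9682, 3: 0.9686},
    Parameter.FL: {1: 0.9640, 2: 0.9732, 3: 0.9732},
}

#: Per-parameter record counts of the source cohort (total / train / test
#: under the 70:30 floor-rule split).
REFERENCE_COUNTS: dict[Parameter, tuple[int, int, int]] = {
    Parameter.AC: (4594, 3215, 1379),
    Parameter.CRL: (985, 689, 296),
    Parameter.EFW: (5639, 3947, 1692),
    Parameter.HC: (4495, 3146, 1349),
    Parameter.BPD: (4573, 3201, 1372),
    Parameter.FL: (4531, 3171, 1360),
}

#: Gestational-age ranges (days) over which each reference curve applies.
#: CRL is a first-trimester measurement; the other five span routine
#: second/third-trimester scans to term. The EFW quadratic turns positive
#: near day 75, so its range starts at 80 to keep the mean curve positive.
REFERENCE_GA_RANGE: dict[Parameter, tuple[int, int]] = {
    Parameter.AC: (80, 294),
    Parameter.CRL: (45, 100),
    Parameter.EFW: (80, 294),
    Parameter.HC: (80, 294),
    Parameter.BPD: (80, 294),
    Parameter.FL: (80, 294),
}

#: Cohort-level defaults.
N_SUBJECTS = 980
GDM_PREVALENCE = 0.08
PE_PREVALENCE = 0.04
#: Condition shifts on EFW, in units of the EFW measurement-noise SD.
GDM_EFFECT_SD_UNITS = 0.5
PE_EFFECT_SD_UNITS = -0.5
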
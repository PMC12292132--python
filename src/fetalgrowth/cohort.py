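"""Synthetic longitudinal fetal-biometry cohorts.

The generator emulates the statistical structure the growth-reference
analysis assumes: per-parameter quadratic mean growth against gestational
age, approximately homoscedastic Gaussian measurement noise, records
pooled across 980 subjects, and condition-linked shifts of estimated
fetal weight (gestational diabetes heavier, preeclampsia lighter). Its
defaults reproduce the source cohort's published curves, per-parameter
record counts and determination levels, so downstream fitting,
validation and group comparison are exercised under realistic conditions
without any clinical data.

Noise calibration
-----------------
Rather than guessing a noise SD, a parameter may specify a target
population R². With ages X uniform on the integer days of the range and
value = f(X) + ε, the population R² is Var(f(X)) / (Var(f(X)) + σ²), so

    σ = sqrt( Var(f(X)) · (1 − R²) / R² ),

with Var(f(X)) computed exactly by enumerating the integer days.

Positivity
----------
Near the lower age bound the mean curves approach zero and Gaussian
noise can produce nonpositive measurements; such draws are resampled
(noise redrawn, age kept) up to a bounded retry count, keeping the noise
distribution near-Gaussian away from the bound instead of truncating it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import defaults
from .errors import GenerationError, InvalidParameterError
from .polynomial import polyval_ascending
from .records import Condition, Parameter

RETRY_CAP = 100


def curve_variance(coefficients, ga_range: tuple[int, int]) -> float:
    """Exact variance of the true curve under uniform sampling of the
    integer days of ``ga_range`` (population variance, by enumeration)."""
    lo, hi = int(ga_range[0]), int(ga_range[1])
    if hi < lo:
        raise InvalidParameterError(f"empty ga_range [{lo}, {hi}]")
    days = np.arange(lo, hi + 1, dtype=float)
    f = polyval_ascending(coefficients, days)
    return float(np.var(f))


def calibrate_noise_sd(
    true_coefficients, ga_range: tuple[int, int], target_r2: float
) -> float:
    """Noise SD giving the requested population R² for the generative model."""
    if not 0.0 < target_r2 <= 1.0:
        raise InvalidParameterError(f"target_r2 must be in (0, 1], got {target_r2}")
    var_f = curve_variance(true_coefficients, ga_range)
    return float(np.sqrt(var_f * (1.0 - target_r2) / target_r2))


@dataclass(frozen=True)
class ParameterCurveSpec:
    """Generative description of one biometric parameter.

    Exactly one of ``noise_sd`` / ``target_r2`` must be given.
    """

    coefficients: tuple[float, float, float]
    ga_range: tuple[int, int]
    noise_sd: float | None = None
    target_r2: float | None = None
    n_records: int = 0
    #: optional linear-in-age SD multiplier for robustness testing:
    #: sd(x) = sd · (1 + slope · (x − lo)/(hi − lo)); 0 = homoscedastic
    noise_sd_slope: float = 0.0

    def __post_init__(self) -> None:
        if (self.noise_sd is None) == (self.target_r2 is None):
            raise InvalidParameterError(
                "exactly one of noise_sd / target_r2 must be specified"
            )
        if self.noise_sd is not None and self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.target_r2 is not None and not 0.0 < self.target_r2 <= 1.0:
            raise InvalidParameterError(
                f"target_r2 must be in (0, 1], got {self.target_r2}"
            )
        if int(self.ga_range[0]) >= int(self.ga_range[1]):
            raise InvalidParameterError(f"ga_range min < max required: {self.ga_range}")
        if self.n_records < 0:
            raise InvalidParameterError("n_records must be >= 0")
        if self.noise_sd_slope < 0:
            raise InvalidParameterError("noise_sd_slope must be >= 0")

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        return calibrate_noise_sd(self.coefficients, self.ga_range, self.target_r2)


def _default_parameters() -> dict[Parameter, ParameterCurveSpec]:
    return {
        p: ParameterCurveSpec(
            coefficients=defaults.REFERENCE_COEFFICIENTS[p],
            ga_range=defaults.REFERENCE_GA_RANGE[p],
            target_r2=defaults.REFERENCE_R2_BY_DEGREE[p][2],
            n_records=defaults.REFERENCE_COUNTS[p][0],
        )
        for p in Parameter
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full generative description of a synthetic cohort.

    ``condition_effect_g`` gives additive EFW shifts in grams for GDM and
    PE; when None, the defaults ±0.5 of the EFW noise SD are used.
    ``subject_effect_sd`` is the SD of a per-subject additive intercept
    shared across that subject's records (default 0: the reference
    analysis pools records without subject-level effects).
    """

    n_subjects: int = defaults.N_SUBJECTS
    parameters: Mapping[Parameter, ParameterCurveSpec] = field(
        default_factory=_default_parameters
    )
    subject_effect_sd: float = 0.0
    gdm_prevalence: float = defaults.GDM_PREVALENCE
    pe_prevalence: float = defaults.PE_PREVALENCE
    condition_effect_g: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise InvalidParameterError("n_subjects must be positive")
        if self.subject_effect_sd < 0:
            raise InvalidParameterError("subject_effect_sd must be >= 0")
        if self.gdm_prevalence < 0 or self.pe_prevalence < 0:
            raise InvalidParameterError("prevalences must be >= 0")
        if self.gdm_prevalence + self.pe_prevalence > 1:
            raise InvalidParameterError("prevalences must sum to <= 1")
        object.__setattr__(
            self,
            "parameters",
            {Parameter(k): v for k, v in self.parameters.items()},
        )

    @property
    def visits_per_subject(self) -> float:
        """Mean number of EFW-bearing visits per subject implied by the
        record counts (records are dealt to subjects at random)."""
        total = max((s.n_records for s in self.parameters.values()), default=0)
        return total / self.n_subjects

    def resolved_condition_effects(self) -> dict[Condition, float]:
        if self.condition_effect_g is not None:
            gdm, pe = self.condition_effect_g
        else:
            efw = self.parameters.get(Parameter.EFW)
            sigma = efw.resolved_noise_sd() if efw is not None else 0.0
            gdm = defaults.GDM_EFFECT_SD_UNITS * sigma
            pe = defaults.PE_EFFECT_SD_UNITS * sigma
        return {Condition.GDM: float(gdm), Condition.PE: float(pe),
                Condition.NONE: 0.0}

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "subject_effect_sd": self.subject_effect_sd,
            "gdm_prevalence": self.gdm_prevalence,
            "pe_prevalence": self.pe_prevalence,
            "condition_effect_g": (
                list(self.condition_effect_g)
                if self.condition_effect_g is not None
                else None
            ),
            "seed": self.seed,
            "parameters": {
                p.value: {
                    "coefficients": list(s.coefficients),
                    "ga_range": list(s.ga_range),
                    "noise_sd": s.noise_sd,
                    "target_r2": s.target_r2,
                    "n_records": s.n_records,
                    "noise_sd_slope": s.noise_sd_slope,
                }
                for p, s in self.parameters.items()
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        params = {
            Parameter(code): ParameterCurveSpec(
                coefficients=tuple(s["coefficients"]),
                ga_range=tuple(s["ga_range"]),
                noise_sd=s.get("noise_sd"),
                target_r2=s.get("target_r2"),
                n_records=s.get("n_records", 0),
                noise_sd_slope=s.get("noise_sd_slope", 0.0),
            )
            for code, s in d["parameters"].items()
        }
        eff = d.get("condition_effect_g")
        return cls(
            n_subjects=d["n_subjects"],
            parameters=params,
            subject_effect_sd=d.get("subject_effect_sd", 0.0),
            gdm_prevalence=d.get("gdm_prevalence", defaults.GDM_PREVALENCE),
            pe_prevalence=d.get("pe_prevalence", defaults.PE_PREVALENCE),
            condition_effect_g=tuple(eff) if eff is not None else None,
            seed=d.get("seed", 0),
        )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate a cohort as a canonical records DataFrame.

    Deterministic: identical spec (including seed) yields an identical
    frame. An explicit ``seed`` argument overrides ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_sub = spec.n_subjects
    width = max(4, len(str(n_sub)))
    subject_ids = np.array([f"S{i:0{width}d}" for i in range(n_sub)])

    p_none = 1.0 - spec.gdm_prevalence - spec.pe_prevalence
    cond_codes = rng.choice(
        np.array([c.value for c in (Condition.NONE, Condition.GDM, Condition.PE)]),
        size=n_sub,
        p=[p_none, spec.gdm_prevalence, spec.pe_prevalence],
    )
    subject_u = (
        rng.normal(0.0, spec.subject_effect_sd, size=n_sub)
        if spec.subject_effect_sd > 0
        else np.zeros(n_sub)
    )
    effects = spec.resolved_condition_effects()
    cond_shift = np.array([effects[Condition(c)] for c in cond_codes])

    frames = []
    # fixed parameter order for determinism
    for param in sorted(spec.parameters, key=lambda p: p.value):
        pspec = spec.parameters[param]
        n = pspec.n_records
        if n == 0:
            continue
        sigma = pspec.resolved_noise_sd()
        lo, hi = int(pspec.ga_range[0]), int(pspec.ga_range[1])
        subj = rng.integers(0, n_sub, size=n)
        ages = rng.integers(lo, hi + 1, size=n)
        mean = polyval_ascending(pspec.coefficients, ages.astype(float))
        mean = mean + subject_u[subj]
        if param is Parameter.EFW:
            mean = mean + cond_shift[subj]
        sd = sigma * (
            1.0 + pspec.noise_sd_slope * (ages - lo) / max(hi - lo, 1)
        )
        values = mean + (rng.normal(0.0, sd) if sigma > 0 else np.zeros(n))
        # resample nonpositive draws (noise only), bounded retries
        for _ in range(RETRY_CAP):
            bad = values <= 0
            if not bad.any():
                break
            values[bad] = mean[bad] + rng.normal(0.0, sd[bad])
        else:
            bad = values <= 0
            if bad.any():
                i = int(np.argmax(bad))
                raise GenerationError(
                    f"could not draw a positive {param.value} value at "
                    f"ga_days={int(ages[i])} after {RETRY_CAP} retries "
                    f"(mean {float(mean[i]):.3g}, noise sd {sigma:.3g})"
                )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[subj],
                    "ga_days": ages.astype(np.int64),
                    "parameter": param.value,
                    "value": values,
                    "condition": np.array(
                        [str(c) for c in cond_codes], dtype=object
                    )[subj],
                }
            )
        )
    if not frames:
        raise InvalidParameterError("spec generates no records")
    return pd.concat(frames, ignore_index=True)


def write_provenance(spec: CohortSpec, path: str | Path) -> None:
    """Write the generating spec (including seed) next to a cohort CSV."""
    Path(path).write_text(
        json.dumps({"generator": "fetalgrowth.cohort", "spec": spec.to_dict()},
                   indent=2) + "\n"
    )
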
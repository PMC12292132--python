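"""Reference bands, anomaly flagging and per-day empirical summaries.

The reference band for a parameter is built by perturbing each fitted
coefficient by ±2 of its standard deviation: with mean curve
``a·x² + b·x + c`` and coefficient SDs ``(σc, σb, σa)``, the upper bound
is ``(a+2σa)x² + (b+2σb)x + (c+2σc)`` and the lower bound the mirror
image. Because every basis term ``x^k`` is nonnegative for ``x ≥ 0``,
the ordering lower ≤ mean ≤ upper holds at every nonnegative age.

This coefficient-wise envelope is the band the source reference charts
use; it is not a pointwise prediction interval. A conventional
alternative — mean ± 2·(residual RMSE), a constant-width envelope for
individual measurements — is available via ``band_mode="rmse"``.

A measurement is flagged anomalous only on strict exceedance of a bound
(boundary values count as normal), the conservative clinical reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    InvalidParameterError,
    InvalidStateError,
    RangeError,
)
from .polynomial import GrowthCurveResults, polyval_ascending
from .records import BiometricRecord, Parameter, UNITS

BAND_MODES = ("coefficient", "rmse")


@dataclass(frozen=True)
class GrowthReference:
    """±2σ reference band for one biometric parameter."""

    parameter: Parameter
    mean_coeffs: tuple[float, ...]
    upper_coeffs: tuple[float, ...]
    lower_coeffs: tuple[float, ...]
    ga_range: tuple[float, float]
    units: str
    band_mode: str = "coefficient"

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter.value,
            "units": self.units,
            "band_mode": self.band_mode,
            "mean_coefficients": list(self.mean_coeffs),
            "upper_coefficients": list(self.upper_coeffs),
            "lower_coefficients": list(self.lower_coeffs),
            "ga_range": list(self.ga_range),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthReference":
        return cls(
            parameter=Parameter(d["parameter"]),
            mean_coeffs=tuple(d["mean_coefficients"]),
            upper_coeffs=tuple(d["upper_coefficients"]),
            lower_coeffs=tuple(d["lower_coefficients"]),
            ga_range=tuple(d["ga_range"]),
            units=d["units"],
            band_mode=d.get("band_mode", "coefficient"),
        )


@dataclass(frozen=True)
class AnomalyResult:
    """Classification of one record against a reference band."""

    record: BiometricRecord
    predicted_mean: float
    lower_bound: float
    upper_bound: float
    status: str  # "normal" | "above_upper" | "below_lower"


@dataclass(frozen=True)
class DailySummary:
    """Empirical mean ± 2·SD of one parameter on one gestational day."""

    ga_days: int
    n: int
    mean: float
    sd: float
    upper: float
    lower: float


def build_bands(
    results: GrowthCurveResults,
    band_mode: str = "coefficient",
    parameter: Parameter | None = None,
) -> GrowthReference:
    """Construct the reference band from a fitted growth curve.

    ``band_mode="coefficient"`` perturbs coefficients by ±2·SE (requires
    SEs, i.e. positive residual degrees of freedom);
    ``band_mode="rmse"`` shifts the intercept by ±2·(residual RMSE).
    """
    if band_mode not in BAND_MODES:
        raise InvalidParameterError(
            f"band_mode must be one of {BAND_MODES}, got {band_mode!r}"
        )
    param = parameter or results.parameter
    if param is None:
        raise InvalidParameterError("parameter code required to build a reference")
    mean = np.asarray(results.params, dtype=float)
    if band_mode == "coefficient":
        if results.bse is None:
            raise InvalidStateError(
                "coefficient SEs unavailable (zero residual degrees of freedom); "
                "cannot build a coefficient-wise band"
            )
        delta = 2.0 * np.asarray(results.bse, dtype=float)
        upper, lower = mean + delta, mean - delta
    else:
        shift = np.zeros_like(mean)
        shift[0] = 2.0 * results.rmse
        upper, lower = mean + shift, mean - shift
    return GrowthReference(
        parameter=Parameter(param),
        mean_coeffs=tuple(float(c) for c in mean),
        upper_coeffs=tuple(float(c) for c in upper),
        lower_coeffs=tuple(float(c) for c in lower),
        ga_range=(float(results.ga_range[0]), float(results.ga_range[1])),
        units=UNITS[Parameter(param)],
        band_mode=band_mode,
    )


def build_bands_from_coefficients(
    parameter: Parameter | str,
    mean_coeffs,
    coeff_sd,
    ga_range: tuple[float, float],
) -> GrowthReference:
    """Band directly from published mean coefficients and coefficient SDs
    (no refit), e.g. the default reference tables."""
    param = Parameter(parameter)
    mean = np.asarray(mean_coeffs, dtype=float)
    sd = np.asarray(coeff_sd, dtype=float)
    if mean.shape != sd.shape:
        raise InvalidParameterError("mean_coeffs and coeff_sd must match in length")
    if np.any(sd < 0):
        raise InvalidParameterError("coefficient SDs must be nonnegative")
    return GrowthReference(
        parameter=param,
        mean_coeffs=tuple(float(c) for c in mean),
        upper_coeffs=tuple(float(c) for c in mean + 2.0 * sd),
        lower_coeffs=tuple(float(c) for c in mean - 2.0 * sd),
        ga_range=(float(ga_range[0]), float(ga_range[1])),
        units=UNITS[param],
    )


def evaluate_bands(ref: GrowthReference, age: float) -> tuple[float, float, float]:
    """(mean, lower, upper) of the band at one gestational age."""
    lo, hi = ref.ga_range
    if not lo <= age <= hi:
        raise RangeError(f"age {age:g} outside reference range [{lo:g}, {hi:g}]")
    mean = float(polyval_ascending(ref.mean_coeffs, age))
    lower = float(polyval_ascending(ref.lower_coeffs, age))
    upper = float(polyval_ascending(ref.upper_coeffs, age))
    return mean, lower, upper


def flag_anomaly(ref: GrowthReference, record: BiometricRecord) -> AnomalyResult:
    """Classify one record against the band (boundary counts as normal)."""
    if record.parameter != ref.parameter:
        raise InvalidParameterError(
            f"record parameter {record.parameter.value} does not match "
            f"reference parameter {ref.parameter.value}"
        )
    mean, lower, upper = evaluate_bands(ref, record.ga_days)
    if record.value > upper:
        status = "above_upper"
    elif record.value < lower:
        status = "below_lower"
    else:
        status = "normal"
    return AnomalyResult(
        record=record,
        predicted_mean=mean,
        lower_bound=lower,
        upper_bound=upper,
        status=status,
    )


def flag_frame(ref: GrowthReference, df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized anomaly report for a canonical records DataFrame.

    Returns one row per input record with columns subject_id, ga_days,
    parameter, value, predicted_mean, lower, upper, status.
    """
    sub = df[df["parameter"] == ref.parameter.value]
    ages = sub["ga_days"].to_numpy(float)
    lo, hi = ref.ga_range
    if len(ages) and (ages.min() < lo or ages.max() > hi):
        raise RangeError(
            f"record ages outside reference range [{lo:g}, {hi:g}]"
        )
    mean = polyval_ascending(ref.mean_coeffs, ages)
    lower = polyval_ascending(ref.lower_coeffs, ages)
    upper = polyval_ascending(ref.upper_coeffs, ages)
    values = sub["value"].to_numpy(float)
    status = np.where(
        values > upper, "above_upper", np.where(values < lower, "below_lower", "normal")
    )
    return pd.DataFrame(
        {
            "subject_id": sub["subject_id"].to_numpy(),
            "ga_days": sub["ga_days"].to_numpy(),
            "parameter": sub["parameter"].to_numpy(),
            "value": values,
            "predicted_mean": mean,
            "lower": lower,
            "upper": upper,
            "status": status,
        }
    )


def empirical_daily_summary(df: pd.DataFrame) -> list[DailySummary]:
    """Per-day empirical mean and ±2·SD summaries of one parameter.

    Sample SD uses denominator n−1 and is defined as 0 on days with a
    single observation, so every observed day stays summarizable.
    """
    if df.empty:
        raise InvalidParameterError("no records to summarize")
    codes = df["parameter"].unique()
    if len(codes) != 1:
        raise InvalidParameterError(
            f"records must share one parameter, got {sorted(codes)}"
        )
    out = []
    for day, grp in df.groupby("ga_days", sort=True):
        vals = grp["value"].to_numpy(float)
        n = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        out.append(
            DailySummary(
                ga_days=int(day), n=n, mean=mean, sd=sd,
                upper=mean + 2 * sd, lower=mean - 2 * sd,
            )
        )
    return out


def daily_summary_frame(summaries: Iterable[DailySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def default_references() -> dict[Parameter, GrowthReference]:
    """The six published reference bands (mean coefficients ± 2·SD)."""
    from . import defaults

    return {
        p: build_bands_from_coefficients(
            p,
            defaults.REFERENCE_COEFFICIENTS[p],
            defaults.REFERENCE_COEFFICIENT_SD[p],
            defaults.REFERENCE_GA_RANGE[p],
        )
        for p in Parameter
    }
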
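"""Biometric visit records and their tabular (CSV) representation.

A record is one measurement of one fetal biometric parameter at one
gestational age (in days). Lengths and circumferences are centimetres;
estimated fetal weight is grams. The optional maternal condition label
distinguishes gestational diabetes (GDM) and preeclampsia (PE) from the
control population ("none").
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ParseError


class Parameter(str, enum.Enum):
    """The six fetal biometric parameters."""

    AC = "AC"    #: abdominal circumference (cm)
    CRL = "CRL"  #: crown-rump length (cm)
    EFW = "EFW"  #: estimated fetal weight (g)
    HC = "HC"    #: head circumference (cm)
    BPD = "BPD"  #: biparietal diameter / skull diameter (cm)
    FL = "FL"    #: femur length / thigh length (cm)


class Condition(str, enum.Enum):
    """Maternal condition label attached to a pregnancy."""

    NONE = "none"
    GDM = "GDM"
    PE = "PE"


#: Measurement unit per parameter.
UNITS: dict[Parameter, str] = {
    Parameter.AC: "cm",
    Parameter.CRL: "cm",
    Parameter.EFW: "g",
    Parameter.HC: "cm",
    Parameter.BPD: "cm",
    Parameter.FL: "cm",
}

#: Column order of the canonical CSV record format.
COLUMNS = ("subject_id", "ga_days", "parameter", "value", "condition")


@dataclass(frozen=True)
class BiometricRecord:
    """One visit's measurement of one parameter.

    ``value`` may be any finite number — raw generator draws near the lower
    age bound can be small or (transiently) negative before resampling —
    but ``ga_days`` must be a positive integer and ``parameter`` one of
    the six codes.
    """

    subject_id: str
    ga_days: int
    parameter: Parameter
    value: float
    condition: Condition = Condition.NONE

    def __post_init__(self) -> None:
        if self.ga_days <= 0:
            raise InvalidParameterError(f"ga_days must be positive, got {self.ga_days}")
        if not math.isfinite(self.value):
            raise InvalidParameterError(f"value must be finite, got {self.value}")
        if not isinstance(self.parameter, Parameter):
            object.__setattr__(self, "parameter", Parameter(self.parameter))
        if not isinstance(self.condition, Condition):
            object.__setattr__(self, "condition", Condition(self.condition))

    @property
    def units(self) -> str:
        return UNITS[self.parameter]


def records_to_frame(records: Iterable[BiometricRecord]) -> pd.DataFrame:
    """Pack records into the canonical five-column DataFrame."""
    rows = [
        (r.subject_id, r.ga_days, r.parameter.value, r.value, r.condition.value)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df["ga_days"] = df["ga_days"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return df


def frame_to_records(df: pd.DataFrame) -> list[BiometricRecord]:
    """Unpack the canonical DataFrame into record objects."""
    return [
        BiometricRecord(
            subject_id=str(row.subject_id),
            ga_days=int(row.ga_days),
            parameter=Parameter(row.parameter),
            value=float(row.value),
            condition=Condition(row.condition),
        )
        for row in df.itertuples(index=False)
    ]


def _validate_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: missing required column(s) {missing}")
    if "condition" not in df.columns:
        df["condition"] = Condition.NONE.value
    df = df[list(COLUMNS)].copy()
    df["condition"] = df["condition"].fillna(Condition.NONE.value)
    df.loc[df["condition"].astype(str).str.strip() == "", "condition"] = (
        Condition.NONE.value
    )

    codes = {p.value for p in Parameter}
    conds = {c.value for c in Condition}
    # Row numbers are 1-based data rows (header excluded), for error messages.
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if str(row.parameter) not in codes:
            raise ParseError(
                f"{source}: row {i}: unknown parameter code {row.parameter!r}"
            )
        if str(row.condition) not in conds:
            raise ParseError(
                f"{source}: row {i}: unknown condition label {row.condition!r}"
            )
        try:
            ga = int(row.ga_days)
        except (TypeError, ValueError):
            raise ParseError(
                f"{source}: row {i}: ga_days {row.ga_days!r} is not an integer"
            ) from None
        if ga <= 0:
            raise ParseError(f"{source}: row {i}: ga_days must be positive, got {ga}")
        try:
            v = float(row.value)
        except (TypeError, ValueError):
            raise ParseError(
                f"{source}: row {i}: value {row.value!r} is not numeric"
            ) from None
        if not math.isfinite(v):
            raise ParseError(f"{source}: row {i}: value must be finite, got {v}")
    df["ga_days"] = df["ga_days"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    df["subject_id"] = df["subject_id"].astype(str)
    return df.reset_index(drop=True)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a records CSV into the canonical DataFrame.

    Raises :class:`~fetalgrowth.errors.ParseError` citing the offending
    row for any malformed entry.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"records file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    return _validate_frame(df, str(path))


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical DataFrame as UTF-8 CSV with full precision."""
    df = df[list(COLUMNS)]
    df.to_csv(path, index=False)


def weeks_days_to_days(weeks: int, days: int = 0) -> int:
    """Convert a weeks+days gestational age to days (input convenience;
    ages are stored in days everywhere)."""
    if weeks < 0 or not 0 <= days <= 6:
        raise InvalidParameterError(f"invalid weeks+days: {weeks}w{days}d")
    return 7 * weeks + days


def filter_parameter(df: pd.DataFrame, parameter: Parameter | str) -> pd.DataFrame:
    """Rows of one biometric parameter."""
    code = Parameter(parameter).value
    return df[df["parameter"] == code].reset_index(drop=True)


def column_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(ages, values) arrays from a canonical DataFrame."""
    return df["ga_days"].to_numpy(float), df["value"].to_numpy(float)
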
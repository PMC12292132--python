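"""Residual group comparison: Kruskal–Wallis H and Dunn's post-hoc tests.

Residuals against the fitted mean growth curve are compared across
maternal-condition groups (gestational diabetes, preeclampsia, control).
Both tests use mid-ranks of the pooled sample with the standard tie
correction; the omnibus H is referred to a chi-square distribution with
(groups − 1) degrees of freedom, and Dunn's pairwise z statistics to the
standard normal, with Holm adjustment by default.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError, InvalidStateError, UndefinedStatisticError
from .polynomial import GrowthCurveResults
from .records import Condition, filter_parameter

ADJUSTMENTS = {"holm": "holm", "bonferroni": "bonferroni", "none": None}


@dataclass(frozen=True)
class GroupTestResult:
    """Omnibus Kruskal–Wallis result plus the Dunn pairwise table."""

    group_sizes: dict[str, int]
    H: float
    df: int
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, z, p_raw, p_adjusted
    adjustment: str

    def to_dict(self) -> dict:
        return {
            "group_sizes": self.group_sizes,
            "H": self.H,
            "df": self.df,
            "p_value": self.p_value,
            "adjustment": self.adjustment,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _pooled_ranks(groups: Mapping[str, np.ndarray]):
    labels = list(groups)
    sizes = np.array([len(groups[g]) for g in labels])
    if any(s == 0 for s in sizes):
        raise InvalidParameterError("groups must be nonempty")
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    N = len(pooled)
    ranks = stats.rankdata(pooled)  # mid-ranks
    mean_ranks = {}
    start = 0
    for g, s in zip(labels, sizes):
        mean_ranks[g] = float(ranks[start : start + s].mean())
        start += s
    # tie correction term ΣT = Σ(t³ − t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    sum_t = float(np.sum(counts.astype(float) ** 3 - counts))
    return labels, sizes, N, mean_ranks, sum_t


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis test. Returns (H, df, p)."""
    if len(groups) < 2:
        raise InvalidParameterError("need at least two groups")
    labels, sizes, N, mean_ranks, sum_t = _pooled_ranks(groups)
    if N < 3:
        raise InvalidParameterError(f"need total N >= 3, got {N}")
    correction = 1.0 - sum_t / (N**3 - N)
    if correction == 0.0:
        raise UndefinedStatisticError(
            "all pooled values identical: H undefined (tie correction 0)"
        )
    expected = (N + 1) / 2.0
    h = (
        12.0
        / (N * (N + 1))
        * sum(n_i * (mean_ranks[g] - expected) ** 2 for g, n_i in zip(labels, sizes))
    )
    h /= correction
    df = len(labels) - 1
    p = float(stats.chi2.sf(h, df))
    return float(h), df, p


def dunn_pairwise(
    groups: Mapping[str, Sequence[float]], adjustment: str = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise z comparisons on the pooled mid-ranks.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j)),
    two-sided normal p, adjusted per ``adjustment`` (holm, bonferroni or
    none). Returns a tidy frame of all unordered pairs.
    """
    if adjustment not in ADJUSTMENTS:
        raise InvalidParameterError(
            f"adjustment must be one of {sorted(ADJUSTMENTS)}, got {adjustment!r}"
        )
    if len(groups) < 2:
        raise InvalidParameterError("need at least two groups")
    labels, sizes, N, mean_ranks, sum_t = _pooled_ranks(groups)
    var_term = N * (N + 1) / 12.0 - sum_t / (12.0 * (N - 1))
    if var_term <= 0.0:
        raise UndefinedStatisticError("all pooled values tied: Dunn z undefined")
    rows = []
    for (g1, n1), (g2, n2) in itertools.combinations(zip(labels, sizes), 2):
        se = np.sqrt(var_term * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        rows.append((g1, g2, float(z), float(2.0 * stats.norm.sf(abs(z)))))
    df = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    method = ADJUSTMENTS[adjustment]
    if method is None:
        df["p_adjusted"] = df["p_raw"]
    else:
        df["p_adjusted"] = multipletests(df["p_raw"].to_numpy(), method=method)[1]
    return df


def residuals_by_group(
    results: GrowthCurveResults, df: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Residuals (value − predicted mean) grouped by condition label.

    Records without a condition label join the control group. Empty
    groups are dropped with a warning; fewer than two nonempty groups is
    an error.
    """
    if results.parameter is not None:
        sub = filter_parameter(df, results.parameter)
    else:
        sub = df
    if sub.empty:
        raise InvalidParameterError("no records for the model's parameter")
    ages = sub["ga_days"].to_numpy(float)
    resid = sub["value"].to_numpy(float) - results.predict(ages, extrapolate=True)
    cond = sub["condition"].fillna(Condition.NONE.value).astype(str)
    cond = cond.where(cond.str.strip() != "", Condition.NONE.value)
    out: dict[str, np.ndarray] = {}
    for label in (Condition.GDM.value, Condition.PE.value, Condition.NONE.value):
        vals = resid[(cond == label).to_numpy()]
        if len(vals) == 0:
            warnings.warn(f"condition group {label!r} is empty; dropped")
            continue
        out[label] = vals
    if len(out) < 2:
        raise InvalidStateError(
            "fewer than two nonempty condition groups; group comparison undefined"
        )
    return out


def compare_groups(
    results: GrowthCurveResults, df: pd.DataFrame, adjustment: str = "holm"
) -> GroupTestResult:
    """Full residual group analysis: omnibus H plus Dunn pairwise table."""
    groups = residuals_by_group(results, df)
    H, dof, p = kruskal_wallis(groups)
    pairwise = dunn_pairwise(groups, adjustment=adjustment)
    return GroupTestResult(
        group_sizes={g: int(len(v)) for g, v in groups.items()},
        H=H,
        df=dof,
        p_value=p,
        pairwise=pairwise,
        adjustment=adjustment,
    )
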
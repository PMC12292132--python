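"""Closed-form polynomial least-squares and ridge regression.

The model of a fetal biometric value :math:`y` at gestational age
:math:`x` (days) is a degree-:math:`d` polynomial

.. math:: f(x;\\theta) = \\phi(x)^\\mathsf{T}\\theta = \\sum_{k=0}^{d} \\theta_k x^k,

fitted by minimizing the residual sum of squares, optionally with an L2
coefficient penalty :math:`\\lambda\\lVert\\theta\\rVert_2^2`. Both
estimators have closed forms,

.. math::

    \\hat\\theta_{\\mathrm{OLS}} = (\\Phi^\\mathsf{T}\\Phi)^{-1}\\Phi^\\mathsf{T}y,
    \\qquad
    \\hat\\theta_{\\mathrm{ridge}} = (\\Phi^\\mathsf{T}\\Phi + \\lambda I)^{-1}
        \\Phi^\\mathsf{T}y,

where :math:`\\Phi` is the Vandermonde design matrix. The implementation
solves these through a rank-revealing least-squares decomposition (the
ridge case through the augmented system
:math:`[\\Phi; \\sqrt{\\lambda} I]\\theta = [y; 0]`), which is
algebraically identical to the normal-equation forms but numerically
stable; the equivalence is a tested contract. By default the penalty
matrix is the full identity — the intercept is penalized — because that
is the estimator the reference curves were built with; pass
``penalize_intercept=False`` for conventional ridge.

Ages enter in raw days (no centering or scaling) so fitted coefficients
are directly comparable to published reference equations. The Gram matrix
of a quadratic in raw days is ill-conditioned in the classical sense
(condition number ~1e10); the decomposition handles this in double
precision, and a warning is emitted above ``COND_WARN_THRESHOLD``.

Usage follows the Model/Results convention::

    model = GrowthCurveModel(values, ages, degree=2, lam=0.1)
    res = model.fit()
    res.params, res.bse, res.rsquared, res.rmse
    print(res.summary())
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidParameterError,
    RangeError,
    SingularDesignError,
    UndefinedStatisticError,
)
from .records import Parameter, UNITS, column_arrays, filter_parameter

logger = logging.getLogger(__name__)

#: Gram-matrix condition number above which a warning is logged.
COND_WARN_THRESHOLD = 1e10


# ---------------------------------------------------------------------------
# design matrix and elementary statistics


@dataclass(frozen=True)
class DesignMatrix:
    """Polynomial (Vandermonde) design matrix.

    Row *i* is the basis expansion ``[1, x_i, x_i^2, ..., x_i^d]`` of
    gestational age ``x_i``.
    """

    ages: np.ndarray
    degree: int
    matrix: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        """Number of basis functions, degree + 1."""
        return self.matrix.shape[1]


def build_design_matrix(ages: Sequence[float], degree: int) -> DesignMatrix:
    """Expand ages into the polynomial design matrix of the given degree."""
    if degree < 0:
        raise InvalidParameterError(f"degree must be >= 0, got {degree}")
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1 or ages.size == 0:
        raise InvalidParameterError("ages must be a nonempty 1-D vector")
    if not np.all(np.isfinite(ages)):
        raise InvalidParameterError("ages must be finite")
    matrix = np.vander(ages, degree + 1, increasing=True)
    return DesignMatrix(ages=ages, degree=degree, matrix=matrix)


def r_squared(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    May be negative for fits worse than the mean predictor. Undefined
    (raises) when ``y`` is constant.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise InvalidParameterError("y and y_hat must have equal length")
    if y.size < 2:
        raise InvalidParameterError("need at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("R^2 undefined: y is constant (SS_tot = 0)")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Root mean squared error with divisor ``n``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0 or y.shape != y_hat.shape:
        raise InvalidParameterError("y and y_hat must be nonempty and equal length")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def polyval_ascending(coeffs: Sequence[float], x) -> np.ndarray | float:
    """Evaluate a polynomial with ascending coefficients at x."""
    return np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))


# ---------------------------------------------------------------------------
# fit statistics and results


@dataclass(frozen=True)
class FitStatistics:
    """Goodness-of-fit summary of a single training fit."""

    r2: float
    rmse: float
    n: int
    residuals: np.ndarray


class GrowthCurveModel:
    """Polynomial growth-curve model of a biometric value against age.

    Parameters
    ----------
    endog :
        Measured biometric values (cm, or g for estimated fetal weight).
    ages :
        Gestational ages in days, same length as ``endog``.
    degree :
        Polynomial degree (default 2, the degree used for all six
        reference curves).
    lam :
        Ridge penalty λ ≥ 0; 0 gives ordinary least squares. The
        reference fits use λ = 0.1 for numerical stability.
    parameter :
        Optional biometric code attached to results and serializations.
    penalize_intercept :
        If True (default), λ multiplies the full identity — the literal
        closed form above. If False, the intercept is exempt
        (conventional ridge).
    """

    def __init__(
        self,
        endog: Sequence[float],
        ages: Sequence[float],
        degree: int = 2,
        lam: float = 0.0,
        parameter: Parameter | str | None = None,
        penalize_intercept: bool = True,
    ) -> None:
        if lam < 0:
            raise InvalidParameterError(f"lam must be >= 0, got {lam}")
        self.design = build_design_matrix(ages, degree)
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.shape != self.design.ages.shape:
            raise InvalidParameterError("endog and ages must have equal length")
        if not np.all(np.isfinite(self.endog)):
            raise InvalidParameterError("endog must be finite")
        if lam == 0.0 and self.design.n < self.design.p:
            # OLS needs at least d+1 points; ridge is well posed regardless
            raise InvalidParameterError(
                f"need n >= degree + 1 observations ({self.design.n} < {self.design.p})"
            )
        self.degree = degree
        self.lam = float(lam)
        self.parameter = Parameter(parameter) if parameter is not None else None
        self.penalize_intercept = penalize_intercept
        self.ga_range = (float(self.design.ages.min()), float(self.design.ages.max()))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        parameter: Parameter | str,
        degree: int = 2,
        lam: float = 0.0,
        **kwargs,
    ) -> "GrowthCurveModel":
        """Build the model from a canonical records DataFrame, selecting
        one biometric parameter."""
        sub = filter_parameter(df, parameter)
        if sub.empty:
            raise InvalidParameterError(f"no records for parameter {parameter}")
        ages, values = column_arrays(sub)
        return cls(values, ages, degree=degree, lam=lam, parameter=parameter, **kwargs)

    # -- solver -------------------------------------------------------------

    def fit(self) -> "GrowthCurveResults":
        """Solve the (penalized) least-squares problem in closed form."""
        Phi = self.design.matrix
        n, p = Phi.shape
        if self.lam == 0.0:
            theta, _, rank, sv = np.linalg.lstsq(Phi, self.endog, rcond=None)
            if rank < p:
                raise SingularDesignError(
                    "design matrix is rank deficient (duplicate ages?); "
                    "use ridge regression (lam > 0)"
                )
            cond2 = (sv[0] / sv[-1]) ** 2 if sv[-1] > 0 else np.inf
        else:
            penalty = np.eye(p)
            if not self.penalize_intercept:
                penalty[0, 0] = 0.0
            aug = np.vstack([Phi, np.sqrt(self.lam) * penalty])
            rhs = np.concatenate([self.endog, np.zeros(p)])
            theta, _, _, sv = np.linalg.lstsq(aug, rhs, rcond=None)
            cond2 = (sv[0] / sv[-1]) ** 2 if sv[-1] > 0 else np.inf
        if cond2 > COND_WARN_THRESHOLD:
            logger.warning(
                "Gram matrix condition number %.3g exceeds %.0e; "
                "coefficients remain valid in double precision but consider "
                "ridge or a narrower age range",
                cond2,
                COND_WARN_THRESHOLD,
            )

        fitted = Phi @ theta
        resid = self.endog - fitted
        try:
            r2 = r_squared(self.endog, fitted)
        except UndefinedStatisticError:
            warnings.warn("constant response: R^2 undefined, recorded as NaN")
            r2 = float("nan")
        stats = FitStatistics(
            r2=r2, rmse=rmse(self.endog, fitted), n=n, residuals=resid
        )
        bse = None
        if n > p:
            bse = _coefficient_se(
                Phi, resid, self.lam, self.penalize_intercept
            )
        return GrowthCurveResults(model=self, params=theta, bse=bse, fit_stats=stats)


def _coefficient_se(
    Phi: np.ndarray, resid: np.ndarray, lam: float, penalize_intercept: bool = True
) -> np.ndarray:
    """Analytic coefficient standard errors.

    OLS: sqrt diag of s²(ΦᵀΦ)⁻¹ with s² = SSE/(n−p). Ridge: the sandwich
    sqrt diag of s²(ΦᵀΦ+λP)⁻¹ΦᵀΦ(ΦᵀΦ+λP)⁻¹, which reduces to the OLS
    form at λ = 0.
    """
    n, p = Phi.shape
    s2 = float(resid @ resid) / (n - p)
    # (ΦᵀΦ)⁻¹ via SVD of Φ for numerical robustness at high condition
    U, s, Vt = np.linalg.svd(Phi, full_matrices=False)
    if lam == 0.0:
        cov = (Vt.T * (1.0 / s**2)) @ Vt * s2
    else:
        G = Phi.T @ Phi
        penalty = np.eye(p)
        if not penalize_intercept:
            penalty[0, 0] = 0.0
        M = np.linalg.solve(G + lam * penalty, np.eye(p))
        cov = s2 * (M @ G @ M)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def coefficient_standard_errors(
    dm: DesignMatrix, y: Sequence[float], lam: float = 0.0,
    penalize_intercept: bool = True,
) -> np.ndarray:
    """Standalone coefficient-SE computation for a design/response pair.

    Raises when the residual degrees of freedom ``n − (d+1)`` are zero.
    """
    y = np.asarray(y, dtype=float)
    if dm.n <= dm.p:
        raise UndefinedStatisticError(
            f"coefficient SEs undefined: n={dm.n} <= degree+1={dm.p}"
        )
    if lam == 0.0:
        theta, _, rank, _ = np.linalg.lstsq(dm.matrix, y, rcond=None)
        if rank < dm.p:
            raise SingularDesignError("rank-deficient design; use ridge")
    else:
        penalty = np.eye(dm.p)
        if not penalize_intercept:
            penalty[0, 0] = 0.0
        aug = np.vstack([dm.matrix, np.sqrt(lam) * penalty])
        theta = np.linalg.lstsq(aug, np.concatenate([y, np.zeros(dm.p)]), rcond=None)[0]
    resid = y - dm.matrix @ theta
    return _coefficient_se(dm.matrix, resid, lam, penalize_intercept)


class GrowthCurveResults:
    """Fitted growth curve: coefficient estimates, their uncertainties and
    goodness-of-fit diagnostics.

    Attributes
    ----------
    params : ndarray
        Ascending coefficient vector θ = (θ0, …, θd).
    bse : ndarray or None
        Analytic coefficient standard errors; None when the fit has zero
        residual degrees of freedom.
    """

    def __init__(
        self,
        model: GrowthCurveModel,
        params: np.ndarray,
        bse: np.ndarray | None,
        fit_stats: FitStatistics,
    ) -> None:
        self.model = model
        self.params = params
        self.bse = bse
        self.fit_stats = fit_stats

    # statsmodels-flavoured aliases
    @property
    def rsquared(self) -> float:
        return self.fit_stats.r2

    @property
    def rmse(self) -> float:
        return self.fit_stats.rmse

    @property
    def resid(self) -> np.ndarray:
        return self.fit_stats.residuals

    @property
    def nobs(self) -> int:
        return self.fit_stats.n

    @property
    def degree(self) -> int:
        return self.model.degree

    @property
    def lam(self) -> float:
        return self.model.lam

    @property
    def ga_range(self) -> tuple[float, float]:
        return self.model.ga_range

    @property
    def parameter(self) -> Parameter | None:
        return self.model.parameter

    def predict(self, ages, extrapolate: bool = False) -> np.ndarray | float:
        """Evaluate the fitted curve at the given gestational ages.

        Ages outside the training range raise :class:`RangeError` unless
        ``extrapolate=True``; polynomial extrapolation beyond the data is
        not clinically meaningful.
        """
        scalar = np.isscalar(ages)
        arr = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.ga_range
        if not extrapolate:
            if arr.min() < lo:
                raise RangeError(
                    f"age {arr.min():g} below fitted range minimum {lo:g} "
                    "(pass extrapolate=True to override)"
                )
            if arr.max() > hi:
                raise RangeError(
                    f"age {arr.max():g} above fitted range maximum {hi:g} "
                    "(pass extrapolate=True to override)"
                )
        out = polyval_ascending(self.params, arr)
        return float(out[0]) if scalar else out

    def summary(self) -> str:
        """Human-readable fit report (coefficients at display precision)."""
        name = self.parameter.value if self.parameter else "value"
        unit = UNITS.get(self.parameter, "") if self.parameter else ""
        lines = [
            "Growth curve fit",
            "=" * 58,
            f"parameter:      {name}" + (f" ({unit})" if unit else ""),
            f"degree:         {self.degree}",
            f"lambda:         {self.lam:g}",
            f"n obs:          {self.nobs}",
            f"R-squared:      {self.rsquared:.6f}",
            f"RMSE:           {self.rmse:.6f}",
            f"GA range:       [{self.ga_range[0]:g}, {self.ga_range[1]:g}] days",
            "-" * 58,
            f"{'term':<8}{'coef':>16}{'std err':>16}",
        ]
        for k, theta in enumerate(self.params):
            se = f"{self.bse[k]:>16.6f}" if self.bse is not None else f"{'--':>16}"
            lines.append(f"x^{k:<6}{theta:>16.6f}{se}")
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter.value if self.parameter else None,
            "units": UNITS.get(self.parameter) if self.parameter else None,
            "degree": self.degree,
            "coefficients": [float(c) for c in self.params],
            "lambda": self.lam,
            "coefficient_se": (
                [float(s) for s in self.bse] if self.bse is not None else None
            ),
            "r2": float(self.rsquared),
            "rmse": float(self.rmse),
            "n": int(self.nobs),
            "ga_range": [float(self.ga_range[0]), float(self.ga_range[1])],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


# ---------------------------------------------------------------------------
# functional surface


def fit_ols(dm: DesignMatrix, y: Sequence[float]) -> GrowthCurveResults:
    """Ordinary least squares on a prebuilt design matrix."""
    model = GrowthCurveModel(y, dm.ages, degree=dm.degree, lam=0.0)
    return model.fit()


def fit_ridge(dm: DesignMatrix, y: Sequence[float], lam: float) -> GrowthCurveResults:
    """Ridge regression on a prebuilt design matrix; λ=0 reduces to OLS."""
    model = GrowthCurveModel(y, dm.ages, degree=dm.degree, lam=lam)
    return model.fit()


def select_degree(fits_by_degree: Mapping[int, float], epsilon: float = 0.005) -> int:
    """Smallest polynomial degree whose R² is within ``epsilon`` of the best.

    Formalizes the parsimony rule used to choose the quadratic: a higher
    degree must buy more than ``epsilon`` in R² to be preferred.
    Degrees 1, 2 and 3 must all be present.
    """
    if epsilon < 0:
        raise InvalidParameterError(f"epsilon must be >= 0, got {epsilon}")
    required = {1, 2, 3}
    if not required.issubset(fits_by_degree.keys()):
        missing = sorted(required - set(fits_by_degree))
        raise InvalidParameterError(f"missing degree(s) {missing} in fits_by_degree")
    best = max(fits_by_degree.values())
    for d in sorted(fits_by_degree):
        if best - fits_by_degree[d] <= epsilon:
            return d
    raise AssertionError("unreachable: the best degree always qualifies")
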
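"""Validation protocol: 70:30 split, k-fold cross-validation, residual
diagnostics, and cross-validated ridge-penalty selection.

The train/test split takes ``floor(ratio * n)`` records for training
after a seeded uniform shuffle — the rounding that reproduces the source
cohort's published per-parameter train/test counts exactly.

Cross-validation deals shuffled indices into k folds whose sizes differ
by at most one; each fold serves once as the test set for a model fitted
on the remaining folds, and the test-set coefficient of determination is
recorded per fold.

Residual diagnostics summarize the residual distribution (mean,
skewness, excess kurtosis) and assess heteroscedasticity by the Spearman
rank correlation between |residual| and gestational age — a robust,
direction-free check for spread that drifts with age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError, UndefinedStatisticError
from .polynomial import GrowthCurveModel, r_squared


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test index sets covering ``range(n)`` exactly."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    ratio: float

    @property
    def n(self) -> int:
        return len(self.train_ids) + len(self.test_ids)


@dataclass(frozen=True)
class CVResult:
    """Per-fold test R² of a k-fold cross-validation."""

    per_fold_r2: np.ndarray
    mean_r2: float
    sd_r2: float
    k: int
    n_excluded: int = 0  # folds with undefined R² (constant test response)

    def rounded(self, decimals: int = 2) -> list[float]:
        """Display view at reporting precision."""
        return [round(float(v), decimals) for v in self.per_fold_r2]


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Residual-distribution moments and a heteroscedasticity check.

    ``normal_ok`` and ``homosced_ok`` are pure functions of the
    statistics and the configured thresholds.
    """

    mean_residual: float
    skewness: float
    excess_kurtosis: float
    hetero_rank_corr: float
    hetero_p: float
    normal_ok: bool
    homosced_ok: bool

    def to_dict(self) -> dict:
        return {
            "mean_residual": self.mean_residual,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
            "hetero_rank_corr": self.hetero_rank_corr,
            "hetero_p": self.hetero_p,
            "normal_ok": self.normal_ok,
            "homosced_ok": self.homosced_ok,
        }


def train_test_split(n: int, ratio: float = 0.7, seed: int = 0) -> SplitResult:
    """Seeded uniform split of ``range(n)``; train size is floor(ratio·n)."""
    if n < 2:
        raise InvalidParameterError(f"need n >= 2 to split, got {n}")
    if not 0.0 < ratio < 1.0:
        raise InvalidParameterError(f"ratio must be in (0, 1), got {ratio}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratio * n))
    return SplitResult(
        train_ids=np.sort(perm[:n_train]),
        test_ids=np.sort(perm[n_train:]),
        ratio=ratio,
    )


def _deal_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    perm = np.random.default_rng(seed).permutation(n)
    return [np.asarray(f) for f in np.array_split(perm, k)]


def kfold_cross_validate(
    ages: np.ndarray,
    values: np.ndarray,
    degree: int = 2,
    lam: float = 0.0,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold cross-validation of the polynomial growth-curve fit.

    A fold whose test response is constant has undefined R²; it is
    excluded from the mean with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 2 <= k <= n:
        raise InvalidParameterError(f"need n >= k >= 2, got n={n}, k={k}")
    folds = _deal_folds(n, k, seed)
    r2s: list[float] = []
    n_excluded = 0
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        res = GrowthCurveModel(values[mask], ages[mask], degree=degree, lam=lam).fit()
        # test ages may fall outside the training fold's range
        y_hat = res.predict(ages[fold], extrapolate=True)
        try:
            r2s.append(r_squared(values[fold], y_hat))
        except UndefinedStatisticError:
            warnings.warn("constant test response in one fold: R^2 excluded")
            r2s.append(float("nan"))
            n_excluded += 1
    arr = np.array(r2s)
    valid = arr[~np.isnan(arr)]
    return CVResult(
        per_fold_r2=arr,
        mean_r2=float(valid.mean()) if valid.size else float("nan"),
        sd_r2=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
        k=k,
        n_excluded=n_excluded,
    )


def select_lambda_cv(
    ages: np.ndarray,
    values: np.ndarray,
    degree: int = 2,
    grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
    k: int = 10,
    seed: int = 0,
) -> float:
    """Ridge penalty chosen by cross-validated RMSE over a small grid.

    Low-order polynomial fits are weakly sensitive to λ; ties at display
    precision resolve to the smallest candidate.
    """
    if not grid:
        raise InvalidParameterError("empty lambda grid")
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    folds = _deal_folds(n, k, seed)
    best_lam, best_rmse = None, np.inf
    for lam in sorted(grid):
        if lam < 0:
            raise InvalidParameterError(f"lambda must be >= 0, got {lam}")
        sse = 0.0
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            res = GrowthCurveModel(
                values[mask], ages[mask], degree=degree, lam=lam
            ).fit()
            err = values[fold] - res.predict(ages[fold], extrapolate=True)
            sse += float(err @ err)
        cv_rmse = np.sqrt(sse / n)
        if cv_rmse < best_rmse - 1e-12:
            best_lam, best_rmse = lam, cv_rmse
    return float(best_lam)


def residual_diagnostics(
    ages: np.ndarray,
    residuals: np.ndarray,
    skew_threshold: float = 0.5,
    kurtosis_threshold: float = 1.0,
    alpha: float = 0.05,
) -> ResidualDiagnostics:
    """Normality and homoscedasticity checks on fitted residuals.

    normal_ok: |skewness| < skew_threshold and |excess kurtosis| <
    kurtosis_threshold. homosced_ok: the Spearman correlation of
    |residual| with age is not significant at ``alpha``.
    """
    ages = np.asarray(ages, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    n = len(residuals)
    if n < 10:
        raise InsufficientDataError(f"need n >= 10 residuals, got {n}")
    if len(ages) != n:
        raise InvalidParameterError("ages and residuals must have equal length")
    mean_res = float(residuals.mean())
    abs_res = np.abs(residuals)
    if np.ptp(abs_res) == 0 or np.ptp(ages) == 0:
        warnings.warn(
            "degenerate residuals or ages: rank correlation defined as 0"
        )
        rho, p = 0.0, 1.0
        skew = kurt = 0.0 if np.ptp(residuals) == 0 else None
        if skew is None:
            skew = float(stats.skew(residuals))
            kurt = float(stats.kurtosis(residuals))
    else:
        skew = float(stats.skew(residuals))
        kurt = float(stats.kurtosis(residuals))  # excess (Fisher)
        rho, p = stats.spearmanr(abs_res, ages)
        rho, p = float(rho), float(p)
    return ResidualDiagnostics(
        mean_residual=mean_res,
        skewness=skew,
        excess_kurtosis=kurt,
        hetero_rank_corr=rho,
        hetero_p=p,
        normal_ok=abs(skew) < skew_threshold and abs(kurt) < kurtosis_threshold,
        homosced_ok=p >= alpha,
    )
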
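"""Correlation and stepwise-AIC regression for the wild-catch recovery analysis.

The attribution question: which covariates (nursery-habitat proxy, fishing
effort, sea-surface temperature, hatchery fraction) explain the variation in
annual wild catch?  Plain OLS with greedy AIC-based variable selection, using
the full Gaussian log-likelihood AIC convention (so AIC levels are comparable
with standard statistical software, and differences drive the selection).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PearsonTest",
    "pearson_test",
    "RegressionResult",
    "ols_fit",
    "stepwise_aic",
]


@dataclass
class PearsonTest:
    r: float
    t: float
    p: float
    df: int


def pearson_test(x: np.ndarray, y: np.ndarray) -> PearsonTest:
    """Pearson correlation with the exact t test.

    t = r sqrt(df / (1 - r^2)) on df = n - 2 degrees of freedom, two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    if abs(r) >= 1.0:
        return PearsonTest(r, math.inf if r > 0 else -math.inf, 0.0, df)
    t = r * math.sqrt(df / (1 - r * r))
    p = 2 * float(stats.t.sf(abs(t), df))
    return PearsonTest(r, t, p, df)


@dataclass
class RegressionResult:
    """OLS fit summary with the R-style Gaussian AIC."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    aic: float
    selected: list[str]
    n: int

    def __post_init__(self) -> None:
        if self.df_model + self.df_resid + 1 != self.n:
            raise ValueError("degrees of freedom inconsistent with n")


def gaussian_aic(rss: float, n: int, n_predictors: int) -> float:
    """AIC with the full Gaussian constant: n ln(RSS/n) + n(ln 2pi + 1) + 2(p+2).

    p + 2 parameters: p slopes, the intercept, and the error variance —
    matching the convention of mainstream stepwise-selection tools, so AIC
    *levels* (not just differences) line up with theirs.
    """
    return n * math.log(rss / n) + n * (math.log(2 * math.pi) + 1) + 2 * (n_predictors + 2)


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    _, rdiag = np.linalg.qr(design.to_numpy())
    bad = np.abs(np.diag(rdiag)) < 1e-10 * max(1.0, np.abs(np.diag(rdiag)).max())
    return [c for c, b in zip(design.columns, bad) if b]


def ols_fit(y: np.ndarray | pd.Series, X: pd.DataFrame) -> RegressionResult:
    """Ordinary least squares of y on the columns of X plus an intercept."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if len(X) != n:
        raise ValueError("y and X length mismatch")
    design = sm.add_constant(X.astype(float), has_constant="add")
    if n <= design.shape[1]:
        raise ValueError("need n > number of parameters")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    p = X.shape[1]
    rss = float(res.ssr)
    aic = gaussian_aic(rss, n, p)
    fval = float(res.fvalue) if p > 0 else math.nan
    fp = float(res.f_pvalue) if p > 0 else math.nan
    return RegressionResult(
        res.params, res.bse, res.tvalues, res.pvalues,
        float(res.rsquared), fval, fp,
        int(res.df_model), int(res.df_resid), aic,
        list(X.columns), n,
    )


def stepwise_aic(
    y: np.ndarray | pd.Series,
    X_full: pd.DataFrame,
    direction: str = "backward",
) -> tuple[RegressionResult, list[tuple[str, str, float]]]:
    """Greedy AIC minimization over subsets of the candidate columns.

    Directions: ``backward`` (default; drop from the full model), ``forward``
    (add from the intercept-only model), ``both`` (consider drops and adds
    from the full model each round).  Ties are broken toward the smaller
    model, then alphabetically.  Returns the selected fit and the search
    path as (action, column, resulting AIC) triples, starting with the
    initial model ("start", "", AIC).
    """
    if direction not in {"backward", "forward", "both"}:
        raise ValueError("direction must be backward, forward or both")
    candidates = list(X_full.columns)
    current = [] if direction == "forward" else list(candidates)

    def fit(cols: list[str]) -> RegressionResult:
        return ols_fit(y, X_full[cols])

    best = fit(current)
    path: list[tuple[str, str, float]] = [("start", "", best.aic)]
    while True:
        moves: list[tuple[float, int, str, str, list[str]]] = []
        if direction in {"backward", "both"} and current:
            for col in current:
                cols = [c for c in current if c != col]
                moves.append((fit(cols).aic, len(cols), "drop", col, cols))
        if direction in {"forward", "both"}:
            for col in candidates:
                if col in current:
                    continue
                cols = current + [col]
                moves.append((fit(cols).aic, len(cols), "add", col, cols))
        if not moves:
            break
        # tie-break: lower AIC, then fewer predictors, then column name
        moves.sort(key=lambda m: (m[0], m[1], m[3]))
        aic, _, action, col, cols = moves[0]
        if aic < best.aic - 1e-10:
            current = cols
            best = fit(cols)
            path.append((action, col, best.aic))
        else:
            break
    return best, path
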
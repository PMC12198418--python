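"""Shared statistical primitives: t-tests with effect sizes, standardized OLS, BH-FDR.

Conventions used throughout the package:

* Paired comparisons are one-sample t-tests on the within-pair differences;
  Cohen's delta for paired data is ``mean(diff) / sd(diff)`` (sample sd, ddof=1).
* Independent comparisons use the pooled-variance t-test and
  ``d = (mean_x - mean_y) / sigma_pooled`` with
  ``sigma_pooled = sqrt(((n_x-1)s_x^2 + (n_y-1)s_y^2) / (n_x+n_y-2))``.
* Standardized regression coefficients are obtained by z-scoring both the
  dependent and every independent variable before ordinary least squares.
* One-sided confidence intervals are reported as ``[lower, inf)`` (or
  ``(-inf, upper]``), matching common reporting style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EffectReport",
    "paired_t",
    "independent_t",
    "standardized_ols",
    "fdr_bh",
]


@dataclass
class EffectReport:
    """Result of a mean comparison: difference, CI, t, df, p and Cohen's delta."""

    mean_difference: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float
    d: float
    sidedness: str = "two"

    def to_dict(self) -> dict:
        return {
            "mean_difference": self.mean_difference,
            "ci95": list(self.ci95),
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "d": self.d,
            "sidedness": self.sidedness,
        }


def _check_sidedness(sidedness: str) -> None:
    if sidedness not in {"one", "two"}:
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")


def paired_t(differences: np.ndarray, sidedness: str = "two") -> EffectReport:
    """One-sample t-test of paired differences against zero.

    ``sidedness='one'`` tests the alternative mean > 0 and reports a
    one-sided CI ``[lower, inf)``.
    """
    _check_sidedness(sidedness)
    d = np.asarray(differences, dtype=float).ravel()
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance")
    n = d.size
    df = n - 1
    mean = d.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    if sidedness == "two":
        p = 2 * sps.t.sf(abs(t), df)
        tcrit = sps.t.ppf(0.975, df)
        ci = (mean - tcrit * se, mean + tcrit * se)
    else:
        p = sps.t.sf(t, df)
        tcrit = sps.t.ppf(0.95, df)
        ci = (mean - tcrit * se, np.inf)
    return EffectReport(mean, ci, t, df, p, mean / sd, sidedness)


def independent_t(x: np.ndarray, y: np.ndarray, sidedness: str = "two") -> EffectReport:
    """Pooled-variance two-sample t-test (no Welch correction)."""
    _check_sidedness(sidedness)
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    df = nx + ny - 2
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if pooled_var == 0:
        raise ValueError("pooled variance is zero")
    sigma = np.sqrt(pooled_var)
    mean_diff = x.mean() - y.mean()
    se = sigma * np.sqrt(1 / nx + 1 / ny)
    t = mean_diff / se
    if sidedness == "two":
        p = 2 * sps.t.sf(abs(t), df)
        tcrit = sps.t.ppf(0.975, df)
        ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
    else:
        p = sps.t.sf(t, df)
        tcrit = sps.t.ppf(0.95, df)
        ci = (mean_diff - tcrit * se, np.inf)
    return EffectReport(mean_diff, ci, t, df, p, mean_diff / sigma, sidedness)


@dataclass
class OLSReport:
    """Standardized OLS fit: one row per regressor (beta, CI, t, p)."""

    table: pd.DataFrame
    model: object = field(repr=False, default=None)

    def beta(self, name: str) -> float:
        return float(self.table.loc[name, "beta_sd"])


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (a - a.mean()) / sd


def standardized_ols(y: np.ndarray, X: np.ndarray | pd.DataFrame,
                     names: list[str] | None = None) -> OLSReport:
    """OLS on z-scored dependent and independent variables.

    A constant ``y`` yields all-zero coefficients rather than an error; a
    constant regressor column is a rank problem and raises.
    """
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    Xz = np.column_stack([_zscore(X[:, j]) for j in range(X.shape[1])])
    if np.linalg.matrix_rank(Xz) < Xz.shape[1]:
        raise ValueError("design matrix is rank deficient after z-scoring")
    ysd = y.std(ddof=0)
    if ysd == 0:
        table = pd.DataFrame(
            {"beta_sd": 0.0, "ci_low": 0.0, "ci_high": 0.0, "t": 0.0,
             "df": y.size - X.shape[1] - 1, "p": 1.0},
            index=pd.Index(names, name="regressor"),
        )
        return OLSReport(table)
    yz = (y - y.mean()) / ysd
    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "beta_sd": fit.params[1:],
            "ci_low": np.asarray(ci)[1:, 0],
            "ci_high": np.asarray(ci)[1:, 1],
            "t": fit.tvalues[1:],
            "df": int(fit.df_resid),
            "p": fit.pvalues[1:],
        },
        index=pd.Index(names, name="regressor"),
    )
    return OLSReport(table, fit)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up procedure; returns a boolean discovery mask."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
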
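"""Univariate and covariate-adjusted linear models for cohort outcomes.

Thin layer over statsmodels OLS that reports the quantities the analysis
tables need: unstandardized beta, SE, standardized beta
(beta * sd(x)/sd(y), sample SDs), t, two-sided p, bivariate r (univariate
fits only), model r^2, residual df and n.  Includes the Bonferroni
family-wise threshold helper (alpha / m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "univariate_fit",
    "multiple_regression",
    "bonferroni_alpha",
    "results_to_frame",
]


@dataclass(frozen=True)
class RegressionResult:
    term: str
    beta: float
    se: float
    std_beta: float
    t: float
    p: float
    r2: float
    df_resid: int
    n: int
    r: float | None = None  # bivariate correlation, univariate fits only
    outcome: str = ""


def _clean_xy(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.shape[0] != x.shape[0]:
        raise ValueError(f"length mismatch: y has {y.shape[0]}, x has {x.shape[0]}")
    keep = np.isfinite(y) & np.isfinite(x)
    if keep.sum() < y.shape[0]:
        logger.info("dropping %d rows with missing values", int((~keep).sum()))
    return y[keep], x[keep]


def univariate_fit(
    y: np.ndarray, x: np.ndarray, term: str = "x", outcome: str = "y"
) -> RegressionResult:
    """Simple OLS of ``y`` on ``x`` with the bivariate Pearson r attached."""
    y, x = _clean_xy(y, x)
    n = y.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 complete observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {term!r} is constant")
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    sd_y = y.std(ddof=1)
    std_beta = float(res.slope * x.std(ddof=1) / sd_y) if sd_y > 0 else 0.0
    tval = res.slope / res.stderr if res.stderr > 0 else np.inf
    return RegressionResult(
        term=term,
        beta=float(res.slope),
        se=float(res.stderr),
        std_beta=std_beta,
        t=float(tval),
        p=float(res.pvalue),
        r=r,
        r2=r * r,
        df_resid=n - 2,
        n=n,
        outcome=outcome,
    )


def _collinear_terms(design: pd.DataFrame) -> list[str]:
    x = design.to_numpy(dtype=float)
    full_rank = np.linalg.matrix_rank(x)
    bad = []
    for k, name in enumerate(design.columns):
        reduced = np.delete(x, k, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(name)
    return bad


def multiple_regression(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    covariates: Sequence[str] = ("sex", "education"),
) -> list[RegressionResult]:
    """OLS of ``outcome`` on predictors plus adjustment covariates.

    Returns one :class:`RegressionResult` per predictor and covariate term
    (the intercept is fitted but not reported).  Rows with any missing value
    among the model variables are dropped listwise and logged.
    """
    terms = list(dict.fromkeys([*predictors, *covariates]))
    missing = [c for c in [outcome, *terms] if c not in data.columns]
    if missing:
        raise ValueError(f"variables not in data: {missing}")
    sub = data.loc[:, [outcome, *terms]].astype(float)
    complete = sub.dropna()
    if len(complete) < len(sub):
        logger.info(
            "multiple_regression(%s): dropped %d incomplete rows",
            outcome,
            len(sub) - len(complete),
        )
    n = len(complete)
    if n <= len(terms) + 1:
        raise ValueError(f"n={n} too small for {len(terms)} terms plus intercept")
    design = complete.loc[:, terms]
    if np.linalg.matrix_rank(design.to_numpy()) < len(terms) or any(
        design[t].std(ddof=1) == 0 for t in terms
    ):
        const = [t for t in terms if design[t].std(ddof=1) == 0]
        bad = const or _collinear_terms(design)
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    y = complete[outcome].to_numpy()
    fit = sm.OLS(y, sm.add_constant(design, has_constant="add")).fit()
    sd_y = y.std(ddof=1)
    out = []
    for t in terms:
        beta = float(fit.params[t])
        std_beta = float(beta * design[t].std(ddof=1) / sd_y) if sd_y > 0 else 0.0
        out.append(
            RegressionResult(
                term=t,
                beta=beta,
                se=float(fit.bse[t]),
                std_beta=std_beta,
                t=float(fit.tvalues[t]),
                p=float(fit.pvalues[t]),
                r2=float(fit.rsquared),
                df_resid=int(fit.df_resid),
                n=n,
                outcome=outcome,
            )
        )
    return out


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m controlling the family-wise error rate."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def results_to_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Tabulate results in the analysis-table layout."""
    return pd.DataFrame(
        {
            "outcome": [r.outcome for r in results],
            "term": [r.term for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "std_beta": [r.std_beta for r in results],
            "p": [r.p for r in results],
            "r2": [r.r2 for r in results],
            "n": [r.n for r in results],
        }
    )
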
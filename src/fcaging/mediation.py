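"""Parallel-mediator path analysis with non-parametric bootstrap inference.

The standard parallel model: each mediator M_j is regressed on the exposure
X (a-path), the outcome Y is regressed on X and all mediators jointly
(c'-path and b-paths), and the total effect c comes from regressing Y on X
alone.  Indirect effects are the products a_j * b_j and, with ordinary
least squares throughout, satisfy the exact decomposition

    c  =  c'  +  sum_j a_j * b_j.

Inference uses case resampling of subjects with replacement: percentile (or
bias-corrected) confidence intervals and a two-sided bootstrap p-value
2 * min(P(est <= 0), P(est >= 0)) per effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MediationModel",
    "EffectEstimate",
    "MediationResult",
    "fit_paths",
    "bootstrap_mediation",
    "sobel_test",
]


@dataclass(frozen=True)
class MediationModel:
    """Variable roles for a parallel-mediator model.

    With ``a_paths_adjust_mediators`` each a-path equation additionally
    conditions on the other mediators; note the exact decomposition identity
    c = c' + sum(a_j b_j) is guaranteed only in the standard mode (off).
    """

    exposure: str
    mediators: tuple[str, ...]
    outcome: str
    covariates: tuple[str, ...] = ()
    a_paths_adjust_mediators: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "mediators", tuple(self.mediators))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not self.mediators:
            raise ValueError("at least one mediator is required")
        if self.exposure in self.mediators:
            raise ValueError("exposure cannot be a mediator")
        if self.outcome in self.mediators or self.outcome == self.exposure:
            raise ValueError("outcome must differ from exposure and mediators")

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.exposure, *self.mediators, self.outcome, *self.covariates)


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    std_beta: float
    se: float | None = None
    p: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class MediationResult:
    """Point estimates (and, after bootstrapping, CIs and p-values).

    ``effects`` is keyed by ``total``, ``direct``, ``a_<mediator>``,
    ``b_<mediator>``, ``indirect_<mediator>`` and ``indirect_sum``.
    """

    model: MediationModel
    n: int
    effects: Mapping[str, EffectEstimate]
    n_boot: int = 0

    @property
    def total(self) -> float:
        return self.effects["total"].estimate

    @property
    def direct(self) -> float:
        return self.effects["direct"].estimate

    def indirect(self, mediator: str) -> float:
        return self.effects[f"indirect_{mediator}"].estimate

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append(
                {
                    "effect": name,
                    "estimate": e.estimate,
                    "se": e.se,
                    "std_beta": e.std_beta,
                    "p": e.p,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# point estimation


def _extract(data: pd.DataFrame, model: MediationModel) -> np.ndarray:
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise ValueError(f"missing variable(s) in data: {missing}")
    sub = data.loc[:, list(model.variables)].astype(float).dropna()
    arr = sub.to_numpy()
    n_terms = 1 + len(model.mediators) + len(model.covariates)
    if arr.shape[0] <= n_terms + 2:
        raise ValueError(f"n={arr.shape[0]} too small for {n_terms} model terms")
    return arr


def _ols(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design in path regression")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return coef


def _effect_names(model: MediationModel) -> list[str]:
    names = ["total", "direct"]
    for m in model.mediators:
        names += [f"a_{m}", f"b_{m}", f"indirect_{m}"]
    names.append("indirect_sum")
    return names


def _path_estimates(arr: np.ndarray, model: MediationModel) -> dict[str, float]:
    """All path effects from a (n, variables) array; column order follows
    ``model.variables``: exposure, mediators..., outcome, covariates..."""
    k = len(model.mediators)
    x = arr[:, 0]
    med = arr[:, 1 : 1 + k]
    y = arr[:, 1 + k]
    cov = arr[:, 2 + k :]
    ones = np.ones((arr.shape[0], 1))

    d_total = np.hstack([ones, x[:, None], cov])
    total = _ols(y, d_total)[1]
    d_out = np.hstack([ones, x[:, None], med, cov])
    out_coef = _ols(y, d_out)
    direct = out_coef[1]
    b = out_coef[2 : 2 + k]
    a = np.empty(k)
    for j in range(k):
        others = np.delete(med, j, axis=1) if model.a_paths_adjust_mediators else np.empty((arr.shape[0], 0))
        d_a = np.hstack([ones, x[:, None], cov, others])
        a[j] = _ols(med[:, j], d_a)[1]
    eff: dict[str, float] = {"total": float(total), "direct": float(direct)}
    for j, m in enumerate(model.mediators):
        eff[f"a_{m}"] = float(a[j])
        eff[f"b_{m}"] = float(b[j])
        eff[f"indirect_{m}"] = float(a[j] * b[j])
    eff["indirect_sum"] = float(np.sum(a * b))
    return eff


def _standardize_effects(
    eff: Mapping[str, float], arr: np.ndarray, model: MediationModel
) -> dict[str, float]:
    """Scale unstandardized effects to the z-scored-variable metric."""
    k = len(model.mediators)
    sd = arr.std(axis=0, ddof=1)
    sd_x, sd_y = sd[0], sd[1 + k]
    out: dict[str, float] = {}
    for name, v in eff.items():
        if name in ("total", "direct", "indirect_sum") or name.startswith("indirect_"):
            out[name] = v * sd_x / sd_y
        elif name.startswith("a_"):
            m = name[2:]
            out[name] = v * sd_x / sd[1 + model.mediators.index(m)]
        elif name.startswith("b_"):
            m = name[2:]
            out[name] = v * sd[1 + model.mediators.index(m)] / sd_y
    return out


def fit_paths(data: pd.DataFrame, model: MediationModel) -> MediationResult:
    """Point estimates of all paths, indirect, direct and total effects."""
    arr = _extract(data, model)
    eff = _path_estimates(arr, model)
    std = _standardize_effects(eff, arr, model)
    effects = {
        name: EffectEstimate(estimate=eff[name], std_beta=std[name])
        for name in _effect_names(model)
    }
    return MediationResult(model=model, n=arr.shape[0], effects=effects)


# ---------------------------------------------------------------------------
# bootstrap


def _batched_slope(
    db: np.ndarray, pred_cols: Sequence[int], y_col: int
) -> np.ndarray:
    """Coefficients of y ~ 1 + data[:, pred_cols] per resample batch.

    ``db`` has shape (B, n, V); returns (B, 1 + len(pred_cols)).
    """
    b_, n, _ = db.shape
    x = np.concatenate([np.ones((b_, n, 1)), db[:, :, list(pred_cols)]], axis=2)
    y = db[:, :, y_col]
    xtx = np.einsum("bni,bnj->bij", x, x)
    xty = np.einsum("bni,bn->bi", x, y)
    return np.linalg.solve(xtx, xty[..., None])[..., 0]


def _batch_effects(db: np.ndarray, model: MediationModel) -> dict[str, np.ndarray]:
    """Per-resample path effects; column layout as in ``model.variables``."""
    k = len(model.mediators)
    v = db.shape[2]
    cov_cols = list(range(2 + k, v))
    x_col, y_col = 0, 1 + k
    med_cols = list(range(1, 1 + k))

    total = _batched_slope(db, [x_col, *cov_cols], y_col)[:, 1]
    out_coef = _batched_slope(db, [x_col, *med_cols, *cov_cols], y_col)
    direct = out_coef[:, 1]
    b = out_coef[:, 2 : 2 + k]
    a = np.empty((db.shape[0], k))
    for j in range(k):
        others = [c for c in med_cols if c != med_cols[j]] if model.a_paths_adjust_mediators else []
        a[:, j] = _batched_slope(db, [x_col, *cov_cols, *others], med_cols[j])[:, 1]
    eff = {"total": total, "direct": direct}
    for j, m in enumerate(model.mediators):
        eff[f"a_{m}"] = a[:, j]
        eff[f"b_{m}"] = b[:, j]
        eff[f"indirect_{m}"] = a[:, j] * b[:, j]
    eff["indirect_sum"] = (a * b).sum(axis=1)
    return eff


def _bc_interval(draws: np.ndarray, point: float, alpha: float) -> tuple[float, float]:
    """Bias-corrected percentile interval."""
    frac = np.clip(np.mean(draws < point), 1e-8, 1 - 1e-8)
    z0 = stats.norm.ppf(frac)
    zlo, zhi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    plo, phi = stats.norm.cdf([2 * z0 + zlo, 2 * z0 + zhi])
    lo, hi = np.percentile(draws, [100 * plo, 100 * phi])
    return float(lo), float(hi)


def bootstrap_mediation(
    data: pd.DataFrame,
    model: MediationModel,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_type: str = "percentile",
    alpha: float = 0.05,
) -> MediationResult:
    """Case-resampling bootstrap of all mediation effects.

    Subjects are resampled with replacement ``n_boot`` times; per effect the
    95% (``1 - alpha``) percentile CI, the bootstrap SE and the two-sided
    sign-based p-value are reported.  A resample with a constant exposure is
    redrawn (and logged).  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is very small for percentile intervals",
            stacklevel=2,
        )
    if ci_type not in ("percentile", "bc"):
        raise ValueError(f"ci_type must be 'percentile' or 'bc', got {ci_type!r}")
    arr = _extract(data, model)
    n, v = arr.shape
    point = _path_estimates(arr, model)
    std_point = _standardize_effects(point, arr, model)

    rng = np.random.default_rng(seed)
    names = _effect_names(model)
    draws = {name: np.empty(n_boot) for name in names}
    chunk = max(1, min(500, int(2e7 / (n * v))))
    done = 0
    redrawn = 0
    while done < n_boot:
        c = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(c, n))
        # redraw degenerate resamples (constant exposure)
        while True:
            xb = arr[idx, 0]
            bad = np.flatnonzero(np.ptp(xb, axis=1) == 0)
            if bad.size == 0:
                break
            redrawn += bad.size
            idx[bad] = rng.integers(0, n, size=(bad.size, n))
        db = arr[idx]  # (c, n, V)
        eff = _batch_effects(db, model)
        for name in names:
            draws[name][done : done + c] = eff[name]
        done += c
    if redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", redrawn)

    effects: dict[str, EffectEstimate] = {}
    for name in names:
        d = draws[name]
        if ci_type == "percentile":
            lo, hi = np.percentile(d, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        else:
            lo, hi = _bc_interval(d, point[name], alpha)
        p = 2 * min(float(np.mean(d <= 0)), float(np.mean(d >= 0)))
        effects[name] = EffectEstimate(
            estimate=point[name],
            std_beta=std_point[name],
            se=float(d.std(ddof=1)),
            p=min(1.0, p),
            ci_low=float(lo),
            ci_high=float(hi),
        )
    return MediationResult(model=model, n=n, effects=effects, n_boot=n_boot)


def sobel_test(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Normal-theory test of an indirect effect a*b (z statistic, p-value)."""
    se = np.sqrt(a * a * se_b * se_b + b * b * se_a * se_a)
    if se == 0:
        raise ValueError("zero standard error in Sobel test")
    z = a * b / se
    return float(z), float(2 * stats.norm.sf(abs(z)))
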
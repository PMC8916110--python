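"""Network-based statistic (NBS) with permutation family-wise-error control.

Mass-univariate edge-wise linear models give a t-statistic per ROI pair for
the association between functional connectivity and a subject-level
predictor (age).  Edges whose t exceeds a primary threshold (default 3.2)
form a graph; its connected components are the candidate subnetworks.
Significance is assessed by permuting the predictor across subjects,
recording the maximal suprathreshold component size (edge count) of each
permutation, and reporting for each observed component the proportion of
permutations whose maximal size reaches it - the FWE-corrected p-value over
all components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import ConnectomeStack

logger = logging.getLogger(__name__)

__all__ = [
    "NBSConfig",
    "EdgeStats",
    "Component",
    "ComponentResult",
    "edge_statistics",
    "suprathreshold_components",
    "nbs_test",
    "component_edge_mask",
    "node_degree_table",
]

T_SENTINEL = 1e6  # stands in for an infinite t on a perfectly fitted edge
_PERM_CHUNK = 250


@dataclass(frozen=True)
class NBSConfig:
    """Settings for the NBS permutation test.

    ``direction='negative'`` tests for connectivity decreasing with the
    predictor (the primary aging contrast); ``'positive'`` for increases.
    ``permutation_scheme`` is ``'simple'`` (permute the predictor) without
    covariates and Freedman-Lane residual permutation with them.
    ``add_one_correction`` switches the FWE p from the plain proportion to
    the (k+1)/(n+1) variant.
    """

    t_threshold: float = 3.2
    n_permutations: int = 5000
    direction: str = "negative"
    include_covariates: bool = False
    seed: int = 0
    size_metric: str = "edge_count"
    add_one_correction: bool = False

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError(f"t_threshold must be positive, got {self.t_threshold}")
        if self.n_permutations < 1:
            raise ValueError(
                f"n_permutations must be >= 1, got {self.n_permutations}"
            )
        if self.direction not in ("negative", "positive"):
            raise ValueError(f"direction must be 'negative' or 'positive', got {self.direction!r}")
        if self.size_metric != "edge_count":
            raise ValueError("only the edge_count size metric is supported")


@dataclass(frozen=True)
class EdgeStats:
    """Per-edge t map over the upper triangle (i < j)."""

    t: np.ndarray  # (E,), NaN for excluded (constant) edges
    i: np.ndarray
    j: np.ndarray
    n: int
    df: int
    excluded: tuple[int, ...] = ()  # indices into the edge arrays

    def as_matrix(self, n_rois: int) -> np.ndarray:
        out = np.full((n_rois, n_rois), np.nan)
        out[self.i, self.j] = self.t
        out[self.j, self.i] = self.t
        np.fill_diagonal(out, 0.0)
        return out


@dataclass(frozen=True)
class Component:
    """A suprathreshold connected component (candidate subnetwork)."""

    edges: tuple[tuple[int, int, float], ...]  # (i, j, t)
    nodes: frozenset[int]
    degrees: dict[int, int]
    size: int  # edge count

    def __post_init__(self) -> None:
        if self.size != len(self.edges):
            raise ValueError("size must equal the number of edges")


@dataclass(frozen=True)
class ComponentResult(Component):
    """A component with its permutation null and FWE-corrected p-value."""

    fwe_p: float = 1.0
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


# ---------------------------------------------------------------------------
# edge-wise statistics


def _stack_edges(stack: ConnectomeStack | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    data = stack.data if isinstance(stack, ConnectomeStack) else np.asarray(stack, dtype=float)
    if data.ndim != 3 or data.shape[1] != data.shape[2]:
        raise ValueError(f"stack must be (S, N, N), got {data.shape}")
    iu, ju = np.triu_indices(data.shape[1], 1)
    return data[:, iu, ju], iu, ju


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    z = np.ones((n, 1))
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise ValueError("covariates length must match number of subjects")
        z = np.hstack([z, c])
    return z


def _residualize(a: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residual of columns of ``a`` after projection onto span(q) (q orthonormal)."""
    return a - q @ (q.T @ a)


def _t_from_r(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return r * np.sqrt(df) / np.sqrt(1.0 - r * r)


def edge_statistics(
    stack: ConnectomeStack | np.ndarray,
    predictor: Sequence[float],
    covariates: np.ndarray | None = None,
) -> EdgeStats:
    """t-statistic of the predictor's slope in a per-edge linear model.

    Simple regression of each edge on the predictor by default; with
    ``covariates`` the slope is covariate-adjusted (partial-correlation t).
    Edges constant across subjects are excluded (t = NaN) and logged; a
    perfectly fitted edge gets the sentinel +/-``T_SENTINEL``.
    """
    y, iu, ju = _stack_edges(stack)
    x = np.asarray(predictor, dtype=float).ravel()
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError(f"predictor length {x.shape[0]} != number of subjects {n}")
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    z = _design(n, covariates)
    q, _ = np.linalg.qr(z)
    df = n - z.shape[1] - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    rx = _residualize(x[:, None], q)[:, 0]
    ry = _residualize(y, q)
    ny = np.linalg.norm(ry, axis=0)
    nx_ = np.linalg.norm(rx)
    # a constant edge has zero residual variance up to projection round-off
    excluded = np.flatnonzero((np.ptp(y, axis=0) == 0) | (ny == 0))
    ny = ny.copy()
    ny[excluded] = 0.0
    if excluded.size:
        logger.warning("excluding %d constant edges from the t map", excluded.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rx @ ry) / (nx_ * ny)
    perfect = np.abs(r) >= 1 - 1e-12
    if np.any(perfect[np.isfinite(r)]):
        logger.warning(
            "capping %d perfectly fitted edges at |t| = %g",
            int(perfect[np.isfinite(r)].sum()),
            T_SENTINEL,
        )
    t = _t_from_r(r, df)
    t[perfect] = np.sign(r[perfect]) * T_SENTINEL
    t[excluded] = np.nan
    return EdgeStats(t=t, i=iu, j=ju, n=n, df=df, excluded=tuple(int(k) for k in excluded))


# ---------------------------------------------------------------------------
# components


def _suprathreshold_mask(t: np.ndarray, t_threshold: float, direction: str) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if direction == "negative":
            return t < -t_threshold
        if direction == "positive":
            return t > t_threshold
    raise ValueError(f"direction must be 'negative' or 'positive', got {direction!r}")


def suprathreshold_components(
    stats: EdgeStats, t_threshold: float, direction: str = "negative"
) -> list[Component]:
    """Connected components of the suprathreshold edge graph.

    Components are sorted by size (edge count) descending, ties by smallest
    node index.  An empty list is a valid result.
    """
    mask = _suprathreshold_mask(stats.t, t_threshold, direction)
    g = nx.Graph()
    for i, j, t in zip(stats.i[mask], stats.j[mask], stats.t[mask]):
        g.add_edge(int(i), int(j), t=float(t))
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        edges = tuple(
            sorted((min(u, v), max(u, v), d["t"]) for u, v, d in sub.edges(data=True))
        )
        comps.append(
            Component(
                edges=edges,
                nodes=frozenset(int(v) for v in nodes),
                degrees={int(v): int(d) for v, d in sub.degree()},
                size=sub.number_of_edges(),
            )
        )
    comps.sort(key=lambda c: (-c.size, min(c.nodes)))
    return comps


def _max_component_size(ei: np.ndarray, ej: np.ndarray) -> int:
    """Largest connected-component edge count via union-find (hot path)."""
    parent: dict[int, int] = {}

    def find(u: int) -> int:
        root = u
        while parent[root] != root:
            root = parent[root]
        while parent[u] != root:  # path compression
            parent[u], u = root, parent[u]
        return root

    for u, v in zip(ei.tolist(), ej.tolist()):
        if u not in parent:
            parent[u] = u
        if v not in parent:
            parent[v] = v
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    counts: dict[int, int] = {}
    for u in ei.tolist():
        r = find(u)
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values()) if counts else 0


# ---------------------------------------------------------------------------
# the permutation test


def _null_max_sizes_simple(
    yn: np.ndarray,
    xn: np.ndarray,
    df: int,
    ei: np.ndarray,
    ej: np.ndarray,
    config: NBSConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution by permuting the predictor (no covariates).

    ``yn``: centered unit-norm edge columns; ``xn``: centered unit-norm
    predictor.  Permutations are evaluated in chunks through one matrix
    product per chunk.
    """
    n = xn.shape[0]
    thr = config.t_threshold
    out = np.empty(config.n_permutations, dtype=int)
    done = 0
    while done < config.n_permutations:
        c = min(_PERM_CHUNK, config.n_permutations - done)
        perms = np.stack([rng.permutation(n) for _ in range(c)])
        r = xn[perms] @ yn  # (c, E)
        t = _t_from_r(r, df)
        mask = _suprathreshold_mask(t, thr, config.direction)
        for k in range(c):
            row = mask[k]
            out[done + k] = (
                _max_component_size(ei[row], ej[row]) if row.any() else 0
            )
        done += c
    return out


def _null_max_sizes_freedman_lane(
    ry: np.ndarray,
    rx: np.ndarray,
    q: np.ndarray,
    df: int,
    ei: np.ndarray,
    ej: np.ndarray,
    config: NBSConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Freedman-Lane null: permute reduced-model residuals of the edges."""
    n = rx.shape[0]
    nx_ = np.linalg.norm(rx)
    out = np.empty(config.n_permutations, dtype=int)
    for p in range(config.n_permutations):
        perm = rng.permutation(n)
        ryp = _residualize(ry[perm], q)
        ny = np.linalg.norm(ryp, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (rx @ ryp) / (nx_ * ny)
        t = _t_from_r(r, df)
        mask = _suprathreshold_mask(t, config.t_threshold, config.direction)
        out[p] = _max_component_size(ei[mask], ej[mask]) if mask.any() else 0
    return out


def nbs_test(
    stack: ConnectomeStack | np.ndarray,
    predictor: Sequence[float],
    config: NBSConfig | None = None,
    covariates: np.ndarray | None = None,
) -> list[ComponentResult]:
    """Run the full NBS: observed components plus permutation FWE p-values.

    The corrected p of each observed component is the proportion of
    permutations whose maximal suprathreshold component size is at least the
    observed size.  Deterministic given ``config.seed``.
    """
    config = config or NBSConfig()
    cov = covariates if config.include_covariates else None
    if covariates is not None and not config.include_covariates:
        logger.info("covariates supplied but include_covariates is off; ignoring them")
    stats = edge_statistics(stack, predictor, cov)
    observed = suprathreshold_components(stats, config.t_threshold, config.direction)

    y, iu, ju = _stack_edges(stack)
    x = np.asarray(predictor, dtype=float).ravel()
    rng = np.random.default_rng(config.seed)
    if cov is None:
        xc = x - x.mean()
        xn = xc / np.linalg.norm(xc)
        yc = y - y.mean(axis=0)
        ny = np.linalg.norm(yc, axis=0)
        const = (np.ptp(y, axis=0) == 0) | (ny == 0)
        yn = yc / np.where(const, 1.0, ny)
        yn[:, const] = 0.0  # constant edges can never be suprathreshold
        null = _null_max_sizes_simple(yn, xn, stats.df, iu, ju, config, rng)
    else:
        z = _design(y.shape[0], cov)
        q, _ = np.linalg.qr(z)
        rx = _residualize(x[:, None], q)[:, 0]
        ry = _residualize(y, q)
        null = _null_max_sizes_freedman_lane(ry, rx, q, stats.df, iu, ju, config, rng)

    results = []
    for comp in observed:
        ge = int((null >= comp.size).sum())
        if config.add_one_correction:
            p = (ge + 1) / (config.n_permutations + 1)
        else:
            p = ge / config.n_permutations
        results.append(
            ComponentResult(
                edges=comp.edges,
                nodes=comp.nodes,
                degrees=comp.degrees,
                size=comp.size,
                fwe_p=float(p),
                null_max_sizes=null,
            )
        )
    return results


# ---------------------------------------------------------------------------
# component utilities


def component_edge_mask(component: Component) -> list[tuple[int, int]]:
    """The component's upper-triangle edge set, usable as an FC edge mask."""
    if component.size == 0:
        raise ValueError("component is empty")
    return [(i, j) for i, j, _ in component.edges]


def node_degree_table(component: Component) -> pd.DataFrame:
    """Per-node degree within the component, highest degree first."""
    if component.size == 0:
        raise ValueError("component is empty")
    rows = sorted(component.degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["node", "degree"])
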
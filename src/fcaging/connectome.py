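"""Connectivity matrices: construction, proportional thresholding, summaries.

A functional connectome is a symmetric ROI x ROI matrix of Pearson
correlations between regional resting-state time series.  Matrices are kept
either *signed* (raw correlations) or *absolute* (magnitudes, the primary
mode here).  Proportional thresholding retains a fixed fraction of the
strongest edges; network summaries average retained edges within and between
resting-state networks.  Also provided: the PSMD spread statistic
(95th minus 5th percentile of skeletonized mean-diffusivity values) and the
Trail-Making-Test B/A ratio score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "ConnectivityMatrix",
    "ConnectomeStack",
    "NetworkSummary",
    "correlation_matrix",
    "proportional_threshold",
    "threshold_stack",
    "mean_connectivity",
    "subnetwork_fc",
    "network_means",
    "group_difference_map",
    "psmd",
    "tmt_ratio",
    "read_matrix",
    "write_matrix",
]

UNTHRESHOLDED = None  # sentinel for retained_proportion


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class Parcellation:
    """ROI -> resting-state-network assignment.

    ``roi_names[k]`` and ``networks[k]`` describe the 0-based ROI index ``k``.
    Networks are non-overlapping: each ROI carries exactly one label.
    """

    roi_names: tuple[str, ...]
    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.roi_names) != len(self.networks):
            raise ValueError("roi_names and networks must have equal length")
        if len(self.roi_names) == 0:
            raise ValueError("parcellation is empty")

    @property
    def n_rois(self) -> int:
        return len(self.networks)

    @property
    def network_labels(self) -> tuple[str, ...]:
        """Distinct network labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.networks:
            seen.setdefault(lab, None)
        return tuple(seen)

    def nodes_of(self, network: str) -> np.ndarray:
        """0-based ROI indices belonging to ``network``."""
        return np.flatnonzero(np.asarray(self.networks) == network)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        required = {"roi_index", "roi_name", "network"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        idx = df["roi_index"].to_numpy()
        if len(np.unique(idx)) != len(idx) or not np.array_equal(
            np.sort(idx), np.arange(len(idx))
        ):
            raise ValueError("roi_index must be unique and contiguous from 0")
        order = np.argsort(idx)
        return cls(
            roi_names=tuple(df["roi_name"].to_numpy()[order].astype(str)),
            networks=tuple(df["network"].to_numpy()[order].astype(str)),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Parcellation":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_index": np.arange(self.n_rois),
                "roi_name": self.roi_names,
                "network": self.networks,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _validate_square_symmetric(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weights must be square, got shape {w.shape}")
    if not np.allclose(w, w.T, atol=1e-10, equal_nan=False):
        raise ValueError("weights must be symmetric")
    return w


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI x ROI edge-weight matrix with zero diagonal.

    ``retained_proportion`` is ``None`` for an unthresholded matrix, else the
    proportion of strongest upper-triangle edges retained.
    """

    weights: np.ndarray
    mode: str = "absolute"
    retained_proportion: float | None = UNTHRESHOLDED

    def __post_init__(self) -> None:
        w = _validate_square_symmetric(self.weights)
        if np.any(np.diag(w) != 0):
            w = w.copy()
            np.fill_diagonal(w, 0.0)
        if self.mode not in ("signed", "absolute"):
            raise ValueError(f"mode must be 'signed' or 'absolute', got {self.mode!r}")
        if self.mode == "absolute" and (w.min() < 0 or w.max() > 1):
            raise ValueError("absolute-mode weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ConnectomeStack:
    """A cohort of connectivity matrices sharing mode and threshold state.

    ``data`` has shape ``(n_subjects, n_rois, n_rois)``; ``subject_ids`` is
    aligned with the first axis.
    """

    data: np.ndarray
    subject_ids: tuple[str, ...]
    mode: str = "absolute"
    retained_proportion: float | None = UNTHRESHOLDED

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[1] != d.shape[2]:
            raise ValueError(f"stack must be (S, N, N), got {d.shape}")
        if len(self.subject_ids) != d.shape[0]:
            raise ValueError("subject_ids length must match stack size")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def matrix(self, s: int) -> ConnectivityMatrix:
        return ConnectivityMatrix(
            self.data[s], mode=self.mode, retained_proportion=self.retained_proportion
        )


@dataclass(frozen=True)
class NetworkSummary:
    """Mean FC over retained edges, globally and by network class."""

    global_mean: float
    within_mean: float
    between_mean: float
    per_network_mean: Mapping[str, float]
    undefined_networks: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# construction


def correlation_matrix(timeseries: np.ndarray, mode: str = "absolute") -> ConnectivityMatrix:
    """Pearson correlation of each ROI pair of an ROI x time array.

    In absolute mode the magnitude of the correlation is stored.  The
    diagonal (self-connections) is set to zero.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"timeseries must be 2-D (ROI x time), got shape {ts.shape}")
    n_rois, n_t = ts.shape
    if n_t < 3:
        raise ValueError(f"need at least 3 timepoints, got {n_t}")
    sd = ts.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant time series for ROI(s) {constant.tolist()}")
    r = np.corrcoef(ts)
    r = np.clip(r, -1.0, 1.0)
    if mode == "absolute":
        r = np.abs(r)
    elif mode != "signed":
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2.0  # exact symmetry against rounding
    return ConnectivityMatrix(r, mode=mode)


# ---------------------------------------------------------------------------
# thresholding


def _retained_count(proportion: float, n_edges: int) -> int:
    # round(p*E) with exact .5 rounded up (not banker's rounding)
    return int(math.floor(proportion * n_edges + 0.5))


def _threshold_weights(w: np.ndarray, proportion: float, mode: str) -> np.ndarray:
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    strength = np.abs(vals) if mode == "signed" else vals
    k = _retained_count(proportion, vals.size)
    # deterministic tie-break: strength desc, then i asc, then j asc
    order = np.lexsort((ju, iu, -strength))
    keep = order[:k]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    out[ju[keep], iu[keep]] = vals[keep]
    return out


def proportional_threshold(m: ConnectivityMatrix, proportion: float) -> ConnectivityMatrix:
    """Retain the ``round(p * E)`` strongest upper-triangle edges, zero the rest.

    "Strongest" means largest value in absolute mode and largest magnitude in
    signed mode.  Ties at the cut are broken deterministically by
    (strength desc, i asc, j asc).
    """
    if not 0 < proportion <= 1:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    out = _threshold_weights(m.weights, proportion, m.mode)
    return ConnectivityMatrix(out, mode=m.mode, retained_proportion=proportion)


def threshold_stack(stack: ConnectomeStack, proportion: float) -> ConnectomeStack:
    """Per-subject proportional thresholding of a whole stack."""
    if not 0 < proportion <= 1:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    out = np.empty_like(stack.data)
    for s in range(stack.n_subjects):
        out[s] = _threshold_weights(stack.data[s], proportion, stack.mode)
    return ConnectomeStack(
        out, stack.subject_ids, mode=stack.mode, retained_proportion=proportion
    )


# ---------------------------------------------------------------------------
# summaries


def _edge_mask_to_pairs(edge_mask: Iterable[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    pairs = [(min(i, j), max(i, j)) for i, j in edge_mask]
    if not pairs:
        raise ValueError("edge_mask is empty")
    if any(i == j for i, j in pairs):
        raise ValueError("edge_mask contains a self-edge")
    arr = np.asarray(sorted(set(pairs)), dtype=int)
    return arr[:, 0], arr[:, 1]


def mean_connectivity(
    m: ConnectivityMatrix, edge_mask: Iterable[tuple[int, int]] | None = None
) -> float:
    """Arithmetic mean FC over retained upper-triangle edges.

    For a thresholded matrix, zeroed (excluded) edges do not enter the
    denominator.  ``edge_mask`` restricts the mean to the given ROI pairs.
    """
    w = m.weights
    if edge_mask is not None:
        mi, mj = _edge_mask_to_pairs(edge_mask)
        if mi.max(initial=-1) >= m.n_rois:
            raise ValueError("edge_mask references ROI outside matrix")
        vals = w[mi, mj]
        if m.retained_proportion is not UNTHRESHOLDED:
            vals = vals[vals != 0]
    else:
        iu, ju = np.triu_indices(m.n_rois, 1)
        vals = w[iu, ju]
        if m.retained_proportion is not UNTHRESHOLDED:
            vals = vals[vals != 0]
    if vals.size == 0:
        raise ValueError("no retained edges in scope")
    return float(vals.mean())


def subnetwork_fc(stack: ConnectomeStack, edge_mask: Iterable[tuple[int, int]]) -> np.ndarray:
    """Per-subject mean FC over a fixed edge set (e.g. an NBS component).

    Uses the stored edge values directly (intended for unthresholded stacks,
    so the denominator is the same for every subject).
    """
    mi, mj = _edge_mask_to_pairs(edge_mask)
    if mi.max(initial=-1) >= stack.n_rois:
        raise ValueError("edge_mask references ROI outside stack")
    return stack.data[:, mi, mj].mean(axis=1)


def network_means(m: ConnectivityMatrix, parc: Parcellation) -> NetworkSummary:
    """Global / within-network / between-network / per-network mean FC.

    A network with fewer than 2 ROIs has no internal edges; its per-network
    mean is NaN and the network is flagged in ``undefined_networks``.
    """
    if parc.n_rois != m.n_rois:
        raise ValueError(
            f"parcellation covers {parc.n_rois} ROIs but matrix has {m.n_rois}"
        )
    labels = np.asarray(parc.networks)
    iu, ju = np.triu_indices(m.n_rois, 1)
    vals = m.weights[iu, ju]
    retained = (
        np.ones(vals.shape, dtype=bool)
        if m.retained_proportion is UNTHRESHOLDED
        else vals != 0
    )
    same = labels[iu] == labels[ju]

    def _mean(sel: np.ndarray) -> float:
        v = vals[sel & retained]
        return float(v.mean()) if v.size else float("nan")

    per: dict[str, float] = {}
    undefined: set[str] = set()
    for lab in parc.network_labels:
        members = labels == lab
        if members.sum() < 2:
            per[lab] = float("nan")
            undefined.add(lab)
            continue
        sel = members[iu] & members[ju]
        per[lab] = _mean(sel)
    return NetworkSummary(
        global_mean=_mean(np.ones(vals.shape, dtype=bool)),
        within_mean=_mean(same),
        between_mean=_mean(~same),
        per_network_mean=per,
        undefined_networks=frozenset(undefined),
    )


def group_difference_map(stack: ConnectomeStack, group_labels: Sequence[str]) -> np.ndarray:
    """Entrywise (mean over 'young') - (mean over 'old') connectivity map."""
    labels = np.asarray(group_labels)
    if labels.shape[0] != stack.n_subjects:
        raise ValueError("group_labels length must match stack size")
    young = stack.data[labels == "young"]
    old = stack.data[labels == "old"]
    if young.shape[0] == 0 or old.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    return young.mean(axis=0) - old.mean(axis=0)


# ---------------------------------------------------------------------------
# scalar markers


def psmd(md_values: np.ndarray, method: str = "linear") -> float:
    """Peak width of skeletonized mean diffusivity.

    The difference between the 95th and 5th percentile of mean-diffusivity
    values on the white-matter skeleton (units follow the input, typically
    mm^2/s).  ``method`` is the percentile interpolation convention passed to
    :func:`numpy.percentile` (linear closest-ranks interpolation by default).
    """
    x = np.asarray(md_values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("md_values contains non-finite entries")
    hi, lo = np.percentile(x, [95, 5], method=method)
    return float(hi - lo)


def tmt_ratio(tmtb_s: float, tmta_s: float) -> float:
    """Trail-Making-Test B/A ratio (set-shifting cost net of motor speed)."""
    b = np.asarray(tmtb_s, dtype=float)
    a = np.asarray(tmta_s, dtype=float)
    if np.any(b <= 0) or np.any(a <= 0):
        raise ValueError("TMT times must be positive")
    out = b / a
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# matrix I/O (delimited text, whitespace or comma separated)


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    try:
        w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed matrix file {path.name}: {exc}") from exc
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"matrix file {path.name} is not square: shape {w.shape}")
    return w


def write_matrix(w: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(w, dtype=float), fmt="%.8f")
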
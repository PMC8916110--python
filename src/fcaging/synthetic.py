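"""Synthetic aging-cohort and connectome generator with known ground truth.

Emulates the statistical structure of a middle-aged-to-older population MRI
cohort: ages uniform on 45-74, ~45% female, cortical thickness declining and
white-matter damage (PSMD) rising with age, Trail-Making times worsening with
age, 200-ROI absolute-value connectomes with a global mean FC near 0.36, and
a planted connected subnetwork of edges whose connectivity declines with age
partly through a cortical-thickness channel (age -> thickness -> FC) and
feeding executive slowing (age -> FC -> TMTB).

The target age-correlations are reached analytically: each variable is
linear-in-age plus Gaussian noise whose SD is solved from the slope and the
predictor variance, so the generating model stays interpretable for
mediation-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, ConnectomeStack, Parcellation, write_matrix

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_cohort",
    "generate_parcellation",
    "generate_connectomes",
    "generate_timeseries",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
]

COHORT_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "education",
    "cortical_thickness",
    "psmd",
    "tmta",
    "tmtb",
)

# Marginal anchors (cohort-level medians and per-year drifts).
THICKNESS_MID = 2.4  # mm at mid-age
PSMD_MID = 2.17e-4  # mm^2/s
PSMD_SLOPE = 3e-6  # mm^2/s per year (old-young strata gap over ~13 y)
TMTA_MID = 36.0  # s
TMTA_SLOPE = 0.6  # s per year
TMTB_MID = 79.0  # s
TMTB_DIRECT_SLOPE = 1.1  # s per year not running through FC
TMT_FLOOR = 5.0  # truncation keeping completion times positive
SUBJECT_FC_SD = 0.03  # latent per-subject factor on planted edges
EDUCATION_RANGE = (8, 18)  # years, uniform integers

# Fraction of ROIs per resting-state network; remainder labelled "other_1".
NETWORK_FRACTIONS = {
    "default": 0.23,
    "dorsal_attention": 0.13,
    "salience": 0.14,
    "control": 0.15,
}
PLANTED_NETWORK = "default"


class ConfigurationError(ValueError):
    """A generator configuration field is invalid."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the emulated cohort: 976 subjects aged 45-74 (45.4%
    female), 200-ROI connectomes with mean FC 0.36, and the published
    age-correlation targets for thickness (-0.4), PSMD (+0.5) and the
    Trail-Making tests.
    """

    n_subjects: int = 976
    n_rois: int = 200
    seed: int = 0
    n_timepoints: int = 125
    tr_ms: float = 2500.0
    age_min: int = 45
    age_max: int = 74
    female_fraction: float = 0.454
    target_r_age_thickness: float = -0.4
    target_r_age_psmd: float = 0.5
    target_r_age_tmta: float = 0.32
    target_r_age_tmtb: float = 0.3
    baseline_fc_mean: float = 0.36
    edge_noise_sd: float = 0.10
    planted_edge_fraction: float = 0.10
    planted_slope: float = -0.002  # total FC change per year on planted edges
    mediation_a: float = -0.012  # thickness mm per year
    mediation_b: float = 0.02  # FC per mm thickness
    mediation_c_direct: float | None = None  # derived from planted_slope if None
    outcome_b_fc: float = -50.0  # TMTB seconds per FC unit

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ConfigurationError(f"n_subjects must be >= 3, got {self.n_subjects}")
        if self.n_rois < 4:
            raise ConfigurationError(f"n_rois must be >= 4, got {self.n_rois}")
        if self.n_timepoints < 1:
            raise ConfigurationError(
                f"n_timepoints must be >= 1, got {self.n_timepoints}"
            )
        if self.tr_ms <= 0:
            raise ConfigurationError(f"tr_ms must be positive, got {self.tr_ms}")
        if not self.age_min < self.age_max:
            raise ConfigurationError(
                f"age_min must be < age_max, got {self.age_min} >= {self.age_max}"
            )
        for name in ("female_fraction", "planted_edge_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "target_r_age_thickness",
            "target_r_age_psmd",
            "target_r_age_tmta",
            "target_r_age_tmtb",
        ):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ConfigurationError(f"{name} must be in (-1, 1), got {v}")
        if self.edge_noise_sd <= 0:
            raise ConfigurationError(
                f"edge_noise_sd must be positive, got {self.edge_noise_sd}"
            )

    # --- derived quantities -------------------------------------------------

    @property
    def age_mid(self) -> float:
        return (self.age_min + self.age_max) / 2.0

    @property
    def age_sd(self) -> float:
        """SD of the uniform-integer age distribution (population value)."""
        m = self.age_max - self.age_min + 1
        return math.sqrt((m * m - 1) / 12.0)

    @property
    def c_direct(self) -> float:
        """Direct (not thickness-mediated) per-year slope of planted edges."""
        ab = self.mediation_a * self.mediation_b
        if self.mediation_c_direct is not None:
            return self.mediation_c_direct
        return self.planted_slope - ab

    @property
    def total_planted_slope(self) -> float:
        """Total expected FC-per-year slope of planted edges (direct + a*b)."""
        return self.c_direct + self.mediation_a * self.mediation_b


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    planted_edges: tuple[tuple[int, int], ...]  # upper-triangle (i < j)
    true_slope: float  # total FC change per year on planted edges
    true_paths: dict  # {'a': ..., 'b': ..., 'c_direct': ...}
    planted_network: str = PLANTED_NETWORK

    def __post_init__(self) -> None:
        if any(i >= j for i, j in self.planted_edges):
            raise ValueError("planted edges must be upper-triangle (i < j)")


def _noise_sd_for_target(slope: float, sd_x: float, target_r: float) -> tuple[float, float]:
    """(signed slope, noise SD) so that corr(x, slope*x + noise) == target_r.

    The slope magnitude is kept; its sign is taken from the target.  A zero
    target returns a zero slope with noise at the scale the slope would have
    produced, so the variable keeps a realistic spread.
    """
    mag = abs(slope)
    if target_r == 0 or mag == 0:
        return 0.0, mag * sd_x if mag > 0 else 1.0
    signed = math.copysign(mag, target_r)
    sd_noise = mag * sd_x * math.sqrt(1 - target_r**2) / abs(target_r)
    return signed, sd_noise


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a cohort table with the configured age-correlation structure.

    Returns a DataFrame with the public covariate columns plus a hidden
    ``latent_fc`` column: the per-subject factor shared between planted-edge
    connectivity and TMTB, which carries the age->FC->TMTB mediation channel.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    ages = rng.integers(cfg.age_min, cfg.age_max + 1, size=n)
    age_c = ages - cfg.age_mid
    sex = (rng.random(n) < cfg.female_fraction).astype(int)  # 1 = female
    education = rng.integers(EDUCATION_RANGE[0], EDUCATION_RANGE[1] + 1, size=n)

    # cortical thickness: slope is the mediation a-path
    a_slope, sd_th = _noise_sd_for_target(
        cfg.mediation_a, cfg.age_sd, cfg.target_r_age_thickness
    )
    thickness_noise = rng.normal(0.0, sd_th, size=n)
    thickness = THICKNESS_MID + a_slope * age_c + thickness_noise

    psmd_slope, sd_psmd = _noise_sd_for_target(PSMD_SLOPE, cfg.age_sd, cfg.target_r_age_psmd)
    psmd = PSMD_MID + psmd_slope * age_c + rng.normal(0.0, sd_psmd, size=n)

    tmta_slope, sd_tmta = _noise_sd_for_target(TMTA_SLOPE, cfg.age_sd, cfg.target_r_age_tmta)
    tmta = np.maximum(
        TMTA_MID + tmta_slope * age_c + rng.normal(0.0, sd_tmta, size=n), TMT_FLOOR
    )

    # latent subject-level FC factor on planted edges; feeds TMTB (model two)
    latent_fc = rng.normal(0.0, SUBJECT_FC_SD, size=n)
    # systematic + latent deviation of planted-edge FC from baseline:
    # direct age term plus the thickness channel (b * thickness deviation)
    fc_dev = (
        cfg.c_direct * age_c
        + cfg.mediation_b * (thickness - THICKNESS_MID)
        + latent_fc
    )
    realized_slope = cfg.c_direct + cfg.mediation_b * a_slope

    if cfg.target_r_age_tmtb == 0:
        tmtb_systematic = np.zeros(n)
        lam = 0.0
    else:
        tmtb_systematic = TMTB_DIRECT_SLOPE * age_c + cfg.outcome_b_fc * fc_dev
        lam = TMTB_DIRECT_SLOPE + cfg.outcome_b_fc * realized_slope
    # residual SD solved so corr(age, tmtb) hits the target
    r = cfg.target_r_age_tmtb
    if r == 0 or lam == 0:
        sd_eps = abs(TMTB_DIRECT_SLOPE) * cfg.age_sd  # realistic spread, no age link
    else:
        if math.copysign(1, lam) != math.copysign(1, r):
            raise ConfigurationError(
                "target_r_age_tmtb sign contradicts the generating TMTB age slope"
            )
        # population (not sample) variance of the non-age TMTB components
        var_nonage = (cfg.outcome_b_fc**2) * (
            (cfg.mediation_b**2) * sd_th**2 + SUBJECT_FC_SD**2
        )
        total_nonage = (lam * cfg.age_sd) ** 2 * (1 / r**2 - 1)
        var_eps = total_nonage - var_nonage
        if var_eps <= 0:
            raise ConfigurationError(
                "target_r_age_tmtb unreachable: FC-path variance alone exceeds "
                "the noise budget implied by the target correlation"
            )
        sd_eps = math.sqrt(var_eps)
    tmtb = np.maximum(
        TMTB_MID + tmtb_systematic + rng.normal(0.0, sd_eps, size=n), TMT_FLOOR
    )

    width = len(str(n))
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:0{width}d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "education": education,
            "cortical_thickness": thickness,
            "psmd": psmd,
            "tmta": tmta,
            "tmtb": tmtb,
            "latent_fc": latent_fc,
        }
    )


def generate_parcellation(config: GeneratorConfig) -> Parcellation:
    """Assign ROIs to resting-state networks in contiguous blocks.

    Block sizes follow :data:`NETWORK_FRACTIONS`; remaining ROIs are labelled
    ``other_1``.  Deterministic given ``n_rois``.
    """
    n = config.n_rois
    labels: list[str] = []
    for name, frac in NETWORK_FRACTIONS.items():
        labels.extend([name] * max(2, round(frac * n)))
    labels = labels[:n]
    labels.extend(["other_1"] * (n - len(labels)))
    names = tuple(f"ROI_{k + 1:03d}" for k in range(n))
    return Parcellation(roi_names=names, networks=tuple(labels))


def _planted_subgraph(
    nodes: np.ndarray, n_edges: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """A connected random subgraph with exactly ``n_edges`` edges on ``nodes``.

    Grows from a random start node, repeatedly adding an unused edge with at
    least one endpoint already reached, so every intermediate state is
    connected (mirrors a compact affected subnetwork).
    """
    nodes = list(nodes)
    max_edges = len(nodes) * (len(nodes) - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"cannot plant {n_edges} edges among {len(nodes)} nodes (max {max_edges})"
        )
    reached = {nodes[rng.integers(len(nodes))]}
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_edges:
        candidates = [
            (min(u, v), max(u, v))
            for u in reached
            for v in nodes
            if u != v and (min(u, v), max(u, v)) not in chosen
        ]
        e = candidates[rng.integers(len(candidates))]
        chosen.add(e)
        reached.update(e)
    return sorted(chosen)


def generate_connectomes(
    config: GeneratorConfig, cohort: pd.DataFrame
) -> tuple[ConnectomeStack, GroundTruth]:
    """Per-subject absolute-mode connectivity matrices with a planted effect.

    Non-planted edges are baseline + noise with no expected age slope.  The
    planted edges (a connected subgraph inside the designated network) follow

        baseline + c_direct*(age - mean age) + b*(thickness residual-in-age
        scaled) + subject factor + noise,

    so their total expected age slope is ``config.planted_slope`` and part of
    it runs through cortical thickness (the mediation channel).  Entries are
    clipped to [0.01, 0.99] and symmetrized with a zero diagonal.
    """
    cfg = config
    if len(cohort) != cfg.n_subjects:
        raise ValueError(
            f"cohort has {len(cohort)} subjects but config expects {cfg.n_subjects}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    parc = generate_parcellation(cfg)
    net_nodes = parc.nodes_of(PLANTED_NETWORK)

    n = cfg.n_subjects
    n_rois = cfg.n_rois
    iu, ju = np.triu_indices(n_rois, 1)
    n_edges = iu.size

    e_net = len(net_nodes) * (len(net_nodes) - 1) // 2
    k_planted = int(math.floor(cfg.planted_edge_fraction * e_net + 0.5))
    planted = _planted_subgraph(net_nodes, k_planted, rng) if k_planted else []
    edge_pos = {(int(i), int(j)): idx for idx, (i, j) in enumerate(zip(iu, ju))}
    planted_idx = np.array([edge_pos[e] for e in planted], dtype=int)

    age_c = cohort["age"].to_numpy() - cfg.age_mid
    a_slope, _ = _noise_sd_for_target(
        cfg.mediation_a, cfg.age_sd, cfg.target_r_age_thickness
    )
    thickness_dev = cohort["cortical_thickness"].to_numpy() - THICKNESS_MID
    if "latent_fc" in cohort.columns:
        latent = cohort["latent_fc"].to_numpy()
    else:  # cohort reloaded from disk: latent factor unavailable
        latent = np.zeros(n)

    edges = cfg.baseline_fc_mean + rng.normal(0.0, cfg.edge_noise_sd, size=(n, n_edges))
    if planted_idx.size:
        # direct age effect plus the thickness-mediated channel; total
        # expected age slope is c_direct + b * a = planted_slope
        signal = cfg.c_direct * age_c + cfg.mediation_b * thickness_dev + latent
        edges[:, planted_idx] += signal[:, None]
    np.clip(edges, 0.01, 0.99, out=edges)

    data = np.zeros((n, n_rois, n_rois))
    data[:, iu, ju] = edges
    data[:, ju, iu] = edges
    stack = ConnectomeStack(
        data, tuple(cohort["subject_id"].astype(str)), mode="absolute"
    )
    truth = GroundTruth(
        planted_edges=tuple(planted),
        true_slope=cfg.c_direct + cfg.mediation_b * a_slope,
        true_paths={
            "a": a_slope,
            "b": cfg.mediation_b,
            "c_direct": cfg.c_direct,
        },
    )
    return stack, truth


def generate_timeseries(
    target: ConnectivityMatrix | np.ndarray, n_timepoints: int, seed: int = 0
) -> np.ndarray:
    """ROI x time Gaussian series whose population correlation is ``target``.

    ``target`` is interpreted as a correlation matrix (unit diagonal); a
    :class:`ConnectivityMatrix` (zero diagonal) has its diagonal restored.
    The sample correlation converges to the target as the series lengthens.
    """
    if n_timepoints < 3:
        raise ValueError(f"need at least 3 timepoints, got {n_timepoints}")
    c = np.array(target.weights if isinstance(target, ConnectivityMatrix) else target, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"target must be square, got shape {c.shape}")
    np.fill_diagonal(c, 1.0)
    eigvals = np.linalg.eigvalsh(c)
    if eigvals[0] <= 0:
        raise ValueError(
            "target is not positive-definite as a correlation matrix: "
            f"smallest eigenvalue is {eigvals[0]:.3g} (non-positive)"
        )
    chol = np.linalg.cholesky(c)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, c.shape[0]))
    return (z @ chol.T).T


# ---------------------------------------------------------------------------
# file interfaces


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the public cohort columns as CSV (latent columns dropped)."""
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False, float_format="%.10g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def write_connectomes(stack: ConnectomeStack, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s, sid in enumerate(stack.subject_ids):
        write_matrix(stack.data[s], out / f"{sid}_matrix.txt")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\ttrue_slope\n")
        for i, j in truth.planted_edges:
            fh.write(f"{i}\t{j}\t{truth.true_slope:.10g}\n")
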
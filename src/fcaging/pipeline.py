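"""End-to-end analysis pipeline with reproducible configuration and file I/O.

Stage order mirrors the analysis design: cohort summary, per-subject
proportional thresholding and network FC means, univariate age fits,
multiple regressions adjusted for sex and education with a Bonferroni gate
(alpha / m) on the per-network age effect, the network-based statistic on
the surviving networks (and the whole brain), extraction of per-subject
subnetwork FC from significant components, and the two bootstrap mediation
models (structure -> FC, and FC -> executive function).  One master seed
derives every stage seed, so two runs of the same configuration produce
byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import (
    ConnectomeStack,
    Parcellation,
    network_means,
    read_matrix,
    subnetwork_fc,
    threshold_stack,
    tmt_ratio,
)
from .mediation import MediationModel, MediationResult, bootstrap_mediation
from .nbs import Component, ComponentResult, NBSConfig, component_edge_mask, nbs_test
from .regression import bonferroni_alpha, multiple_regression, results_to_frame, univariate_fit
from .synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_connectomes,
    generate_parcellation,
    read_cohort,
    write_cohort,
    write_connectomes,
    write_ground_truth,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ResultsBundle",
    "load_inputs",
    "cohort_summary",
    "run_full_pipeline",
    "simulate_inputs",
]

FLOAT_FMT = "%.10g"
NETWORK_OUTCOMES = ("default", "dorsal_attention", "salience", "control")


@dataclass(frozen=True)
class AnalysisConfig:
    """Flat, fully explicit pipeline configuration."""

    cohort_csv: str | None = None
    matrix_dir: str | None = None
    parcellation_tsv: str | None = None
    output_dir: str | None = None
    retained_proportion: float = 0.5
    matrix_mode: str = "absolute"
    alpha_family: float = 0.05
    m_tests: int = 7
    young_max_age: int = 63
    nbs_t_threshold: float = 3.2
    nbs_n_permutations: int = 5000
    nbs_direction: str = "negative"
    nbs_include_covariates: bool = False
    nbs_component_alpha: float = 0.05
    mediation_n_boot: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a flat key/value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage_seed(self, *tag: int) -> int:
        """A per-stage seed derived deterministically from the master seed."""
        ss = np.random.SeedSequence([self.seed, *tag])
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ResultsBundle:
    """All output tables of one pipeline run plus a provenance block."""

    table1: pd.DataFrame
    univariate: pd.DataFrame
    mlr: pd.DataFrame
    network_gate: pd.DataFrame
    nbs: dict[str, list[ComponentResult]]
    subnetwork_fc: pd.DataFrame
    mediation_one: pd.DataFrame
    mediation_two: pd.DataFrame
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        def _tsv(df: pd.DataFrame, name: str) -> None:
            df.to_csv(out / name, sep="\t", index=False, float_format=FLOAT_FMT)

        _tsv(self.table1, "table1.tsv")
        _tsv(self.univariate, "univariate.tsv")
        _tsv(self.mlr, "mlr.tsv")
        _tsv(self.network_gate, "network_gate.tsv")
        _tsv(self.subnetwork_fc, "subnetwork_fc.tsv")
        _tsv(self.mediation_one, "mediation_model1.tsv")
        _tsv(self.mediation_two, "mediation_model2.tsv")

        summary_rows = []
        for scope, comps in self.nbs.items():
            for k, comp in enumerate(comps):
                summary_rows.append(
                    {
                        "scope": scope,
                        "component": k,
                        "size": comp.size,
                        "n_nodes": len(comp.nodes),
                        "fwe_p": comp.fwe_p,
                    }
                )
                if k == 0:  # largest component: full edge/node/null dumps
                    edges = pd.DataFrame(
                        comp.edges, columns=["node_i", "node_j", "t_value"]
                    )
                    _tsv(edges, f"nbs_{scope}_edges.tsv")
                    deg = pd.DataFrame(
                        sorted(comp.degrees.items(), key=lambda kv: (-kv[1], kv[0])),
                        columns=["node", "degree"],
                    )
                    _tsv(deg, f"nbs_{scope}_nodes.tsv")
                    np.savetxt(
                        out / f"nbs_{scope}_null.txt", comp.null_max_sizes, fmt="%d"
                    )
        _tsv(
            pd.DataFrame(
                summary_rows, columns=["scope", "component", "size", "n_nodes", "fwe_p"]
            ),
            "nbs_summary.tsv",
        )
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, sort_keys=True, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# input handling


def load_inputs(config: AnalysisConfig) -> tuple[pd.DataFrame, ConnectomeStack, Parcellation]:
    """Read cohort CSV, matrix files and the parcellation; align by subject id.

    Subjects with a missing or unreadable matrix file are excluded and
    logged; a malformed (non-square) matrix raises naming the file.
    """
    if not (config.cohort_csv and config.matrix_dir and config.parcellation_tsv):
        raise ValueError("cohort_csv, matrix_dir and parcellation_tsv are required")
    cohort = read_cohort(config.cohort_csv)
    parc = Parcellation.from_tsv(config.parcellation_tsv)
    mdir = Path(config.matrix_dir)
    mats, kept = [], []
    for _, row in cohort.iterrows():
        sid = str(row["subject_id"])
        path = mdir / f"{sid}_matrix.txt"
        if not path.exists():
            logger.warning("excluding %s: matrix file missing", sid)
            continue
        w = read_matrix(path)
        if w.shape[0] != parc.n_rois:
            raise ValueError(
                f"matrix {path.name} has {w.shape[0]} ROIs, parcellation has {parc.n_rois}"
            )
        mats.append(w)
        kept.append(sid)
    if not kept:
        raise ValueError("no subjects with readable matrices")
    excluded = len(cohort) - len(kept)
    if excluded:
        logger.warning("excluded %d of %d subjects (unreadable matrices)", excluded, len(cohort))
    cohort = cohort[cohort["subject_id"].astype(str).isin(kept)].reset_index(drop=True)
    stack = ConnectomeStack(np.stack(mats), tuple(kept), mode=config.matrix_mode)
    return cohort, stack, parc


def simulate_inputs(gen_config: GeneratorConfig, out_dir: str | Path) -> None:
    """Generate a synthetic cohort + connectomes and write all input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(gen_config)
    stack, truth = generate_connectomes(gen_config, cohort)
    parc = generate_parcellation(gen_config)
    write_cohort(cohort, out / "cohort.csv")
    write_connectomes(stack, out / "matrices")
    parc.to_tsv(out / "parcellation.tsv")
    write_ground_truth(truth, out / "ground_truth.tsv")
    logger.info(
        "simulated %d subjects, %d ROIs, %d planted edges -> %s",
        gen_config.n_subjects,
        gen_config.n_rois,
        len(truth.planted_edges),
        out,
    )


# ---------------------------------------------------------------------------
# summaries


def _median_iqr(x: np.ndarray) -> tuple[float, float]:
    x = x[np.isfinite(x)]
    q25, q50, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return float(q50), float(q75 - q25)


def cohort_summary(cohort: pd.DataFrame, split_age: int = 63) -> pd.DataFrame:
    """Median (IQR) per numeric variable and counts for sex, by age stratum.

    Strata: young = age <= ``split_age``, old = age > ``split_age``; they
    partition the cohort exactly.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    young = cohort[cohort["age"] <= split_age]
    old = cohort[cohort["age"] > split_age]
    numeric = [
        c
        for c in ("age", "education", "tmta", "tmtb", "psmd", "cortical_thickness")
        if c in cohort.columns
    ]
    rows = []
    for grp_name, grp in (("overall", cohort), ("young", young), ("old", old)):
        rows.append({"stratum": grp_name, "variable": "n", "value": len(grp), "iqr": np.nan})
        if "sex" in cohort.columns and len(grp):
            n_f = int((grp["sex"] == 1).sum())
            rows.append(
                {
                    "stratum": grp_name,
                    "variable": "female_percent",
                    "value": 100.0 * n_f / len(grp),
                    "iqr": np.nan,
                }
            )
        for var in numeric:
            if len(grp) == 0:
                continue
            med, iqr = _median_iqr(grp[var].to_numpy(dtype=float))
            rows.append({"stratum": grp_name, "variable": var, "value": med, "iqr": iqr})
    return pd.DataFrame(rows, columns=["stratum", "variable", "value", "iqr"])


def _fc_columns(
    cohort: pd.DataFrame, stack: ConnectomeStack, parc: Parcellation, proportion: float
) -> pd.DataFrame:
    """Per-subject global / within / between / per-network mean FC at the
    configured proportional threshold."""
    thresholded = threshold_stack(stack, proportion)
    rows = []
    for s in range(thresholded.n_subjects):
        summ = network_means(thresholded.matrix(s), parc)
        row = {
            "fc_global": summ.global_mean,
            "fc_within": summ.within_mean,
            "fc_between": summ.between_mean,
        }
        for net, v in summ.per_network_mean.items():
            if not net.startswith("other"):
                row[f"fc_{net}"] = v
        rows.append(row)
    out = cohort.copy()
    for col, vals in pd.DataFrame(rows).items():
        out[col] = vals.to_numpy()
    return out


def _remap_component(comp: ComponentResult, nodes: np.ndarray) -> ComponentResult:
    """Translate a component from network-local to global ROI indices."""
    gl = {local: int(g) for local, g in enumerate(nodes)}
    edges = tuple(
        sorted((min(gl[i], gl[j]), max(gl[i], gl[j]), t) for i, j, t in comp.edges)
    )
    return ComponentResult(
        edges=edges,
        nodes=frozenset(gl[v] for v in comp.nodes),
        degrees={gl[v]: d for v, d in comp.degrees.items()},
        size=comp.size,
        fwe_p=comp.fwe_p,
        null_max_sizes=comp.null_max_sizes,
    )


# ---------------------------------------------------------------------------
# the full pipeline


def run_full_pipeline(
    config: AnalysisConfig,
    *,
    cohort: pd.DataFrame | None = None,
    stack: ConnectomeStack | None = None,
    parcellation: Parcellation | None = None,
) -> ResultsBundle:
    """Run every analysis stage and return (and optionally write) the bundle.

    Inputs may be passed in memory; otherwise they are loaded from the paths
    in ``config``.
    """
    if cohort is None or stack is None or parcellation is None:
        cohort, stack, parcellation = load_inputs(config)
    logger.info("stage load: %d subjects, %d ROIs", len(cohort), stack.n_rois)

    table1 = cohort_summary(cohort, split_age=config.young_max_age)

    data = _fc_columns(cohort, stack, parcellation, config.retained_proportion)
    data["tmt_ratio"] = tmt_ratio(
        data["tmtb"].to_numpy(), data["tmta"].to_numpy()
    )
    logger.info("stage connectivity: thresholded at %.2f", config.retained_proportion)

    networks = [n for n in NETWORK_OUTCOMES if f"fc_{n}" in data.columns]
    fc_outcomes = ["fc_global", "fc_within", "fc_between"] + [f"fc_{n}" for n in networks]

    # univariate age effects
    uni_outcomes = [
        "cortical_thickness",
        "psmd",
        "tmta",
        "tmtb",
        "tmt_ratio",
        *fc_outcomes,
    ]
    age = data["age"].to_numpy(dtype=float)
    uni = [
        univariate_fit(data[o].to_numpy(dtype=float), age, term="age", outcome=o)
        for o in uni_outcomes
    ]
    univariate = results_to_frame(uni)
    univariate["r"] = [u.r for u in uni]
    ratio_p = next(u.p for u in uni if u.outcome == "tmt_ratio")
    ratio_gated = ratio_p > 0.05
    if ratio_gated:
        logger.info("tmt_ratio shows no age association (p=%.3g); excluded downstream", ratio_p)

    # multiple regressions, adjusted for sex and education
    mlr_results = []
    for o in fc_outcomes:
        mlr_results.extend(
            multiple_regression(
                data, o, predictors=["age", "cortical_thickness", "psmd"]
            )
        )
    mlr = results_to_frame(mlr_results)
    threshold = bonferroni_alpha(config.alpha_family, config.m_tests)

    gate_rows = []
    surviving = []
    for n in networks:
        p_age = float(
            mlr.loc[(mlr["outcome"] == f"fc_{n}") & (mlr["term"] == "age"), "p"].iloc[0]
        )
        keep = p_age <= threshold
        gate_rows.append(
            {"network": n, "age_p": p_age, "threshold": round(threshold, 3), "survives": keep}
        )
        if keep:
            surviving.append(n)
    network_gate = pd.DataFrame(gate_rows, columns=["network", "age_p", "threshold", "survives"])
    logger.info(
        "stage regression: %d/%d networks pass the age gate at p<=%.3f",
        len(surviving),
        len(networks),
        threshold,
    )

    # NBS on the whole brain and each surviving network (unthresholded values)
    covs = (
        data[["sex", "education"]].to_numpy(dtype=float)
        if config.nbs_include_covariates
        else None
    )
    nbs_out: dict[str, list[ComponentResult]] = {}
    scopes: list[tuple[str, np.ndarray]] = [("whole_brain", np.arange(stack.n_rois))]
    scopes += [(n, parcellation.nodes_of(n)) for n in surviving]
    for k, (scope, nodes) in enumerate(scopes):
        sub = stack.data[:, nodes[:, None], nodes[None, :]]
        cfg = NBSConfig(
            t_threshold=config.nbs_t_threshold,
            n_permutations=config.nbs_n_permutations,
            direction=config.nbs_direction,
            include_covariates=config.nbs_include_covariates,
            seed=config.stage_seed(1, k),
        )
        comps = nbs_test(
            ConnectomeStack(sub, stack.subject_ids, mode=stack.mode),
            age,
            cfg,
            covariates=covs,
        )
        nbs_out[scope] = [_remap_component(c, nodes) for c in comps]
        logger.info(
            "stage nbs [%s]: %d component(s), best fwe_p=%s",
            scope,
            len(comps),
            f"{comps[0].fwe_p:.4f}" if comps else "n/a",
        )

    # per-subject subnetwork FC from the largest significant component per
    # scope; named networks take precedence over whole_brain when a
    # whole-brain component coincides with a network's
    subnet_cols: list[str] = []
    scope_order = sorted(nbs_out, key=lambda s: s == "whole_brain")
    for scope in scope_order:
        comps = nbs_out[scope]
        sig = [c for c in comps if c.fwe_p < config.nbs_component_alpha]
        if not sig:
            logger.info("no significant component in %s; no subnetwork column", scope)
            continue
        col = f"subnet_{scope}"
        vals = subnetwork_fc(stack, component_edge_mask(sig[0]))
        if any(np.array_equal(vals, data[c].to_numpy()) for c in subnet_cols):
            # e.g. the whole-brain component coincides with a network's
            logger.info("subnetwork %s duplicates an earlier one; dropped", scope)
            continue
        data[col] = vals
        subnet_cols.append(col)
    subnetwork_table = data[["subject_id", *subnet_cols]].copy()

    # mediation
    med1_frames, med2_frames = [], []
    if subnet_cols:
        for k, col in enumerate(subnet_cols):
            model = MediationModel(
                exposure="age",
                mediators=("cortical_thickness", "psmd"),
                outcome=col,
            )
            res = bootstrap_mediation(
                data,
                model,
                n_boot=config.mediation_n_boot,
                seed=config.stage_seed(2, k),
            )
            frame = res.to_frame()
            frame.insert(0, "outcome", col)
            med1_frames.append(frame)
        outcomes_two = ["tmtb", "tmta"]
        for k, o in enumerate(outcomes_two):
            model = MediationModel(
                exposure="age", mediators=tuple(subnet_cols), outcome=o
            )
            res = bootstrap_mediation(
                data,
                model,
                n_boot=config.mediation_n_boot,
                seed=config.stage_seed(3, k),
            )
            frame = res.to_frame()
            frame.insert(0, "outcome", o)
            med2_frames.append(frame)
        logger.info("stage mediation: %d model-one fits, %d model-two fits",
                    len(med1_frames), len(med2_frames))
    else:
        logger.info("no significant subnetworks; mediation stage skipped")
    empty_med = pd.DataFrame(
        columns=["outcome", "effect", "estimate", "se", "std_beta", "p", "ci_low", "ci_high"]
    )
    mediation_one = pd.concat(med1_frames, ignore_index=True) if med1_frames else empty_med
    mediation_two = pd.concat(med2_frames, ignore_index=True) if med2_frames else empty_med

    provenance = {
        "software": "fcaging",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_subjects": int(len(cohort)),
        "n_rois": int(stack.n_rois),
        "bonferroni_threshold": round(threshold, 3),
        "surviving_networks": surviving,
        "tmt_ratio_excluded": bool(ratio_gated),
    }
    bundle = ResultsBundle(
        table1=table1,
        univariate=univariate,
        mlr=mlr,
        network_gate=network_gate,
        nbs=nbs_out,
        subnetwork_fc=subnetwork_table,
        mediation_one=mediation_one,
        mediation_two=mediation_two,
        provenance=provenance,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
        logger.info("results written to %s", config.output_dir)
    return bundle
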
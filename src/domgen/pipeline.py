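"""End-to-end orchestration of the dominant-marker analysis pipeline.

Stage order mirrors a standard marker-survey workflow: validate -> MAF
filter -> diversity -> marker efficiency -> distances -> UPGMA tree ->
PCoA -> AMOVA -> admixture structure (K grid, ΔK, assignment) ->
stratified LD.  Every stage is a pure function of (inputs, config,
seeds); a master seed spawns per-stage seeds by fixed offsets so a rerun
with the same config is bit-identical.

An aggregation-only mode consumes a published per-primer TNB/NPB table
(no band matrix needed) and reproduces the marker-survey summary tables:
per-type totals, PPB, EMR and MI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import band_data, distances, diversity, ld, marker_efficiency, upgma
from .admixture import assign_membership, evanno_delta_k, structure_run_grid
from .amova import amova
from .synthetic import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "aggregation_report",
    "load_packaged_primer_counts",
    "STAGE_SEED_OFFSETS",
]

#: fixed offsets turning the master seed into per-stage seeds
STAGE_SEED_OFFSETS = {
    "simulate": 11,
    "bootstrap": 23,
    "amova": 37,
    "structure": 53,
}

#: published per-type Ib_av values usable with aggregation-only input
DEFAULT_IB_AV = {"ISSR": 0.38, "SCoT": 0.43, "EST-SSR": 0.36}


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run; all seeds derive from ``seed``."""

    band_matrix: str | None = None       # TSV path; None -> simulate
    sample_meta: str | None = None
    sim: SimConfig | None = None
    group_key: str = "ecotype"
    maf_threshold: float = 0.05
    maf_two_sided: bool = True           # for the LD/structure input
    tree_metric: str = "nei_li"
    bootstrap_reps: int = 100
    pcoa_axes: int = 2
    amova_permutations: int = 999
    k_min: int = 1
    k_max: int = 5
    structure_reps: int = 3
    burn_in: int = 300
    n_iter: int = 600
    thin: int = 2
    ld_alpha: float = 0.001
    ld_r2_cut: float = 0.1
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
            })
        return cfg

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_packaged_primer_counts() -> pd.DataFrame:
    """The packaged 51-primer TNB/NPB reference table (ISSR/SCoT/EST-SSR)."""
    ref = importlib.resources.files("domgen") / "data" / "primer_band_counts.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def aggregation_report(
    counts: pd.DataFrame | None = None,
    ib_av_by_type: dict[str, float] | None = None,
) -> dict:
    """Aggregation-only mode: marker-survey tables from per-primer counts."""
    if counts is None:
        counts = load_packaged_primer_counts()
    agg = diversity.aggregate_primer_counts(counts)
    eff = marker_efficiency.efficiency_from_primer_counts(
        counts, ib_av_by_type or DEFAULT_IB_AV
    )
    return {
        "aggregate": agg.to_dict(orient="records"),
        "efficiency": eff.to_dict(orient="records"),
    }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; return the report dict (also written to out_dir).

    Raises with the failing stage's name in the message if any stage
    errors out.
    """
    report: dict = {"config_hash": cfg.config_hash(), "stages": {}, "warnings": []}
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    t_start = time.perf_counter()
    try:
        if cfg.band_matrix is not None:
            m = band_data.read_band_matrix(cfg.band_matrix)
            meta = (
                band_data.read_sample_meta(cfg.sample_meta)
                if cfg.sample_meta
                else None
            )
        else:
            sim_cfg = cfg.sim or SimConfig()
            m, meta, _truth = simulate_dataset(
                sim_cfg, seed=cfg.seed + STAGE_SEED_OFFSETS["simulate"]
            )
        report["stages"]["load"] = {
            "n_samples": m.n_samples, "n_loci": m.n_loci,
        }

        stage = "diversity"
        div = diversity.diversity_table(m, group_by="type")
        div_all = diversity.diversity_table(m, group_by="all")
        report["stages"]["diversity"] = {
            "by_type": div.to_dict(orient="records"),
            "overall": div_all.to_dict(orient="records"),
        }

        stage = "efficiency"
        eff = marker_efficiency.efficiency_table(m)
        report["stages"]["efficiency"] = eff.to_dict(orient="records")

        stage = "distances"
        d_nei = distances.nei_li_distance_matrix(m)
        lo, mean, hi = distances.similarity_summary(m)
        report["stages"]["similarity"] = {"min": lo, "mean": mean, "max": hi}

        stage = "tree"
        tree = upgma.bootstrap_support(
            m, metric=cfg.tree_metric, n_reps=cfg.bootstrap_reps,
            seed=cfg.seed + STAGE_SEED_OFFSETS["bootstrap"],
        )
        report["stages"]["tree"] = {"newick": upgma.to_newick(tree)}
        if out:
            upgma.write_newick(tree, out / "tree.nwk")

        stage = "pcoa"
        d_mrd = distances.mrd_matrix(m)
        pc = distances.pcoa(d_mrd, n_axes=cfg.pcoa_axes)
        report["stages"]["pcoa"] = {
            "eigenvalues": pc.eigenvalues[: cfg.pcoa_axes].tolist(),
            "proportion_explained": pc.proportion_explained[: cfg.pcoa_axes].tolist(),
        }
        if out:
            pc.coordinates.to_csv(out / "pcoa_coords.tsv", sep="\t")

        stage = "amova"
        amova_res = None
        if meta is not None:
            labels = band_data.group_labels(m, meta, key=cfg.group_key)
            if len(set(labels)) >= 2:
                d_eu = distances.euclidean_squared_matrix(m)
                amova_res = amova(
                    d_eu, labels, n_perm=cfg.amova_permutations,
                    seed=cfg.seed + STAGE_SEED_OFFSETS["amova"],
                )
                report["stages"]["amova"] = _jsonable(dataclasses.asdict(amova_res))
            else:
                report["warnings"].append("amova skipped: fewer than two groups")
        else:
            report["warnings"].append("amova skipped: no metadata")

        stage = "filter"
        filtered, removed = band_data.maf_filter(
            m, threshold=cfg.maf_threshold, two_sided=cfg.maf_two_sided
        )
        report["stages"]["filter"] = {
            "removed": len(removed), "kept": filtered.n_loci,
        }

        stage = "structure"
        runs = structure_run_grid(
            filtered,
            k_range=range(cfg.k_min, cfg.k_max + 1),
            n_reps=cfg.structure_reps,
            seed=cfg.seed + STAGE_SEED_OFFSETS["structure"],
            burn_in=cfg.burn_in, n_iter=cfg.n_iter, thin=cfg.thin,
        )
        dk = evanno_delta_k(runs)
        best_k = dk.attrs["best_k"]
        best_fit = max(runs[best_k], key=lambda f: f.ln_p_d)
        assignment = assign_membership(best_fit)
        report["stages"]["structure"] = {
            "delta_k": dk.to_dict(orient="records"),
            "best_k": best_k,
            "assignment_counts": assignment["assignment"].value_counts().to_dict(),
        }
        if out:
            dk.to_csv(out / "delta_k.tsv", sep="\t", index=False)
            assignment.to_csv(out / "assignment.tsv", sep="\t", index=False)
            pd.DataFrame(
                best_fit.Q, index=best_fit.samples,
                columns=[f"Q{k + 1}" for k in range(best_k)],
            ).to_csv(out / "q_matrix.tsv", sep="\t")

        stage = "ld"
        strata = {
            g: assignment.loc[assignment["max_membership_group"] == g, "sample_id"].tolist()
            for g in sorted(assignment["max_membership_group"].unique())
        }
        strata = {g: ids for g, ids in strata.items() if len(ids) >= 10}
        res_all = ld.pairwise_r2(filtered)
        report["stages"]["ld"] = {
            "all": ld.ld_summary(res_all, alpha=cfg.ld_alpha, r2_cut=cfg.ld_r2_cut),
        }
        if strata and best_k > 1:
            report["stages"]["ld"]["by_subpopulation"] = ld.stratified_ld(
                m, strata, maf_threshold=cfg.maf_threshold,
                alpha=cfg.ld_alpha, r2_cut=cfg.ld_r2_cut,
            )
    except Exception as exc:  # annotate failures with the stage name
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["elapsed_s"] = round(time.perf_counter() - t_start, 3)
    report = _jsonable(report)
    if out:
        payload = dict(report)
        payload.pop("elapsed_s", None)
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return report
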
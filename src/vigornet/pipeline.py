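"""End-to-end orchestration: crosstalk -> enrichment -> GRN -> integration -> hubs.

Every stage reads and writes plain-text artifacts under one output
directory, and a JSON run manifest records the config echo, per-stage
counts, seeds and wall-clock times so a run can be audited or reproduced.
A stage failure aborts the run with the failing stage named and leaves a
FAILED marker next to the partial outputs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import ConsensusParams, CrosstalkThresholds, SimConfig
from .crosstalk import classify_crosstalk, summarize_crosstalk, write_crosstalk
from .enrichment import (
    build_heatmap_matrix,
    fisher_enrichment,
    read_gmt,
    write_enrichment,
)
from .errors import InferenceError, VigornetError
from .grn import (
    ConsensusNetwork,
    assign_roles,
    consensus_network,
    preprocess,
    retention_filter,
    write_consensus,
)
from .hubs import EpcParams, rank_and_call, write_hub_results
from .integration import filter_ppi, integrate, select_ppi_input, simple_projection, write_integrated
from . import synthetic

logger = logging.getLogger(__name__)

STAGES = ("crosstalk", "enrichment", "grn", "integration", "hubs")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run."""

    expression: str
    transcript_de: str
    protein_de: str
    ppi: str
    mirna_targets: str
    regulators: str
    annotations: str
    outdir: str
    categories: str | None = None
    thresholds: CrosstalkThresholds = field(default_factory=CrosstalkThresholds)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    enrichment_alpha: float = 0.05
    ppi_min_score: int = 400
    top_k: int = 10
    epc_replicates: int = 1000
    seed: int = 0
    skip: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if isinstance(raw.get("thresholds"), dict):
            raw["thresholds"] = CrosstalkThresholds(**raw["thresholds"])
        if isinstance(raw.get("consensus"), dict):
            raw["consensus"] = ConsensusParams(**raw["consensus"])
        if "skip" in raw:
            raw["skip"] = tuple(raw["skip"])
        return cls(**raw)


def _read_lines(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def generate_demo(outdir: str | Path, seed: int = 0, cfg: SimConfig | None = None) -> PipelineConfig:
    """Write a complete synthetic input bundle and return a ready config."""
    cfg = cfg or SimConfig(seed=seed)
    outdir = Path(outdir)
    paths = synthetic.write_bundle(cfg, outdir / "inputs")
    return PipelineConfig(
        expression=str(paths["expression"]),
        transcript_de=str(paths["transcript_de"]),
        protein_de=str(paths["protein_de"]),
        ppi=str(paths["ppi"]),
        mirna_targets=str(paths["mirna_targets"]),
        regulators=str(paths["regulators"]),
        annotations=str(paths["annotations"]),
        outdir=str(outdir / "results"),
        seed=seed,
        consensus=ConsensusParams(seed=seed),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all (non-skipped) stages; returns the run manifest dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(cfg).items()
        },
        "stages": {},
    }
    current_stage = "setup"
    try:
        transcripts = pd.read_csv(cfg.transcript_de, sep="\t")
        proteins = pd.read_csv(cfg.protein_de, sep="\t")
        mirna_targets = _read_lines(cfg.mirna_targets)
        regulators = _read_lines(cfg.regulators)

        # ---- crosstalk ------------------------------------------------
        deg_set: set[str] = set()
        dep_gene_set: set[str] = set()
        table = classify_crosstalk(transcripts, proteins, cfg.thresholds)
        deg_set = set(table.loc[table["t_status"] != "unchanged", "gene_id"])
        dep_gene_set = set(table.loc[table["p_status"] != "unchanged", "gene_id"])
        if "crosstalk" not in cfg.skip:
            current_stage = "crosstalk"
            t0 = time.perf_counter()
            summary = summarize_crosstalk(table["category"].dropna().astype(int))
            write_crosstalk(table, summary, outdir)
            manifest["stages"]["crosstalk"] = {
                "n_features": int(len(table)),
                "counts": {str(k): v for k, v in sorted(summary.counts.items())},
                "fraction_5_to_8": summary.fraction_5_to_8,
                "seconds": round(time.perf_counter() - t0, 3),
            }

        expression = pd.read_csv(cfg.expression, sep="\t", index_col=0)
        background = sorted(set(expression.index) | set(transcripts["gene_id"]) | set(proteins["gene_id"]))

        # ---- enrichment ----------------------------------------------
        if "enrichment" not in cfg.skip:
            current_stage = "enrichment"
            t0 = time.perf_counter()
            annotation = read_gmt(cfg.annotations)
            groups = {
                "transcript_up": set(table.loc[table["t_status"] == "up", "gene_id"]),
                "transcript_down": set(table.loc[table["t_status"] == "down", "gene_id"]),
                "protein_up": set(table.loc[table["p_status"] == "up", "gene_id"]),
                "protein_down": set(table.loc[table["p_status"] == "down", "gene_id"]),
            }
            cells = []
            for gid, members in groups.items():
                cells.extend(fisher_enrichment(members, background, annotation, group_id=gid))
            heatmap = build_heatmap_matrix(cells, alpha=cfg.enrichment_alpha)
            write_enrichment(cells, heatmap, outdir)
            manifest["stages"]["enrichment"] = {
                "n_terms": len(annotation),
                "n_cells": len(cells),
                "n_heatmap_rows": int(len(heatmap.values)),
                "seconds": round(time.perf_counter() - t0, 3),
            }

        # ---- grn ------------------------------------------------------
        consensus = ConsensusNetwork()
        if "grn" not in cfg.skip:
            current_stage = "grn"
            t0 = time.perf_counter()
            zm = preprocess(expression)
            de_union = deg_set | dep_gene_set | set(mirna_targets)
            retained = retention_filter(zm, de_union | set(regulators))
            params = ConsensusParams(
                n_subsets=cfg.consensus.n_subsets,
                subset_fraction=cfg.consensus.subset_fraction,
                confidence=cfg.consensus.confidence,
                max_regulators_per_target=cfg.consensus.max_regulators_per_target,
                seed=cfg.seed,
            )
            try:
                roles = assign_roles(deg_set, dep_gene_set, regulators, mirna_targets, retained)
                consensus = consensus_network(zm.loc[sorted(retained)], roles, params)
            except InferenceError as exc:
                warnings.warn(f"regulatory inference skipped: {exc}")
                consensus = ConsensusNetwork(n_subsets=params.n_subsets)
            write_consensus(consensus, params, outdir)
            manifest["stages"]["grn"] = {
                "n_retained": len(retained),
                "n_edges": len(consensus),
                "min_count": params.min_count,
                "seed": params.seed,
                "seconds": round(time.perf_counter() - t0, 3),
            }

        # ---- integration ---------------------------------------------
        graph = None
        if "integration" not in cfg.skip:
            current_stage = "integration"
            t0 = time.perf_counter()
            ppi_raw = pd.read_csv(cfg.ppi, sep="\t")
            nodes = select_ppi_input(consensus, dep_gene_set, mirna_targets, deg_set)
            ppi = filter_ppi(ppi_raw, nodes, cfg.ppi_min_score)
            category_map = {}
            if cfg.categories:
                cat_df = pd.read_csv(cfg.categories, sep="\t")
                category_map = dict(zip(cat_df.iloc[:, 0], cat_df.iloc[:, 1]))
            graph = integrate(
                consensus, ppi, mirna_targets, deg_set, dep_gene_set, category_map
            )
            write_integrated(graph, outdir)
            manifest["stages"]["integration"] = {
                "n_ppi_nodes_selected": len(nodes),
                "n_ppi_edges": int(len(ppi)),
                "n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
                "seconds": round(time.perf_counter() - t0, 3),
            }

        # ---- hubs -----------------------------------------------------
        if "hubs" not in cfg.skip and graph is not None:
            current_stage = "hubs"
            t0 = time.perf_counter()
            simple = simple_projection(graph)
            if simple.number_of_nodes() == 0:
                warnings.warn("integrated network is empty; no hubs to call")
                manifest["stages"]["hubs"] = {"n_hubs": 0, "hubs": []}
            else:
                table6, result = rank_and_call(
                    simple,
                    k=cfg.top_k,
                    epc_params=EpcParams(replicates=cfg.epc_replicates, seed=cfg.seed),
                )
                write_hub_results(table6, result, outdir)
                manifest["stages"]["hubs"] = {
                    "n_hubs": len(result.hubs),
                    "hubs": result.hubs,
                    "first_rank_counts": result.first_rank_counts,
                    "seconds": round(time.perf_counter() - t0, 3),
                }
    except VigornetError:
        (outdir / "FAILED").write_text(f"stage: {current_stage}\n")
        logger.error("pipeline failed at stage %s", current_stage)
        raise
    except Exception as exc:  # unexpected failure: still mark the stage
        (outdir / "FAILED").write_text(f"stage: {current_stage}\n{exc}\n")
        logger.error("pipeline failed at stage %s: %s", current_stage, exc)
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
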
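"""End-to-end orchestration: DEA -> merge -> network -> hubs -> enrichment
-> drug match, with file-based and in-memory entry points."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

import hubdrug
from hubdrug import centrality, dea, drugs, enrichment, expression, network
from hubdrug.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_drug_table,
    simulate_expression,
    simulate_gene_sets,
    simulate_interactions,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All analysis thresholds in one place; defaults follow the study
    conventions (adj p < 0.05, |logFC| > 1, score > 0.8, <= 2 added
    neighbors per seed, top 15% hubs, >= 3 genes per enriched term,
    kappa > 0.4)."""

    alpha: float = 0.05
    lfc_min: float = 1.0
    score_min: float = 0.8
    max_new_per_node: int = 2
    hub_fraction: float = 0.15
    enrich_min_genes: int = 3
    kappa_min: float = 0.4
    adjust_method: str = "bh"
    normalization_method: str = "quantile"
    core_mode: str = "largest_component"
    kcore_k: int = 2
    closeness_variant: str = "component"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.hub_fraction <= 1:
            raise ValueError("alpha in (0,1) and hub_fraction in (0,1] required")
        if not 0 <= self.score_min <= 1:
            raise ValueError("score_min must lie in [0, 1]")
        if self.adjust_method not in dea.ADJUST_METHODS:
            raise ValueError(f"unknown adjust_method: {self.adjust_method!r}")
        if self.normalization_method not in expression.NORMALIZATION_METHODS:
            raise ValueError(f"unknown normalization_method: {self.normalization_method!r}")
        if self.core_mode not in network.CORE_MODES:
            raise ValueError(f"unknown core_mode: {self.core_mode!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        config = cls(**payload)
        config.validate()
        return config


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def analyze(
    matrices,
    annotation: pd.DataFrame,
    interactions: pd.DataFrame,
    gene_sets=None,
    drug_table: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full analysis in memory; returns all intermediates.

    ``matrices`` is one :class:`ExpressionMatrix` per platform.  The
    enrichment query is the final network's node set against the union
    of platform panels as universe.
    """
    config = config or PipelineConfig()
    config.validate()
    results: dict = {"config": asdict(config)}
    stage = "dea"
    try:
        per_platform, flagged = [], []
        for matrix in matrices:
            norm = expression.normalize(matrix, config.normalization_method)
            table = dea.dea_table(norm, annotation, adjust_method=config.adjust_method)
            per_platform.append(table)
            flagged.append(dea.flag_degs(table, alpha=config.alpha, lfc_min=config.lfc_min))
        merged = dea.merge_platforms(flagged)
        results.update(dea_tables=per_platform, flagged=flagged, merged=merged)

        stage = "network"
        seeds = list(merged["gene"])
        interactions = network.normalize_interactions(interactions)
        seed_graph = network.build_seed_network(seeds, interactions, config.score_min)
        graph = network.expand_network(
            seed_graph, interactions, config.score_min, config.max_new_per_node
        )
        core = network.analysis_core(graph, config.core_mode, config.kcore_k)
        results.update(graph=graph, core=core)

        stage = "hubs"
        selection = centrality.select_hubs(
            core, config.hub_fraction, config.closeness_variant
        )
        hub_table = centrality.attach_logfc(selection, merged, config.lfc_min)
        results.update(selection=selection, hub_table=hub_table)

        stage = "enrichment"
        if gene_sets:
            universe = set()
            for matrix in matrices:
                universe |= set(matrix.gene_ids)
            enr = enrichment.enrich(
                set(graph.nodes),
                gene_sets,
                universe,
                alpha=config.alpha,
                min_genes=config.enrich_min_genes,
                adjust_method=config.adjust_method,
            )
            results["enrichment"] = enr
            results["term_network"] = (
                enrichment.term_network(enr, gene_sets, universe, config.kappa_min)
                if len(enr)
                else None
            )

        stage = "drug_match"
        if drug_table is not None:
            candidates = drugs.rank_drugs(drugs.match_drugs(hub_table, drug_table))
            results["candidates"] = candidates
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, exc) from exc

    results["summary"] = _summarize(results, config)
    return results


def _summarize(results: dict, config: PipelineConfig) -> dict:
    summary = {
        "version": hubdrug.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_flagged_per_platform": [int(len(f)) for f in results.get("flagged", [])],
        "n_merged_degs": int(len(results["merged"])),
        "network_nodes": results["graph"].number_of_nodes(),
        "network_edges": results["graph"].number_of_edges(),
        "core_nodes": results["core"].number_of_nodes(),
        "n_hub_selections": len(results["selection"].selections),
        "n_hub_union": len(results["selection"].union_genes),
        "n_hubs_for_drug_query": int(len(results["hub_table"])),
    }
    if "enrichment" in results:
        summary["n_enriched_terms"] = int(len(results["enrichment"]))
    if "candidates" in results:
        summary["ranked_drugs"] = [
            {
                "drug": c.drug,
                "n_matched": c.n_matched,
                "sum_abs_logFC": round(c.sum_abs_logfc, 6),
                "matched_genes": [g for g, _, _ in c.matched],
            }
            for c in results["candidates"]
        ]
    return summary


def run_synthetic_study(
    sim_config: SimulationConfig, config: PipelineConfig | None = None
) -> tuple[dict, GroundTruth]:
    """Simulate a complete study and analyze it; returns (results, truth)."""
    matrices, annotation, truth = simulate_expression(sim_config)
    interactions = simulate_interactions(sim_config, truth)
    gene_sets = simulate_gene_sets(sim_config, truth)
    drug_table = simulate_drug_table(sim_config, truth)
    results = analyze(matrices, annotation, interactions, gene_sets, drug_table, config)
    return results, truth


# ---------------------------------------------------------------------------
# recovery metrics against planted truth


def deg_recovery(merged: pd.DataFrame, truth: GroundTruth) -> dict:
    """Sensitivity and empirical FDR of the merged DEG call set."""
    called = set(merged["gene"])
    true = set(truth.de_genes)
    tp = len(called & true)
    sensitivity = tp / len(true) if true else float("nan")
    fdr = (len(called) - tp) / len(called) if called else 0.0
    return {"sensitivity": sensitivity, "fdr": fdr, "n_called": len(called)}


def hub_jaccard(selection, truth: GroundTruth) -> float:
    union = set(selection.union_genes)
    planted = set(truth.hub_genes)
    if not union | planted:
        return float("nan")
    return len(union & planted) / len(union | planted)


def top_drug(results: dict) -> str | None:
    cands = results.get("candidates") or []
    return cands[0].drug if cands else None


# ---------------------------------------------------------------------------
# file-based pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    expression_paths: list,
    annotation_path,
    interactions_path,
    gmt_path=None,
    drug_table_path=None,
    out_dir="hubdrug_out",
) -> dict:
    """File-based pipeline: read inputs, run :func:`analyze`, write every
    intermediate table plus summary.json and a checksum MANIFEST.

    A stage failure still writes a MANIFEST marking the run incomplete,
    then re-raises :class:`PipelineError`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        annotation = expression.read_annotation_tsv(annotation_path)
        by_platform = annotation.drop_duplicates("sample").set_index("sample")["platform"]
        matrices = []
        for path in expression_paths:
            m = expression.read_expression_tsv(path)
            platforms = {by_platform.get(s) for s in m.sample_ids}
            if len(platforms) != 1 or None in platforms:
                raise ValueError(f"samples of {path} do not map to a single platform")
            m.platform = platforms.pop()
            matrices.append(m)
        interactions = network.load_interactions(interactions_path)
        gene_sets = enrichment.read_gmt(gmt_path) if gmt_path else None
        drug_table = drugs.read_drug_table(drug_table_path) if drug_table_path else None

        results = analyze(matrices, annotation, interactions, gene_sets, drug_table, config)

        for table, platform in zip(results["dea_tables"], [m.platform for m in matrices]):
            p = out / f"dea_{platform}.tsv"
            table.to_csv(p, sep="\t", index=False)
            written.append(p)
        p = out / "merged_degs.tsv"
        results["merged"].to_csv(p, sep="\t", index=False)
        written.append(p)
        network.write_graph(results["graph"], out / "network_edges.tsv", out / "network_nodes.tsv")
        written += [out / "network_edges.tsv", out / "network_nodes.tsv"]
        p = out / "centrality.tsv"
        centrality.centrality_table(results["core"], results["selection"]).to_csv(
            p, sep="\t", index=False
        )
        written.append(p)
        p = out / "hubs.tsv"
        results["hub_table"].to_csv(p, sep="\t", index=False)
        written.append(p)
        if "enrichment" in results:
            p = out / "enrichment.tsv"
            results["enrichment"].to_csv(p, sep="\t", index=False)
            written.append(p)
        if results.get("candidates") is not None:
            p = out / "drug_candidates.tsv"
            drugs.candidates_table(results["candidates"]).to_csv(p, sep="\t", index=False)
            written.append(p)
        p = out / "summary.json"
        with open(p, "w") as fh:
            json.dump(results["summary"], fh, indent=1, sort_keys=True)
        written.append(p)
    except Exception as exc:
        manifest = {
            "complete": False,
            "error": str(exc),
            "files": {f.name: _sha256(f) for f in written},
        }
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("io", exc) from exc

    manifest = {"complete": True, "files": {f.name: _sha256(f) for f in written}}
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results["summary"]


def write_simulation(sim_config: SimulationConfig, out_dir) -> GroundTruth:
    """Generate a synthetic study and write every input file the pipeline
    reads (expression TSVs, annotation, interactions, GMT, drug table,
    truth JSON, simulation config echo)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, annotation, truth = simulate_expression(sim_config)
    for m in matrices:
        expression.write_expression_tsv(m, out / f"expression_{m.platform}.tsv")
    expression.write_annotation_tsv(annotation, out / "annotation.tsv")
    simulate_interactions(sim_config, truth).to_csv(
        out / "interactions.tsv", sep="\t", index=False
    )
    enrichment.write_gmt(simulate_gene_sets(sim_config, truth), out / "gene_sets.gmt")
    simulate_drug_table(sim_config, truth).to_csv(
        out / "drug_targets.tsv", sep="\t", index=False
    )
    truth.to_json(out / "truth.json")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(asdict(sim_config), fh, indent=1, sort_keys=True)
    return truth
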
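"""End-to-end driver: simulate|load -> qc -> normalize -> score ->
ancestry -> dynamics -> report.

Each stage's failure halts the run with a stage-named error; the report
and manifest embed the config hash, seed and package version so a run is
reproducible bit-identically (timestamps are deliberately excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from mamshift.config import PipelineConfig
from mamshift.preprocessing import qc_filter, log_normalize
from mamshift.scoring import GeneSet, MAM_GENE_SET, module_score, stage_score_summary
from mamshift.ancestry import infer_conversions, select_trajectory_subclusters
from mamshift.dynamics import (
    stage_proportions,
    score_proportion_correlation,
    ordered_gene_trend,
    build_report,
    report_to_json,
    report_to_markdown,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _versions() -> dict:
    from importlib.metadata import version

    import mamshift
    import scipy
    return {"mamshift": mamshift.__version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "anndata": version("anndata")}


def run_pipeline(config: PipelineConfig, adata: ad.AnnData, truth=None,
                 out_dir=None) -> dict:
    """Run the full analysis on a (possibly simulated) cohort and return
    the report dict; written to ``out_dir`` as report.json / report.md /
    manifest.json when given."""
    config.validate()
    stages = [s for s in config.stages
              if s in set(adata.obs["stage"].astype(str))] or list(config.stages)

    def _run(stage_name, fn):
        try:
            return fn()
        except Exception as exc:                      # noqa: BLE001 - re-tag by stage
            raise PipelineError(stage_name, exc) from exc

    filtered, qc_report = _run("qc", lambda: qc_filter(
        adata, min_genes=config.min_genes, max_genes=config.max_genes))
    norm = _run("normalize", lambda: log_normalize(
        filtered, scale_factor=config.scale_factor))

    gene_set = (GeneSet.from_file(config.gene_set_path)
                if config.gene_set_path else MAM_GENE_SET)
    score = _run("score", lambda: module_score(
        norm, gene_set, n_bins=config.n_bins, n_ctrl=config.n_ctrl, seed=config.seed))
    stage_scores = _run("score", lambda: stage_score_summary(
        score, norm.obs, stages=stages, restrict_type="CM"))

    graph = _run("ancestry", lambda: infer_conversions(
        norm, stages=stages, k=config.k, gene_universe=config.gene_universe,
        n_hvg=config.ancestry_n_hvg))
    props = _run("dynamics", lambda: stage_proportions(
        norm.obs, stages=stages, restrict="CM"))
    selection = _run("ancestry", lambda: select_trajectory_subclusters(
        graph, props.fractions, min_frac=config.min_frac,
        min_support=config.min_support,
        strict_consistency=config.strict_consistency))

    corr = _run("dynamics", lambda: score_proportion_correlation(
        stage_scores["mean"], props, subtypes=tuple(config.score_subtypes)))
    trends = {}
    for gene in config.trend_genes:
        if gene in norm.var_names:
            trends[gene] = _run("dynamics", lambda g=gene: ordered_gene_trend(
                norm, g, stages=stages, scores=score.scores,
                window=min(config.trend_window, norm.n_obs),
                epsilon_frac=config.trend_epsilon))
        else:
            log.warning("trend gene %s absent from the matrix; skipped", gene)

    report = build_report(qc=qc_report, stage_scores=stage_scores,
                          proportions=props, selection=selection, trends=trends,
                          correlation=corr, config=config.to_dict(),
                          seed=config.seed, versions=_versions())
    if truth is not None:
        report["truth_summary"] = {
            "planted_edges": truth.planted_edges,
            "n_converting_cells": len(truth.cell_ancestor),
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report_to_json(report))
        (out_dir / "report.md").write_text(report_to_markdown(report))
        config_payload = json.dumps(config.to_dict(), sort_keys=True)
        manifest = {
            "config_hash": hashlib.sha256(config_payload.encode()).hexdigest(),
            "input_hash": adata.uns.get("config_hash", ""),
            "seed": config.seed,
            "versions": _versions(),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        selection.edges.to_csv(out_dir / "conversion_edges.tsv", sep="\t", index=False)
        props.fractions.to_csv(out_dir / "proportions.tsv", sep="\t")
        stage_scores.to_csv(out_dir / "stage_scores.tsv", sep="\t")
        score.scores.rename("score").to_csv(out_dir / "cell_scores.tsv", sep="\t")
    return report
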
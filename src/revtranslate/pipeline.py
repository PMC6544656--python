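"""End-to-end orchestration of the reverse-translation pipeline.

Runs the expression arm (preprocess -> differential expression ->
coexpression network -> hubs/centrality) and the cohort arm (marker
table -> panel classifier -> clinical statistics) from a single config,
communicating between stages only via files so every stage is
re-entrant and auditable, and records a manifest with parameters, seed
and sha256 hashes of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clinical, coexpression, diffexpr, hubs, io, panel, preprocess, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage parameters for the full pipeline; defaults follow the study."""

    seed: int = 0
    out_dir: str = "run"
    # simulation (used when no input paths are given)
    expression: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    # preprocess
    lower_pct: float = 20.0
    # differential expression
    p_threshold: float = 0.01
    fc_cutoff: float = 1.0
    # network
    beta: float = coexpression.DEFAULT_BETA
    min_module_size: int = 20
    cut_height: float = 0.99
    merge_cut_height: float = 0.25
    edge_cutoff: float = 0.2
    # panel
    markers: tuple[str, ...] = ("RGS1", "CCL4")
    fraction: float = 0.5
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "markers" in raw:
            raw["markers"] = tuple(raw["markers"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Reruns with the same config and seed reproduce byte-identical tabular
    outputs.  A stage failure aborts with the stage name in the raised
    error; outputs of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "parameters": asdict(config), "stages": {}}
    stage = "simulate"
    try:
        expr_cfg = synthetic.ExprSimConfig(seed=config.seed, **config.expression)
        raw, traits, truth = synthetic.simulate_expression(expr_cfg)
        io.write_matrix(raw, out / "raw.tsv")
        io.write_traits(traits, out / "samples.tsv")
        truth.gene_module.to_csv(out / "truth.tsv", sep="\t")
        cohort_cfg = synthetic.CohortSimConfig(seed=config.seed + 1, **config.cohort)
        marker_expr, labels, subset = synthetic.simulate_qpcr_cohort(cohort_cfg)
        marker_expr.to_csv(out / "cohort_expression.csv")
        labels.to_frame().to_csv(out / "cohort_labels.csv")
        manifest["stages"][stage] = {
            "n_genes": int(raw.shape[0]),
            "n_samples": int(raw.shape[1]),
            "n_cohort": int(len(labels)),
        }

        stage = "preprocess"
        kept = preprocess.background_filter(raw, traits, config.lower_pct)
        norm = preprocess.baseline_transform(
            preprocess.quantile_normalize(raw.loc[kept])
        )
        norm = preprocess.drop_zero_variance(norm)
        io.write_matrix(norm, out / "norm.tsv")
        manifest["stages"][stage] = {"genes_kept": int(norm.shape[0])}

        stage = "diffexpr"
        de_res = diffexpr.moderated_t(norm, traits)
        table = diffexpr.de_table(de_res, config.p_threshold, config.fc_cutoff)
        de_res.to_csv(out / "de_all.tsv", sep="\t")
        table.to_csv(out / "de.tsv", sep="\t")
        manifest["stages"][stage] = {"n_significant": int(len(table))}

        stage = "coexpression"
        cor = coexpression.correlation_matrix(norm)
        adj = coexpression.adjacency(cor, config.beta)
        tom = coexpression.topological_overlap(adj)
        detection = coexpression.detect_modules(
            tom,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_cut_height=config.merge_cut_height,
            expr=norm,
        )
        mt, top = coexpression.module_trait_table(
            detection.eigengenes, traits, config.alpha
        )
        detection.labels.to_csv(out / "modules.tsv", sep="\t")
        detection.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        mt.to_csv(out / "module_trait.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_modules": int(detection.labels.max()),
            "n_significant_modules": int(mt["significant"].sum()),
            "top_module": None if top is None else int(top),
        }

        stage = "hubs_centrality"
        stats = hubs.gene_module_statistics(
            norm, detection.labels, detection.eigengenes, traits, adj
        )
        selection = hubs.select_hub_genes(stats)
        stats.to_csv(out / "gene_stats.tsv", sep="\t")
        selection.hubs.to_csv(out / "hubs.tsv", sep="\t")
        if top is not None:
            module_genes = detection.labels.index[detection.labels == top]
            graph = hubs.threshold_graph(adj, module_genes, config.edge_cutoff)
            centrality = hubs.stress_centrality(graph)
            centrality.to_csv(out / "centrality.tsv", sep="\t")
            hubs.export_network(graph, centrality, stats, out)
        manifest["stages"][stage] = {"n_hubs": int(len(selection.hubs))}

        stage = "biomarker_panel"
        result = panel.classify_samples(
            marker_expr, labels, config.markers, config.fraction
        )
        result.summary.to_csv(out / "panel_summary.csv")
        result.calls.to_csv(out / "panel_calls.csv")
        diff_cor = panel.differential_correlation_matrix(
            marker_expr, labels, config.alpha
        )
        diff_cor.to_csv(out / "differential_correlation.csv", index=False)
        with open(out / "panel.json", "w") as fh:
            json.dump(
                {
                    "thresholds": result.thresholds,
                    "summary": result.summary.to_dict(orient="index"),
                    "fraction": result.fraction,
                },
                fh,
                indent=2,
            )
        manifest["stages"][stage] = {
            "combined_sensitivity": float(result.summary.loc["combination", "sensitivity"]),
            "combined_specificity": float(result.summary.loc["combination", "specificity"]),
        }

        stage = "clinical_stats"
        clin_cfg = synthetic.table4_clinical_config()
        clin = synthetic.simulate_clinical_table(clin_cfg, seed=config.seed + 2)
        positive = pd.Series(
            clin["group"] == "marker_positive", index=clin.index
        )
        report = clinical.group_comparison_table(clin, positive)
        report.to_csv(out / "clinical_report.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_rows": int(len(report))}
    except Exception as exc:  # annotate the failing stage, keep partial outputs
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
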
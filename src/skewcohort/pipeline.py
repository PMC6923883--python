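"""End-to-end orchestration: skewness -> splits -> differences -> mixture
categories -> enrichment, and/or tails -> differential methylation.

A PipelineConfig (usually loaded from YAML) names the inputs and parameters;
``run_pipeline`` executes the stages that the inputs enable, writes every
artifact under ``outdir`` and returns a JSON-serializable run report with
per-stage record counts.  A fixed config and seed reproduces identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import convergence, enrich, io, methlink, mixcat, skewcore, tailsplit

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, outputs and knobs of one pipeline run."""

    expression: str | None = None
    expression_second: str | None = None
    first_name: str = "first"
    second_name: str = "second"
    platform: str = "other"
    methylation: str | None = None
    methylation_is_beta: bool = False
    annotation: str | None = None
    gmt: str | None = None
    outdir: str = "skewcohort_out"
    unbiased: bool = False
    tail_method: str = "quantile"
    q: float = 0.1
    z_threshold: float = 2.5
    alpha: float = 0.01
    enrich_alpha: float = 0.05
    top_n: int = 500
    n_unique: int = 1269
    min_tail: int = 5
    seed: int = 0
    force_k3: bool = True
    smooth_window: int = 3

    def __post_init__(self) -> None:
        for name in ("alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.expression is None:
            raise ValueError("pipeline requires an expression matrix")
        for name in ("expression", "expression_second", "methylation", "annotation", "gmt"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValueError(f"{name} path does not exist: {path}")
        if self.methylation is not None and self.annotation is None:
            raise ValueError("methylation analysis requires a probe annotation")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}

    def stage(name):
        log.info("pipeline stage: %s", name)
        return report["stages"].setdefault(name, {})

    try:
        matrix = io.read_matrix(config.expression, "expression", platform=config.platform)
        skew = skewcore.compute_skewness(matrix, unbiased=config.unbiased)
        io.write_skew_table(skew, outdir / "skewness_first.tsv")
        split = skewcore.gene_split(skew, dataset=config.first_name)
        stage("skew")["n_genes"] = int(skew.shape[0])
        stage("split").update(
            {"fraction_negative": split.fraction_negative, "n_genes": split.n_genes}
        )
    except Exception as exc:
        raise RuntimeError(f"[stage skew] {exc}") from exc

    if config.expression_second is not None:
        try:
            second = io.read_matrix(config.expression_second, "expression", platform=config.platform)
            skew2 = skewcore.compute_skewness(second, unbiased=config.unbiased)
            io.write_skew_table(skew2, outdir / "skewness_second.tsv")
            diffs = skewcore.skew_difference(skew, skew2, config.first_name, config.second_name)
            diffs.rename_axis("gene_id").to_csv(outdir / "skew_differences.tsv", sep="\t")
            stage("diff")["n_genes"] = int(diffs.shape[0])
        except Exception as exc:
            raise RuntimeError(f"[stage diff] {exc}") from exc
        try:
            fit = mixcat.fit_skew_mixture(diffs, seed=config.seed)
            fit.table.to_csv(outdir / "mixture_bic.tsv", sep="\t", index=False)
            categories = mixcat.assign_categories(fit, force_k3=config.force_k3)
            categories.rename_axis("gene_id").to_csv(outdir / "categories.tsv", sep="\t")
            stage("categorize").update(
                {"selected_k": fit.selected_k,
                 "counts": categories["category"].value_counts().to_dict()}
            )
        except Exception as exc:
            raise RuntimeError(f"[stage categorize] {exc}") from exc
        if config.gmt is not None:
            try:
                collection = io.read_gmt(config.gmt)
                results = enrich.overrepresentation_test(
                    categories, collection, alpha=config.enrich_alpha
                )
                results.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                summary = enrich.summarize_top_pathways(results)
                summary.to_csv(outdir / "enrichment_top10.tsv", sep="\t", index=False)
                stage("enrich").update(
                    {"n_tests": int(results.shape[0]),
                     "n_significant": int(results["significant"].sum()) if len(results) else 0}
                )
            except Exception as exc:
                raise RuntimeError(f"[stage enrich] {exc}") from exc

    if config.methylation is not None:
        try:
            tails = tailsplit.split_cohort(
                matrix, skew, method=config.tail_method,
                q=config.q, z_threshold=config.z_threshold,
            )
            io.write_tail_assignments(tails, outdir / "tails.tsv")
            stage("tails")["n_genes"] = len(tails)
        except Exception as exc:
            raise RuntimeError(f"[stage tails] {exc}") from exc
        try:
            if config.methylation_is_beta:
                beta = io._read_tsv_matrix(config.methylation)
                meth = methlink.beta_to_mvalue(beta)
            else:
                meth = io.read_matrix(config.methylation, "methylation")
            annotation = io.read_annotation(config.annotation)
            probes = methlink.probe_dm_test(meth, tails, annotation, min_tail=config.min_tail)
            probes.to_csv(outdir / "probe_dm.tsv", sep="\t", index=False)
            summaries = methlink.summarize_genes(probes, skew, alpha=config.alpha)
            summaries.to_csv(outdir / "gene_dm.tsv", sep="\t", index=False)
            top = methlink.select_top_genes(summaries, n=config.top_n)
            quad = methlink.quadrant_analysis(top)
            grid = list(range(100, config.top_n + 1, 25)) or [config.top_n]
            sweep = methlink.robustness_sweep(
                summaries, n_grid=grid, smooth_window=config.smooth_window
            )
            sweep.to_csv(outdir / "robustness.tsv", sep="\t", index=False)
            correlations = {}
            for region in methlink.ALL_REGIONS:
                try:
                    res = methlink.correlation_with_ci(top, region)
                    correlations[region] = {
                        "n": res.n, "r": res.r, "ci": [res.ci_low, res.ci_high]
                    }
                except ValueError:
                    correlations[region] = None
            with open(outdir / "methlink.json", "w") as fh:
                json.dump(
                    {
                        "quadrant_counts": quad.counts.to_dict(orient="index"),
                        "fisher": quad.fisher.to_dict(orient="records"),
                        "correlations": correlations,
                    },
                    fh, indent=1,
                )
            stage("methlink").update(
                {"n_probes": int(probes.shape[0]), "n_genes": int(summaries.shape[0]),
                 "n_top": int(top.shape[0]), "correlations": correlations}
            )
        except Exception as exc:
            raise RuntimeError(f"[stage methlink] {exc}") from exc

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
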
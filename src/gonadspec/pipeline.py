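"""End-to-end pipeline: quantify -> prefilter -> classify -> enrich -> screen.

Runs either on TSV inputs or in synthetic mode (a SimConfig), writes every
stage's table plus a JSON summary and a log, and returns the summary.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io, simulate
from .candidates import records_to_frame, screen_candidates
from .enrichment import enrich, results_to_frame
from .quantify import compute_rpkm, filter_expressed
from .simulate import SimConfig
from .specificity import classify_all
from .types import ConfigError, ExpressionMatrix, InputError

log = logging.getLogger("gonadspec")


@dataclass
class PipelineConfig:
    """Inputs and thresholds of one pipeline run.

    Exactly one of ``sim`` (synthetic mode) or ``counts_path`` (file mode)
    must be supplied.  Defaults mirror the study: RPKM prefilter threshold
    3, specificity fold threshold 5, adjusted-p cutoff 0.05.
    """

    out_dir: str | Path = "gonadspec_out"
    sim: SimConfig | None = None
    counts_path: str | None = None
    models_path: str | None = None
    metadata_path: str | None = None
    go_map_path: str | None = None
    kegg_map_path: str | None = None
    homolog_path: str | None = None
    rpkm_threshold: float = 3.0
    fold_threshold: float = 5.0
    p_adj_cutoff: float = 0.05
    allow_nonstandard_layout: bool = False
    top_terms: int = 10

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.counts_path is None):
            raise ConfigError("supply exactly one of a SimConfig or a counts path")
        if self.counts_path is not None and (
            self.models_path is None or self.metadata_path is None
        ):
            raise ConfigError("file mode needs counts, gene-model and metadata paths")
        if min(self.rpkm_threshold, self.fold_threshold, self.p_adj_cutoff) <= 0:
            raise ConfigError("thresholds must be positive")


def _load_inputs(config: PipelineConfig, out: Path):
    if config.sim is not None:
        counts, models, metadata, truth = simulate.simulate_dataset(config.sim)
        simulate.write_dataset(counts, models, metadata, truth, out / "dataset")
        lengths = pd.Series(
            {m.gene_id: m.length_bp for m in models}, dtype=float, name="length_bp"
        )
        go_map = simulate.term_map_from_models(models, "go")
        kegg_map = simulate.term_map_from_models(models, "kegg")
        return counts, lengths, metadata, go_map, {}, kegg_map, {}, truth

    counts = io.read_counts(config.counts_path)
    models = io.read_models(config.models_path)
    metadata = io.read_metadata(config.metadata_path)
    lengths = models["length_bp"].astype(float)
    go_map, go_names = ({}, {})
    kegg_map, kegg_names = ({}, {})
    if config.go_map_path:
        go_map, go_names = io.read_term_map(config.go_map_path)
    elif "go_terms" in models:
        go_map = {g: set(t) for g, t in models["go_terms"].items() if t}
    if config.kegg_map_path:
        kegg_map, kegg_names = io.read_term_map(config.kegg_map_path)
    elif "kegg_pathways" in models:
        kegg_map = {g: set(t) for g, t in models["kegg_pathways"].items() if t}
    return counts, lengths, metadata, go_map, go_names, kegg_map, kegg_names, None


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write outputs under ``config.out_dir``.

    Outputs: the input dataset (synthetic mode), rpkm.tsv,
    expressed_genes.txt, specificity.tsv, enrichment_{go,kegg}_{ovary,testis}.tsv,
    candidates.tsv (when a homolog table is supplied), summary.json, run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (InputError, ConfigError) as e:
                raise type(e)(f"[{name}] {e}") from e

        return wrapper

    return deco


def _run(config: PipelineConfig, out: Path) -> dict:
    log.info("gonadspec %s", __version__)
    log.info("config: %s", config)

    counts, lengths, metadata, go_map, go_names, kegg_map, kegg_names, truth = _stage(
        "input"
    )(_load_inputs)(config, out)
    log.info("loaded %d genes x %d samples", len(counts.gene_ids), len(counts.sample_ids))

    expr = _stage("quantify")(compute_rpkm)(counts, lengths, metadata)
    expr.rpkm.rename_axis("gene_id").to_csv(out / "rpkm.tsv", sep="\t", float_format="%.6g")

    expressed = _stage("prefilter")(filter_expressed)(expr, threshold=config.rpkm_threshold)
    (out / "expressed_genes.txt").write_text("".join(g + "\n" for g in expressed))
    log.info("%d of %d genes pass the RPKM > %g prefilter",
             len(expressed), len(counts.gene_ids), config.rpkm_threshold)

    result = _stage("specificity")(classify_all)(
        expr,
        expressed,
        fold_threshold=config.fold_threshold,
        allow_nonstandard_layout=config.allow_nonstandard_layout,
    )
    _write_tsv(result.to_frame(), out / "specificity.tsv")
    log.info("%d ovary-specific, %d testis-specific genes",
             len(result.ovary_specific), len(result.testis_specific))

    summary_enrich = {}
    for ns, term_map, names in (("go", go_map, go_names), ("kegg", kegg_map, kegg_names)):
        for direction, gene_set in (
            ("ovary", result.ovary_specific),
            ("testis", result.testis_specific),
        ):
            if not term_map:
                continue
            res = _stage("enrichment")(enrich)(gene_set, expressed, term_map, names)
            _write_tsv(results_to_frame(res), out / f"enrichment_{ns}_{direction}.tsv")
            top = [
                {"term_id": r.term_id, "genes": r.observed_k,
                 "expected": round(r.expected, 2), "p_value": r.p_raw,
                 "p_adjusted": r.p_adj}
                for r in res[: config.top_terms]
                if r.p_adj < config.p_adj_cutoff
            ]
            summary_enrich[f"{ns}_{direction}"] = {
                "n_terms_tested": len(res),
                "n_significant": sum(1 for r in res if r.p_adj < config.p_adj_cutoff),
                "top_terms": top,
            }

    candidate_summary = None
    if config.homolog_path:
        table = _stage("screen")(io.read_homolog_table)(config.homolog_path)
        records = _stage("screen")(screen_candidates)(result, table, expr)
        _write_tsv(records_to_frame(records), out / "candidates.tsv")
        candidate_summary = {
            r.pathway_gene: r.rendered for r in records
        }

    summary = {
        "version": __version__,
        "n_genes": len(counts.gene_ids),
        "n_samples": len(counts.sample_ids),
        "layout": expr.layout(),
        "n_expressed": len(expressed),
        "n_ovary_specific": len(result.ovary_specific),
        "n_testis_specific": len(result.testis_specific),
        "rpkm_threshold": config.rpkm_threshold,
        "fold_threshold": config.fold_threshold,
        "enrichment": summary_enrich,
        "candidates": candidate_summary,
    }
    if truth is not None and len(truth.labels):
        planted_ov = set(truth.genes_with_label("ovary_specific"))
        planted_te = set(truth.genes_with_label("testis_specific"))
        called_ov, called_te = set(result.ovary_specific), set(result.testis_specific)
        n_planted = len(planted_ov) + len(planted_te)
        background = set(truth.labels.index) - planted_ov - planted_te
        tp = len(called_ov & planted_ov) + len(called_te & planted_te)
        fp = len((called_ov | called_te) & background)
        summary["truth"] = {
            "n_planted": n_planted,
            "sensitivity": tp / n_planted if n_planted else None,
            "false_positive_rate": fp / len(background) if background else None,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("summary written to %s", out / "summary.json")
    return summary
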
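"""Candidate sex-determining-pathway gene screen.

Given the specificity verdicts and a table mapping named pathway genes
(e.g. Sry/Sox30/SoxH, FoxL2, MAB-3/dsx/Dmrt1) to their homologs in the
dataset, produce a presence / sex-specificity record per pathway gene
rendered in the two-sign convention (first sign: a homolog is present;
second: some homolog is sex-specifically expressed), plus per-gene
fold changes and per-group expression profiles.

Homology search itself is out of scope: the homolog table is an input.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .specificity import ClassificationResult
from .types import CandidateRecord, ExpressionMatrix, ExpressionProfile, InputError


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of two mean expression values, a / b.

    b = 0 with a > 0 gives +inf; a = b = 0 gives NaN (undefined).
    """
    if mean_a < 0 or mean_b < 0:
        raise InputError("mean expression values must be non-negative")
    if mean_b == 0:
        return np.inf if mean_a > 0 else np.nan
    return mean_a / mean_b


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, as used in prose-style fold reporting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def render_fold(x: float, ndigits: int = 1) -> str:
    """'5.3'-style rendering; 'inf' and 'NA' for the sentinels."""
    if np.isnan(x):
        return "NA"
    if np.isinf(x):
        return "inf"
    return f"{round_half_up(x, ndigits):.{ndigits}f}"


def profile_gene(gene_id: str, expr: ExpressionMatrix) -> ExpressionProfile:
    """Per-group mean and standard deviation of one gene's RPKM.

    Ovary and testis replicates form one group each; every somatic organ
    and every developmental stage is its own group (by its ``label``).
    The standard deviation uses the n-1 denominator and is 0 for a
    single-sample group.  Groups with no samples are omitted.
    """
    if gene_id not in expr.rpkm.index:
        raise InputError(f"unknown gene {gene_id!r}")
    row = expr.rpkm.loc[gene_id]

    groups: list[tuple[str, list[str]]] = []
    for gonad in ("ovary", "testis"):
        samples = expr.samples_in_group(gonad)
        if samples:
            groups.append((gonad, samples))
    for group in ("somatic", "stage"):
        members = expr.sample_groups[expr.sample_groups["group"] == group]
        for label in dict.fromkeys(members["label"]):
            samples = [
                s for s in expr.rpkm.columns
                if s in set(members.index[members["label"] == label])
            ]
            if samples:
                groups.append((label, samples))

    stats = pd.DataFrame(
        {
            "n": [len(s) for _, s in groups],
            "mean": [float(row[s].mean()) for _, s in groups],
            "sd": [float(row[s].std(ddof=1)) if len(s) > 1 else 0.0 for _, s in groups],
        },
        index=pd.Index([name for name, _ in groups], name="group"),
    )
    return ExpressionProfile(gene_id=gene_id, stats=stats)


def screen_candidates(
    calls: ClassificationResult,
    homolog_table: pd.DataFrame,
    expr: ExpressionMatrix,
) -> list[CandidateRecord]:
    """Build one presence / sex-specificity record per pathway gene.

    ``homolog_table`` needs columns ``pathway_gene`` and ``homolog_ids``
    (a list, or semicolon-separated string, possibly empty).  A pathway
    gene is present when it has at least one homolog; it is sex-specific
    when any homolog carries an ovary or testis verdict.  The record-level
    testis/ovary fold is computed for the representative homolog — the one
    with the greatest combined gonadal mean RPKM — with every homolog's
    verdict and fold listed in ``notes``.
    """
    required = {"pathway_gene", "homolog_ids"}
    if not required <= set(homolog_table.columns):
        raise InputError(f"homolog table must have columns {sorted(required)}")
    ov_samples = expr.samples_in_group("ovary")
    te_samples = expr.samples_in_group("testis")

    records = []
    for _, row in homolog_table.iterrows():
        raw = row["homolog_ids"]
        if isinstance(raw, str):
            homologs = [h for h in raw.split(";") if h]
        else:
            homologs = [h for h in (raw if isinstance(raw, (list, tuple)) else []) if h]
        missing = [h for h in homologs if h not in expr.rpkm.index]
        if missing:
            raise InputError(
                f"homolog {missing[0]!r} of {row['pathway_gene']!r} "
                "is absent from the expression matrix"
            )
        present = bool(homologs)
        sex = "none"
        notes = []
        best, best_signal = None, -1.0
        for h in homologs:
            v = calls.verdict_class(h)
            if v != "none" and sex == "none":
                sex = v
            mt = float(expr.rpkm.loc[h, te_samples].mean()) if te_samples else 0.0
            mo = float(expr.rpkm.loc[h, ov_samples].mean()) if ov_samples else 0.0
            notes.append(f"{h}: verdict={v}, testis/ovary fold={render_fold(fold_change(mt, mo))}")
            if mt + mo > best_signal:
                best, best_signal = (mt, mo), mt + mo
        fold = fold_change(*best) if best is not None else np.nan
        records.append(
            CandidateRecord(
                pathway_gene=str(row["pathway_gene"]),
                homolog_ids=homologs,
                present=present,
                sex_specific=sex,
                fold_testis_vs_ovary=fold,
                notes="; ".join(notes),
            )
        )
    return records


def records_to_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_gene": [r.pathway_gene for r in records],
            "presence": [r.present for r in records],
            "sex_specific": [r.sex_specific for r in records],
            "rendered": [r.rendered for r in records],
            "fold_testis_vs_ovary": [render_fold(r.fold_testis_vs_ovary) for r in records],
            "notes": [r.notes for r in records],
        }
    )
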
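"""RPKM quantification and the expressed-gene prefilter.

RPKM (reads per kilobase of transcript per million mapped reads) for a gene
with C mapped reads, exonic length L bp, in a library of N mapped reads:

    RPKM = C * 1e9 / (N * L)

The prefilter keeps genes whose RPKM exceeds a threshold (default 3,
strictly) in at least one of the 13 core libraries (3 ovary + 3 testis +
7 somatic); developmental-stage libraries are profiled but never counted
toward the prefilter.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import CountMatrix, ExpressionMatrix, InputError

SCALE = 1e9  # kilobase * million


def compute_rpkm(
    counts: CountMatrix,
    lengths: pd.Series,
    sample_groups: pd.DataFrame,
) -> ExpressionMatrix:
    """Convert a count matrix to RPKM.

    Parameters
    ----------
    counts
        Count matrix; its ``library_size`` supplies N per sample (by
        default the column sum, or an explicit mapped-read total).
    lengths
        Exonic length in bp per gene ID; every counted gene must have a
        positive length.
    sample_groups
        Sample metadata (``group``, ``label``) carried into the result.
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.counts.index.difference(lengths.index)
    if len(missing):
        raise InputError(f"missing length for gene(s): {missing.tolist()[:5]}")
    L = lengths.reindex(counts.counts.index)
    if (L <= 0).any():
        bad = L.index[L <= 0].tolist()
        raise InputError(f"non-positive length for gene(s): {bad[:5]}")
    N = counts.library_size
    if (N <= 0).any():
        bad = N.index[N <= 0].tolist()
        raise InputError(f"zero or negative library size for sample(s): {bad}")
    rpkm = counts.counts.to_numpy(dtype=float) * SCALE / (
        N.to_numpy()[None, :] * L.to_numpy()[:, None]
    )
    return ExpressionMatrix(
        rpkm=pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns),
        sample_groups=sample_groups,
    )


def filter_expressed(
    expr: ExpressionMatrix,
    core_samples: Sequence[str] | None = None,
    threshold: float = 3.0,
) -> list[str]:
    """Genes whose maximum RPKM over the core samples exceeds ``threshold``.

    The comparison is strict (RPKM must be larger than the threshold), and
    only the core gonadal + somatic samples count; a gene expressed solely
    in a developmental-stage library is excluded.  Input gene order is
    preserved.
    """
    if core_samples is None:
        core_samples = expr.core_samples()
    core_samples = list(core_samples)
    missing = [s for s in core_samples if s not in expr.rpkm.columns]
    if missing:
        raise InputError(f"core sample(s) not in matrix: {missing}")
    if not core_samples:
        return []
    keep = (expr.rpkm[core_samples] > threshold).any(axis=1)
    return expr.rpkm.index[keep].tolist()


def lengths_from_gff3(path) -> pd.Series:
    """Per-gene exonic length from a GFF3 file (union of exon spans).

    Exons are grouped by their gene (via the Parent chain), overlapping or
    bookended exon intervals are merged, and the merged lengths are summed.
    GFF3 coordinates are 1-based closed, so a span [start, end] contributes
    end - start + 1 bp.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    lengths: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        intervals = sorted(
            (e.start, e.end)
            for e in db.children(gene, featuretype="exon")
        )
        total = 0
        cur_start: int | None = None
        cur_end = -1
        for start, end in intervals:
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end + 1:
                cur_end = max(cur_end, end)
            else:
                total += cur_end - cur_start + 1
                cur_start, cur_end = start, end
        if cur_start is not None:
            total += cur_end - cur_start + 1
        lengths[gene.id] = total
    if not lengths:
        raise InputError(f"no gene features with exons found in {path}")
    return pd.Series(lengths, name="length_bp")
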
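"""Dual-criterion ovary/testis-specificity classifier.

A gene is called specific to a target gonad (ovary or testis) when, on the
13-sample core set (3 target replicates vs the other 10 samples):

1. every target replicate has a strictly greater RPKM than every one of
   the other 10 samples, and
2. the target mean RPKM is at least ``fold_threshold`` (default 5) times
   the mean of the other 10 samples.

Both rules are deterministic; no significance test is involved.  Criterion
1 makes the ovary and testis calls mutually exclusive: an ovary-specific
gene forces every testis value below every ovary value, so the testis call
cannot also pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .types import (
    ConfigError,
    ExpressionMatrix,
    InputError,
    PAPER_LAYOUT,
    SpecificityCall,
)


def _evaluate(
    target: np.ndarray,
    other: np.ndarray,
    fold_threshold: float,
    other_stat: str,
) -> tuple[bool, bool, float]:
    c1 = target.min() > other.max()
    mt = float(target.mean())
    if other_stat == "mean":
        ref = float(other.mean())
    elif other_stat == "max":
        ref = float(other.max())
    else:
        raise ConfigError(f"unknown other_stat {other_stat!r}; use 'mean' or 'max'")
    if ref > 0:
        fold = mt / ref
        c2 = mt >= fold_threshold * ref
    elif mt > 0:
        fold, c2 = np.inf, True
    else:
        fold, c2 = 0.0, False
    return bool(c1), bool(c2), fold


def classify_gene(
    target_values: Sequence[float],
    other_values: Sequence[float],
    fold_threshold: float = 5.0,
    gene_id: str = "",
    target_class: str = "ovary",
    other_stat: str = "mean",
    enforce_layout: bool = True,
) -> SpecificityCall:
    """Apply both specificity criteria to one gene.

    ``target_values`` are the 3 target-gonad RPKMs and ``other_values`` the
    10 remaining samples' RPKMs under the study layout; pass
    ``enforce_layout=False`` to classify other layouts.  ``other_stat``
    selects the reference statistic of criterion 2 ("mean", the default
    reading, or "max" as a sensitivity option).
    """
    t = np.asarray(target_values, dtype=float)
    o = np.asarray(other_values, dtype=float)
    if enforce_layout and (t.size != 3 or o.size != 10):
        raise InputError(
            f"expected 3 target and 10 other values, got {t.size} and {o.size}"
        )
    if t.size == 0 or o.size == 0:
        raise InputError("target and other value sets must be nonempty")
    if np.isnan(t).any() or np.isnan(o).any():
        raise InputError("NaN RPKM value")
    c1, c2, fold = _evaluate(t, o, fold_threshold, other_stat)
    return SpecificityCall(
        gene_id=gene_id,
        target_class=target_class,
        criterion1_pass=c1,
        criterion2_pass=c2,
        fold=fold,
    )


@dataclass
class ClassificationResult:
    """Output of :func:`classify_all`: the two specific-gene lists plus the
    full per-gene, per-direction call records (input gene order, ovary call
    before testis call)."""

    ovary_specific: list[str]
    testis_specific: list[str]
    calls: list[SpecificityCall]

    def verdict_class(self, gene_id: str) -> str:
        """'ovary', 'testis', or 'none' for a classified gene."""
        if gene_id in self._ovary_set:
            return "ovary"
        if gene_id in self._testis_set:
            return "testis"
        return "none"

    def __post_init__(self) -> None:
        self._ovary_set = set(self.ovary_specific)
        self._testis_set = set(self.testis_specific)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in self.calls],
                "class": [c.target_class for c in self.calls],
                "criterion1": [c.criterion1_pass for c in self.calls],
                "criterion2": [c.criterion2_pass for c in self.calls],
                "fold": [c.fold for c in self.calls],
                "verdict": [c.verdict for c in self.calls],
            }
        )


def classify_all(
    expr: ExpressionMatrix,
    expressed_genes: Sequence[str],
    fold_threshold: float = 5.0,
    other_stat: str = "mean",
    allow_nonstandard_layout: bool = False,
) -> ClassificationResult:
    """Run the dual-criterion classifier on every expressed gene.

    Each gene is evaluated twice: ovary as target against testis + somatic,
    and testis as target against ovary + somatic.  Only core (gonadal +
    somatic) samples enter the comparison; the 3/3/7 study layout is
    required unless ``allow_nonstandard_layout`` is set.
    """
    layout = {g: len(expr.samples_in_group(g)) for g in ("ovary", "testis", "somatic")}
    if layout != PAPER_LAYOUT and not allow_nonstandard_layout:
        raise ConfigError(
            f"sample layout {layout} differs from the study layout {PAPER_LAYOUT}; "
            "pass allow_nonstandard_layout=True to classify anyway"
        )
    if layout["ovary"] == 0 or layout["testis"] == 0 or layout["somatic"] == 0:
        raise ConfigError("need at least one sample in each core group")

    expressed_genes = list(expressed_genes)
    missing = [g for g in expressed_genes if g not in expr.rpkm.index]
    if missing:
        raise InputError(f"expressed gene(s) not in matrix: {missing[:5]}")

    ov = expr.samples_in_group("ovary")
    te = expr.samples_in_group("testis")
    so = expr.samples_in_group("somatic")
    M = expr.rpkm.loc[expressed_genes]

    calls: list[SpecificityCall] = []
    verdicts: dict[str, np.ndarray] = {}
    for target_class, t_cols, o_cols in (
        ("ovary", ov, te + so),
        ("testis", te, ov + so),
    ):
        T = M[t_cols].to_numpy(dtype=float)
        O = M[o_cols].to_numpy(dtype=float)
        c1 = T.min(axis=1) > O.max(axis=1) if len(M) else np.zeros(0, bool)
        mt = T.mean(axis=1) if len(M) else np.zeros(0)
        mo = O.mean(axis=1) if len(M) else np.zeros(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            if other_stat == "mean":
                ref = mo
            elif other_stat == "max":
                ref = O.max(axis=1) if len(M) else np.zeros(0)
            else:
                raise ConfigError(f"unknown other_stat {other_stat!r}")
            fold = np.where(ref > 0, mt / ref, np.where(mt > 0, np.inf, 0.0))
            c2 = np.where(ref > 0, mt >= fold_threshold * ref, mt > 0)
        verdicts[target_class] = c1 & c2
        for i, g in enumerate(expressed_genes):
            calls.append(
                SpecificityCall(
                    gene_id=g,
                    target_class=target_class,
                    criterion1_pass=bool(c1[i]),
                    criterion2_pass=bool(c2[i]),
                    fold=float(fold[i]),
                )
            )

    # interleave per gene: ovary call then testis call, in input gene order
    n = len(expressed_genes)
    ordered = [calls[i + d * n] for i in range(n) for d in (0, 1)]
    return ClassificationResult(
        ovary_specific=[g for g, v in zip(expressed_genes, verdicts["ovary"]) if v],
        testis_specific=[g for g, v in zip(expressed_genes, verdicts["testis"]) if v],
        calls=ordered,
    )
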
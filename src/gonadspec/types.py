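"""Core containers shared across the pipeline.

The pipeline follows the design of the oyster gonad transcriptome study it
implements: a read-count matrix over 3 ovary + 3 testis + 7 somatic libraries
(the 13-sample "core" set), optional developmental-stage libraries, RPKM
expression values, deterministic tissue-specificity calls, and per-term
enrichment results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration."""


#: Valid sample groups. "stage" samples are developmental-stage libraries,
#: used for expression profiling but excluded from the 13-sample core set.
GROUPS = ("ovary", "testis", "somatic", "stage")
CORE_GROUPS = ("ovary", "testis", "somatic")

#: The study's sample layout: 3 ovary, 3 testis, 7 somatic libraries.
PAPER_LAYOUT = {"ovary": 3, "testis": 3, "somatic": 7}


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise InputError(f"duplicate {what} ID(s): {dup}")


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample library sizes.

    Parameters
    ----------
    counts
        DataFrame indexed by gene ID with one column per sample ID;
        non-negative integer cells.
    library_size
        Total mapped reads per sample (the N of the RPKM denominator).
        Defaults to the column sums of ``counts``; an explicit value
        overrides this, e.g. when the genome-wide mapped-read total is
        known and exceeds the sum of per-gene counts.
    """

    counts: pd.DataFrame
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.number) or (vals < 0).any()):
            raise InputError("counts must be non-negative numbers")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0).astype(float)
        else:
            self.library_size = pd.Series(self.library_size, dtype=float)
            missing = self.counts.columns.difference(self.library_size.index)
            if len(missing):
                raise InputError(f"library_size missing for sample(s): {missing.tolist()}")
            self.library_size = self.library_size.reindex(self.counts.columns)
            if len(self.counts.columns) and (self.library_size <= 0).any():
                bad = self.library_size[self.library_size <= 0].index.tolist()
                raise InputError(f"library_size must be positive, got non-positive for {bad}")
            if vals.size and (vals > self.library_size.to_numpy()[None, :]).any():
                raise InputError("count exceeds its sample's library size")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()


@dataclass
class ExpressionMatrix:
    """RPKM values, genes x samples, plus sample-group metadata.

    ``sample_groups`` is indexed by sample ID with columns ``group``
    (one of ovary / testis / somatic / stage) and ``label`` (organ or
    stage name; for gonads, the replicate label).
    """

    rpkm: pd.DataFrame
    sample_groups: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.rpkm.index, "gene")
        _check_unique(self.rpkm.columns, "sample")
        missing = self.rpkm.columns.difference(self.sample_groups.index)
        if len(missing):
            raise InputError(f"no group metadata for sample(s): {missing.tolist()}")
        bad = set(self.sample_groups["group"]) - set(GROUPS)
        if bad:
            raise InputError(f"unknown sample group(s): {sorted(bad)}; expected one of {GROUPS}")
        vals = self.rpkm.to_numpy()
        if vals.size and (~np.isfinite(vals) | (vals < 0)).any():
            raise InputError("RPKM values must be finite and non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.rpkm.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.rpkm.columns.tolist()

    def samples_in_group(self, group: str) -> list[str]:
        """Sample IDs assigned to ``group``, in matrix column order."""
        members = set(self.sample_groups.index[self.sample_groups["group"] == group])
        return [s for s in self.rpkm.columns if s in members]

    def core_samples(self) -> list[str]:
        """The gonadal + somatic samples (the study's 13-transcriptome set)."""
        return [s for g in CORE_GROUPS for s in self.samples_in_group(g)]

    def layout(self) -> dict[str, int]:
        return {g: len(self.samples_in_group(g)) for g in GROUPS}


@dataclass
class SpecificityCall:
    """Outcome of the dual-criterion tissue-specificity test for one gene.

    ``criterion1_pass``: every target-tissue replicate strictly exceeds every
    other sample.  ``criterion2_pass``: the target-tissue mean is at least
    ``fold_threshold`` times the mean of the other samples.  ``fold`` is that
    mean ratio (``inf`` when the other-sample mean is zero and the target
    mean positive; 0 when both are zero).
    """

    gene_id: str
    target_class: str  # "ovary" or "testis"
    criterion1_pass: bool
    criterion2_pass: bool
    fold: float
    verdict: bool = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = self.criterion1_pass and self.criterion2_pass


@dataclass
class EnrichmentResult:
    """One annotation term's over-representation test result.

    ``expected`` is the null expectation n*K/N for a set of ``set_n`` genes
    drawn from a universe of ``universe_N`` containing ``term_K`` annotated
    genes; ``observed_k`` is the number actually observed in the set.
    """

    term_id: str
    term_name: str
    observed_k: int
    expected: float
    p_raw: float
    p_adj: float
    universe_N: int
    term_K: int
    set_n: int


@dataclass
class ExpressionProfile:
    """Per-group mean and sample standard deviation of one gene's RPKM.

    ``stats`` is indexed by group label with columns ``n``, ``mean``, ``sd``;
    sd uses the n-1 denominator and is 0 for single-sample groups.
    """

    gene_id: str
    stats: pd.DataFrame


@dataclass
class CandidateRecord:
    """Presence / sex-specificity verdict for one candidate pathway gene."""

    pathway_gene: str
    homolog_ids: list[str]
    present: bool
    sex_specific: str  # "ovary", "testis" or "none"
    fold_testis_vs_ovary: float
    notes: str = ""

    @property
    def rendered(self) -> str:
        """Two-sign rendering: first sign presence, second sex-specificity."""
        first = "+" if self.present else "-"
        second = "+" if self.sex_specific != "none" else "-"
        return f"{first}/{second}"
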
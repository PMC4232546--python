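"""Readers for the pipeline's tab-separated input formats.

All formats are plain TSV with a header row.  Validation errors report the
offending 1-based file line where possible.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .types import CountMatrix, GROUPS, InputError


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty file, expected header {required}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}; header is {list(df.columns)}")
    return df


def _check_dup(df: pd.DataFrame, col: str, path) -> None:
    dup = df[col].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # +1 header, +1 one-based
        raise InputError(f"{path}: duplicate {col} {df[col][dup.idxmax()]!r} at line {line}")


def read_counts(path, library_size: pd.Series | None = None) -> CountMatrix:
    """Read a counts TSV: gene_id column plus one integer column per sample."""
    df = _read_tsv(path, ["gene_id"])
    _check_dup(df, "gene_id", path)
    df = df.set_index("gene_id")
    try:
        counts = df.astype("int64")
    except ValueError as e:
        raise InputError(f"{path}: non-integer count value ({e})") from None
    return CountMatrix(counts=counts, library_size=library_size)


def read_models(path) -> pd.DataFrame:
    """Read a gene-model TSV: gene_id, length_bp, go_terms, kegg_pathways.

    Term columns are semicolon-separated lists (may be empty).  Returns a
    frame indexed by gene_id with length_bp (int) and list-valued term
    columns.
    """
    df = _read_tsv(path, ["gene_id", "length_bp"])
    _check_dup(df, "gene_id", path)
    df = df.set_index("gene_id")
    try:
        df["length_bp"] = df["length_bp"].astype("int64")
    except ValueError as e:
        raise InputError(f"{path}: non-integer length_bp ({e})") from None
    if (df["length_bp"] <= 0).any():
        bad = df.index[df["length_bp"] <= 0][0]
        line = int(df.index.get_loc(bad)) + 2
        raise InputError(f"{path}: non-positive length_bp for {bad!r} at line {line}")
    for col in ("go_terms", "kegg_pathways"):
        if col in df.columns:
            df[col] = df[col].fillna("").map(lambda s: [t for t in s.split(";") if t])
        else:
            df[col] = [[] for _ in range(len(df))]
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata: sample_id, group (ovary/testis/somatic/stage), label."""
    df = _read_tsv(path, ["sample_id", "group", "label"])
    _check_dup(df, "sample_id", path)
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise InputError(
            f"{path}: unknown group {df['group'][bad.idxmax()]!r} at line {line}; "
            f"expected one of {GROUPS}"
        )
    return df.set_index("sample_id")


def read_term_map(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a gene->term TSV (gene_id, term_id, optional term_name).

    Returns the gene->terms mapping and a term->name mapping (empty names
    when the column is absent).
    """
    df = _read_tsv(path, ["gene_id", "term_id"])
    term_map: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for _, row in df.iterrows():
        term_map.setdefault(row["gene_id"], set()).add(row["term_id"])
        if "term_name" in df.columns and isinstance(row.get("term_name"), str):
            names[row["term_id"]] = row["term_name"]
    return term_map, names


def read_truth(path) -> pd.Series:
    """Read planted-truth labels: gene_id, label."""
    df = _read_tsv(path, ["gene_id", "label"])
    _check_dup(df, "gene_id", path)
    return df.set_index("gene_id")["label"]


def read_homolog_table(path) -> pd.DataFrame:
    """Read the candidate table: pathway_gene, optional species_context,
    homolog_ids (semicolon-separated, may be empty)."""
    df = _read_tsv(path, ["pathway_gene", "homolog_ids"])
    _check_dup(df, "pathway_gene", path)
    df["homolog_ids"] = df["homolog_ids"].fillna("")
    return df
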
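"""Term over-representation testing (one-sided Fisher's exact) with BH FDR.

Each annotation term is tested independently ("classic" style: no use of
the GO hierarchy) against the hypergeometric upper tail: for a set of n
genes drawn from a universe of N genes of which K carry the term, the
probability of observing k or more annotated genes in the set.  The
universe is restricted to genes carrying at least one annotation in the
tested namespace, matching the usual convention of GO-enrichment tools.
Raw p-values are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from collections.abc import Collection, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import EnrichmentResult, InputError


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The enrichment p-value: the chance that a random n-gene set from an
    N-gene universe containing K term-annotated genes includes at least k
    of them.  k = 0 gives exactly 1.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if v < 0:
            raise InputError(f"{name} must be non-negative, got {v}")
    if K > N or n > N:
        raise InputError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(n, K):
        raise InputError(f"k={k} exceeds min(n={n}, K={K})")
    if N == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ) over the sorted p-values,
    clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    specific_set: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Collection[str]],
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in a gene set.

    Parameters
    ----------
    specific_set
        The gene set of interest (e.g. ovary-specific genes); must be a
        subset of ``universe``.
    universe
        The background gene set, typically all expressed genes.  Genes
        without any annotation in ``term_map`` are dropped from the
        universe, the set, and the term totals.
    term_map
        gene ID -> collection of term IDs.
    term_names
        Optional term ID -> human-readable name.

    Returns results for every term annotating at least one universe gene,
    sorted by raw p ascending with ties broken by term ID.
    """
    universe = list(dict.fromkeys(universe))
    specific = list(dict.fromkeys(specific_set))
    uni_set = set(universe)
    outside = [g for g in specific if g not in uni_set]
    if outside:
        raise InputError(f"specific gene(s) not in universe: {outside[:5]}")

    annotated = [g for g in universe if term_map.get(g)]
    ann_set = set(annotated)
    set_genes = [g for g in specific if g in ann_set]
    N, n = len(annotated), len(set_genes)

    term_K: dict[str, int] = {}
    for g in annotated:
        for t in term_map[g]:
            term_K[t] = term_K.get(t, 0) + 1
    term_k: dict[str, int] = {t: 0 for t in term_K}
    for g in set_genes:
        for t in term_map[g]:
            term_k[t] += 1

    terms = sorted(term_K)
    if not terms:
        return []
    p_raw = np.array(
        [hypergeom_upper_tail(term_k[t], n, term_K[t], N) for t in terms]
    )
    p_adj = bh_adjust(p_raw)
    names = term_names or {}
    results = [
        EnrichmentResult(
            term_id=t,
            term_name=names.get(t, ""),
            observed_k=term_k[t],
            expected=n * term_K[t] / N,
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
            universe_N=N,
            term_K=term_K[t],
            set_n=n,
        )
        for i, t in enumerate(terms)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular form with the expected count at 2 decimals."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "genes": [r.observed_k for r in results],
            "expected": [round(r.expected, 2) for r in results],
            "p_value": [r.p_raw for r in results],
            "p_adjusted": [r.p_adj for r in results],
        }
    )
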
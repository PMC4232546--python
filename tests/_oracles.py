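"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity by direct transcription of its
definition (pairwise comparisons, exact integer combinatorics), sharing no
code with the package.
"""

from math import comb


def oracle_specific(target: list[float], other: list[float], fold_threshold: float = 5.0) -> bool:
    """Literal evaluation of the two specificity rules: every target
    replicate strictly exceeds every other sample, and the target mean is
    at least fold_threshold times the other-sample mean."""
    rule1 = all(t > o for t in target for o in other)
    mean_t = sum(target) / len(target)
    mean_o = sum(other) / len(other)
    if mean_o == 0:
        rule2 = mean_t > 0
    else:
        rule2 = mean_t >= fold_threshold * mean_o
    return rule1 and rule2


def oracle_hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact enumeration of every 2x2 table with the given
    margins, using integer binomial coefficients."""
    if N == 0:
        return 1.0
    denom = comb(N, n)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / denom


def oracle_bh(p: list[float]) -> list[float]:
    """Step-up BH by the textbook definition: sort, take cumulative minima
    of m*p_(j)/j from the largest rank down, clip at 1, restore order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted
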
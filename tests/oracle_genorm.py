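"""Brute-force geNorm oracle, deliberately naive and independent.

Implements the stepwise exclusion algorithm with plain Python loops and
``statistics.stdev`` so that the vectorized implementation in
``refstab.stability_suite`` can be checked against an unrelated code
path: relative quantities per gene, sample SD of pairwise log2 ratios,
mean pairwise SD as M, exclusion of the highest-M gene (ties resolved
by removing the lexicographically last gene), down to a final pair.
"""

import math
import statistics


def brute_quantities(cq_rows: dict[str, list[float]], eff: dict[str, float]):
    q = {}
    for gene, row in cq_rows.items():
        e = eff.get(gene, 2.0)
        m = min(row)
        q[gene] = [e ** (m - c) for c in row]
    return q


def brute_pair_sd(q: dict[str, list[float]], a: str, b: str) -> float:
    ratios = [math.log2(x / y) for x, y in zip(q[a], q[b])]
    return statistics.stdev(ratios)


def brute_genorm(cq_rows: dict[str, list[float]], eff: dict[str, float] | None = None):
    """Return (removal order, M at removal, final pair, final M)."""
    eff = eff or {}
    q = brute_quantities(cq_rows, eff)
    remaining = sorted(cq_rows)
    removal, m_at_removal = [], []
    while len(remaining) > 2:
        m = {
            g: sum(brute_pair_sd(q, g, h) for h in remaining if h != g) / (len(remaining) - 1)
            for g in remaining
        }
        worst = max(remaining, key=lambda g: (m[g], g))
        removal.append(worst)
        m_at_removal.append(m[worst])
        remaining.remove(worst)
    final_m = brute_pair_sd(q, remaining[0], remaining[1])
    return removal, m_at_removal, tuple(remaining), final_m
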
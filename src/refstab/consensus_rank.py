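"""Comprehensive ranking of candidate genes across stability methods.

Each stability method contributes a per-gene rank (1 = most stable).
The consensus statistic is the geometric mean of a gene's ranks across
methods; a lower geometric mean means more stable overall.  Tied scores
within one method share a rank: under the default ``min-rank`` rule
every member of a tied block gets the block's first position (so a tied
best pair is ranked 1, 1 and the next gene 3); ``mid-rank`` assigns the
block's mid position (1.5, 1.5, 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from refstab.quant_io import ValidationError

METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")
TIE_RULES = ("min-rank", "mid-rank")


@dataclass(frozen=True)
class MethodRanking:
    """Per-gene ranks from one stability method (1 = most stable)."""

    method: str
    ranks: dict[str, float]
    tied_groups: tuple[frozenset[str], ...] = ()

    def order(self) -> tuple[str, ...]:
        return tuple(sorted(self.ranks, key=lambda g: (self.ranks[g], g)))


@dataclass(frozen=True)
class ConsensusResult:
    """Geometric-mean consensus across methods."""

    geomean_rank: dict[str, float]
    final_order: tuple[str, ...]
    per_method: tuple[MethodRanking, ...]
    tied_final: tuple[frozenset[str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos, gene in enumerate(self.final_order, start=1):
            row = {"gene": gene, "comprehensive_rank": pos,
                   "geomean_rank": self.geomean_rank[gene]}
            for mr in self.per_method:
                row[f"rank_{mr.method}"] = mr.ranks[gene]
            rows.append(row)
        return pd.DataFrame(rows)


def _ranks_from_keys(
    keys: Mapping[str, tuple], tie_rule: str
) -> tuple[dict[str, float], tuple[frozenset[str], ...]]:
    if tie_rule not in TIE_RULES:
        raise ValidationError(f"unknown tie rule {tie_rule!r}")
    ordered = sorted(keys, key=lambda g: (keys[g], g))
    ranks: dict[str, float] = {}
    tied: list[frozenset[str]] = []
    pos = 0
    while pos < len(ordered):
        block = [ordered[pos]]
        while pos + len(block) < len(ordered) and keys[ordered[pos + len(block)]] == keys[block[0]]:
            block.append(ordered[pos + len(block)])
        if tie_rule == "min-rank":
            rank = pos + 1
        else:
            rank = pos + (len(block) + 1) / 2
        for g in block:
            ranks[g] = float(rank)
        if len(block) > 1:
            tied.append(frozenset(block))
        pos += len(block)
    return ranks, tuple(tied)


def ranks_from_scores(
    scores: Mapping[str, float],
    ascending: bool = True,
    tie_rule: str = "min-rank",
    method: str = "scores",
) -> MethodRanking:
    """Dense positional ranks from per-gene scores.

    ``ascending=True`` means a lower score is better (rank 1).  Genes
    with exactly equal scores form a tied block handled per
    ``tie_rule``.
    """
    for g, s in scores.items():
        if not math.isfinite(s):
            raise ValidationError(f"non-finite score for gene {g!r}")
    keys = {g: ((s,) if ascending else (-s,)) for g, s in scores.items()}
    ranks, tied = _ranks_from_keys(keys, tie_rule)
    return MethodRanking(method=method, ranks=ranks, tied_groups=tied)


def ranking_from_order(
    method: str,
    order: Sequence[str | Sequence[str]],
    tie_rule: str = "min-rank",
) -> MethodRanking:
    """Encode a printed rank order, e.g. from a published table.

    ``order`` lists genes from most to least stable; an inner sequence
    (or a "A/B" string) marks genes sharing one rank, as geNorm reports
    its best pair.
    """
    keys: dict[str, tuple] = {}
    for pos, entry in enumerate(order):
        if isinstance(entry, str):
            block = entry.split("/") if "/" in entry else [entry]
        else:
            block = list(entry)
        for g in block:
            if g in keys:
                raise ValidationError(f"gene {g!r} listed twice in {method} order")
            keys[g] = (pos,)
    ranks, tied = _ranks_from_keys(keys, tie_rule)
    return MethodRanking(method=method, ranks=ranks, tied_groups=tied)


def comprehensive_rank(rankings: Iterable[MethodRanking]) -> ConsensusResult:
    """Geometric-mean consensus of two or more method rankings.

    All rankings must cover an identical gene set.  Final order is
    ascending by geometric-mean rank, ties broken by gene identifier
    (and flagged in ``tied_final``).
    """
    rankings = tuple(rankings)
    if len(rankings) < 2:
        raise ValidationError("consensus needs at least 2 method rankings")
    gene_set = set(rankings[0].ranks)
    for mr in rankings[1:]:
        if set(mr.ranks) != gene_set:
            raise ValidationError(
                f"gene-set mismatch between methods {rankings[0].method!r} and {mr.method!r}"
            )
    m = len(rankings)
    geomean = {}
    for g in gene_set:
        ranks = [mr.ranks[g] for mr in rankings]
        value = math.exp(sum(math.log(r) for r in ranks) / m)
        # guard the min <= geomean <= max invariant against rounding
        geomean[g] = min(max(value, min(ranks)), max(ranks))
    keys = {g: (geomean[g],) for g in gene_set}
    _, tied = _ranks_from_keys(keys, "min-rank")
    final_order = tuple(sorted(gene_set, key=lambda g: (geomean[g], g)))
    return ConsensusResult(
        geomean_rank=geomean,
        final_order=final_order,
        per_method=rankings,
        tied_final=tied,
    )


def rankings_from_stability(
    results: Mapping[str, object], tie_rule: str = "min-rank"
) -> list[MethodRanking]:
    """Build MethodRankings from the stability suite's result objects.

    geNorm, NormFinder and delta-Ct rank by their scalar scores
    (M at exclusion, SV, mean pair-SD).  BestKeeper ranks by its
    composite key (SD, CV, -r).
    """
    rankings: list[MethodRanking] = []
    for method, result in results.items():
        if hasattr(result, "sort_keys"):
            ranks, tied = _ranks_from_keys(result.sort_keys(), tie_rule)
            rankings.append(MethodRanking(method=method, ranks=ranks, tied_groups=tied))
        elif hasattr(result, "scores"):
            rankings.append(
                ranks_from_scores(result.scores(), ascending=True,
                                  tie_rule=tie_rule, method=method)
            )
        else:
            raise ValidationError(f"cannot rank result of type {type(result).__name__}")
    return rankings


def read_rank_file(path, delimiter: str | None = None) -> list[MethodRanking]:
    """Read hand-entered rankings from a delimited file (method, gene, rank)."""
    from refstab.quant_io import _read_delimited

    raw = _read_delimited(path, delimiter)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = {"method", "gene", "rank"} - set(raw.columns)
    if missing:
        raise ValidationError(f"rank file lacks columns {sorted(missing)}")
    out = []
    for method, sub in raw.groupby("method", sort=False):
        ranks = {str(g): float(r) for g, r in zip(sub["gene"], sub["rank"])}
        blocks: dict[float, list[str]] = {}
        for g, r in ranks.items():
            blocks.setdefault(r, []).append(g)
        tied = tuple(frozenset(b) for b in blocks.values() if len(b) > 1)
        out.append(MethodRanking(method=str(method), ranks=ranks, tied_groups=tied))
    return out
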
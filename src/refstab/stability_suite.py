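"""Expression-stability statistics for candidate reference genes.

Four independent methods are implemented, each producing per-gene scores
where *lower means more stable*:

geNorm
    For every gene pair (j, k), the standard deviation over samples of
    log2(Q_j / Q_k).  A gene's M-value is the mean of these pairwise SDs
    against all other genes.  Genes are excluded stepwise (highest M
    first); the pairwise variation V(n/n+1) between normalization
    factors built from the n and n+1 most stable genes decides how many
    reference genes are needed (conventional cutoff 0.15).
NormFinder
    A model-based variance decomposition on log2 quantities: per-gene,
    per-group intra-group variances are estimated from double-centered
    within-group residuals, inter-group deviations are shrunk toward
    zero, and both combine into a stability value SV.
BestKeeper
    Descriptive statistics on raw Cq: per-gene "SD" (mean absolute
    deviation from the arithmetic mean, in cycles), CV (percent), and
    the Pearson correlation of each gene against the BestKeeper index
    (per-sample geometric mean of Cq across genes).  Genes with SD > 1
    cycle are deemed unacceptable.
Comparative delta-Ct
    The SD over samples of the Cq difference for every gene pair; a
    gene's score is the mean SD against all partners.

All methods need at least 3 samples; geNorm and NormFinder need at
least 3 genes.  When every amplification efficiency is exactly 2, the
delta-Ct mean pair-SD coincides with the initial (pre-exclusion) geNorm
M-value gene for gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from refstab.quant_io import (
    AnalysisConfig,
    CqTable,
    EfficiencyTable,
    SampleSheet,
    ValidationError,
)

MIN_SAMPLES = 3


@dataclass(frozen=True)
class RelativeQuantityTable:
    """Relative quantities Q(g, s) = E_g ** (min_s' Cq(g, s') - Cq(g, s)).

    Q is dimensionless, in (0, 1], and equals 1 for each gene's most
    abundant (lowest-Cq) sample.
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    quantities: np.ndarray
    efficiencies: tuple[float, ...]

    def __post_init__(self) -> None:
        q = np.asarray(self.quantities, dtype=float)
        if q.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("quantity matrix shape does not match identifiers")
        if (q <= 0).any() or (q > 1 + 1e-12).any():
            raise ValidationError("relative quantities must lie in (0, 1]")
        if not np.allclose(q.max(axis=1), 1.0):
            raise ValidationError("each gene's maximum relative quantity must be 1")
        q = q.copy()
        q.setflags(write=False)
        object.__setattr__(self, "quantities", q)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def log2_quantities(self) -> np.ndarray:
        return np.log2(self.quantities)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.quantities[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def subset_genes(self, genes: Sequence[str]) -> "RelativeQuantityTable":
        idx = [self.genes.index(g) for g in genes]
        q = self.quantities[idx]
        # renormalize so the invariant (max per gene = 1) holds on the subset
        return RelativeQuantityTable(
            tuple(genes), self.samples, q / q.max(axis=1, keepdims=True),
            tuple(self.efficiencies[i] for i in idx),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.quantities, index=list(self.genes), columns=list(self.samples))


def to_relative_quantity(cq: CqTable, eff: EfficiencyTable | None = None) -> RelativeQuantityTable:
    """Transform Cq to relative quantities Q = E ** (min Cq - Cq).

    The per-gene minimum Cq (most abundant sample) maps to Q = 1; each
    extra cycle divides Q by the gene's amplification efficiency.
    """
    eff = eff or EfficiencyTable()
    e = np.array([eff.of(g) for g in cq.genes], dtype=float)
    delta = cq.values.min(axis=1, keepdims=True) - cq.values
    q = e[:, None] ** delta
    return RelativeQuantityTable(cq.genes, cq.samples, q, tuple(e))


# ---------------------------------------------------------------------------
# geNorm


@dataclass(frozen=True)
class GeNormResult:
    """Stepwise geNorm output.

    ``m_values`` holds each gene's M at the step of its exclusion (the
    two final genes share the last M); ``exclusion_order`` lists genes
    from least to most stable, i.e. in removal order.  ``m_trajectory``
    keeps the full per-step M map.  ``pairwise_variation`` maps n to
    V(n/n+1); ``recommended_n`` is the smallest n below the cutoff, or
    None when no n qualifies.
    """

    genes: tuple[str, ...]
    m_values: dict[str, float]
    exclusion_order: tuple[str, ...]
    final_pair: tuple[str, str]
    pairwise_sd: np.ndarray
    pairwise_variation: dict[int, float]
    recommended_n: int | None
    m_trajectory: tuple[dict[str, float], ...]

    @property
    def stability_order(self) -> tuple[str, ...]:
        """Genes from most to least stable (final pair first, tied)."""
        return tuple(sorted(self.final_pair)) + tuple(reversed(self.exclusion_order))

    def scores(self) -> dict[str, float]:
        """Per-gene M at exclusion; lower = more stable."""
        return dict(self.m_values)

    def to_frame(self) -> pd.DataFrame:
        order = self.stability_order
        return pd.DataFrame(
            {"gene": order, "m_value": [self.m_values[g] for g in order]}
        )


def genorm_pairwise_sd(q: RelativeQuantityTable) -> np.ndarray:
    """Symmetric matrix of SD over samples of log2(Q_j / Q_k)."""
    if q.n_genes < 2:
        raise ValidationError("geNorm pairwise SDs need at least 2 genes")
    if q.n_samples < MIN_SAMPLES:
        raise ValidationError(f"geNorm needs at least {MIN_SAMPLES} samples")
    logq = q.log2_quantities()
    diff = logq[:, None, :] - logq[None, :, :]
    v = diff.std(axis=2, ddof=1)
    np.fill_diagonal(v, 0.0)
    return v


def _m_values(v: np.ndarray, active: list[int]) -> np.ndarray:
    sub = v[np.ix_(active, active)]
    return sub.sum(axis=1) / (len(active) - 1)


def genorm_rank(
    q: RelativeQuantityTable,
    v_cutoff: float = 0.15,
) -> GeNormResult:
    """Stepwise geNorm ranking with pairwise-variation analysis.

    At each step the gene with the highest M (mean pairwise SD against
    the remaining genes) is excluded; on ties the lexicographically last
    gene goes first.  V(n/n+1) is the SD over samples of
    log2(NF_n / NF_{n+1}) where NF_n is the geometric mean of the n most
    stable genes' quantities.
    """
    if q.n_genes < 3:
        raise ValidationError("geNorm ranking needs at least 3 genes")
    v = genorm_pairwise_sd(q)
    genes = q.genes
    active = list(range(q.n_genes))
    exclusion: list[int] = []
    m_at_exclusion: dict[str, float] = {}
    trajectory: list[dict[str, float]] = []
    while len(active) > 2:
        m = _m_values(v, active)
        trajectory.append({genes[i]: float(mi) for i, mi in zip(active, m)})
        m_max = m.max()
        ties = [active[i] for i in range(len(active)) if m[i] >= m_max - 1e-15]
        worst = max(ties, key=lambda i: genes[i])
        m_at_exclusion[genes[worst]] = float(m[active.index(worst)])
        exclusion.append(worst)
        active.remove(worst)
    final_m = float(v[active[0], active[1]])
    trajectory.append({genes[i]: final_m for i in active})
    for i in active:
        m_at_exclusion[genes[i]] = final_m
    final_pair = (genes[active[0]], genes[active[1]])

    # pairwise variation: add genes from most to least stable
    stability_order = [*sorted(final_pair), *(genes[i] for i in reversed(exclusion))]
    logq = q.log2_quantities()
    index = {g: i for i, g in enumerate(genes)}
    pairwise_variation: dict[int, float] = {}
    for n in range(2, q.n_genes):
        top_n = [index[g] for g in stability_order[:n]]
        top_n1 = [index[g] for g in stability_order[: n + 1]]
        log_nf_n = logq[top_n].mean(axis=0)
        log_nf_n1 = logq[top_n1].mean(axis=0)
        pairwise_variation[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    recommended = next(
        (n for n, val in sorted(pairwise_variation.items()) if val < v_cutoff), None
    )
    return GeNormResult(
        genes=genes,
        m_values=m_at_exclusion,
        exclusion_order=tuple(genes[i] for i in exclusion),
        final_pair=final_pair,
        pairwise_sd=v,
        pairwise_variation=pairwise_variation,
        recommended_n=recommended,
        m_trajectory=tuple(trajectory),
    )


# ---------------------------------------------------------------------------
# NormFinder


@dataclass(frozen=True)
class NormFinderResult:
    """Model-based stability values (lower SV = more stable).

    ``intra_var`` maps gene -> group -> estimated intra-group variance
    (log2 scale, floored at zero); ``inter_dev`` maps gene -> group ->
    shrunk inter-group deviation.  In single-group mode ``inter_dev`` is
    empty and SV reduces to the per-gene variation estimate.
    """

    genes: tuple[str, ...]
    stability: dict[str, float]
    intra_var: dict[str, dict[str, float]]
    inter_dev: dict[str, dict[str, float]]
    grouped: bool

    def scores(self) -> dict[str, float]:
        return dict(self.stability)

    def to_frame(self) -> pd.DataFrame:
        order = sorted(self.stability, key=lambda g: (self.stability[g], g))
        return pd.DataFrame(
            {"gene": order, "stability": [self.stability[g] for g in order]}
        )


def _group_variances(y: np.ndarray) -> np.ndarray:
    """Per-gene intra-group variance from double-centered residuals.

    ``y`` is the (genes x samples) log2 matrix of one group.  Residuals
    remove gene means and per-sample (loading) means; the moment
    estimator corrects for the variance absorbed by the sample means,
    which mixes all genes' variances.  Estimates are floored at zero.
    """
    k, n = y.shape
    if k < 3:
        raise ValidationError("NormFinder variance estimation needs at least 3 genes")
    if n < 2:
        raise ValidationError("each analysed group needs at least 2 samples")
    r = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    u = (r**2).sum(axis=1) / (n - 1)
    total = u.sum()
    sigma2 = (u - total / (k * (k - 1))) * k / (k - 2)
    return np.maximum(sigma2, 0.0)


def normfinder_stability(
    q: RelativeQuantityTable,
    sheet: SampleSheet,
    grouped: bool | None = None,
) -> NormFinderResult:
    """NormFinder stability values on log2 relative quantities.

    Grouped mode (default whenever the sheet defines more than one
    group) decomposes each gene's variation into intra-group variance
    and inter-group deviations; the deviations are shrunk toward zero by
    an empirical-Bayes factor so that apparent group differences
    explainable by sampling noise do not count against a gene.  The
    stability value of gene i is the average over groups of
    ``|shrunk deviation| + sqrt(intra-group variance / group size)``.
    """
    if set(sheet.sample_ids) != set(q.samples):
        raise ValidationError("sample sheet does not match the quantity table's samples")
    if q.n_samples < MIN_SAMPLES:
        raise ValidationError(f"NormFinder needs at least {MIN_SAMPLES} samples")
    groups = sheet.group_names
    if grouped is None:
        grouped = len(groups) > 1
    y = q.log2_quantities()
    col = {s: j for j, s in enumerate(q.samples)}
    genes = q.genes

    if not grouped:
        sigma2 = _group_variances(y)
        sv = np.sqrt(sigma2)
        return NormFinderResult(
            genes=genes,
            stability={g: float(s) for g, s in zip(genes, sv)},
            intra_var={g: {"all": float(s2)} for g, s2 in zip(genes, sigma2)},
            inter_dev={},
            grouped=False,
        )

    group_cols = {g: [col[s] for s in sheet.samples_in_group(g)] for g in groups}
    singletons = [g for g, cols in group_cols.items() if len(cols) < 2]
    if singletons:
        raise ValidationError(
            f"group(s) {singletons} have a single sample; grouped NormFinder needs "
            ">= 2 samples per group — use single-group mode (grouped=False) instead"
        )
    n_g = np.array([len(group_cols[g]) for g in groups], dtype=float)
    sigma2 = np.column_stack([_group_variances(y[:, group_cols[g]]) for g in groups])
    means = np.column_stack([y[:, group_cols[g]].mean(axis=1) for g in groups])
    d = means - means.mean(axis=1, keepdims=True) - means.mean(axis=0, keepdims=True) + means.mean()

    v = sigma2 / n_g[None, :]  # sampling variance of each group mean
    k, n_groups = d.shape
    gamma2 = (d**2).sum() / ((k - 1) * (n_groups - 1)) - v.mean()
    gamma2 = max(gamma2, 0.0)
    shrink = gamma2 / (gamma2 + v) if gamma2 > 0 else np.zeros_like(v)
    d_shrunk = d * shrink

    rho = np.abs(d_shrunk) + np.sqrt(v)
    sv = rho.mean(axis=1)
    return NormFinderResult(
        genes=genes,
        stability={g: float(s) for g, s in zip(genes, sv)},
        intra_var={
            gene: {grp: float(sigma2[i, j]) for j, grp in enumerate(groups)}
            for i, gene in enumerate(genes)
        },
        inter_dev={
            gene: {grp: float(d_shrunk[i, j]) for j, grp in enumerate(groups)}
            for i, gene in enumerate(genes)
        },
        grouped=True,
    )


# ---------------------------------------------------------------------------
# BestKeeper


@dataclass(frozen=True)
class BestKeeperResult:
    """BestKeeper descriptives on raw Cq values.

    ``sd`` is the mean absolute deviation from the arithmetic mean (the
    BestKeeper convention, in cycles), ``cv`` is 100 * sd / mean
    (percent), ``index`` the per-sample geometric mean of Cq across
    genes, ``r`` each gene's Pearson correlation against the index
    (NaN for a constant gene).  Ranking is by (sd, cv, -r) ascending.
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    arithmetic_mean: dict[str, float]
    geometric_mean: dict[str, float]
    min_cq: dict[str, float]
    max_cq: dict[str, float]
    sd: dict[str, float]
    cv: dict[str, float]
    r: dict[str, float]
    p_value: dict[str, float]
    acceptable: dict[str, bool]
    index: dict[str, float]

    def sort_keys(self) -> dict[str, tuple[float, ...]]:
        """Per-gene ranking key (sd, cv, -r); lower = more stable."""
        return {
            g: (
                self.sd[g],
                self.cv[g],
                -(self.r[g] if math.isfinite(self.r[g]) else 0.0),
            )
            for g in self.genes
        }

    @property
    def rank_order(self) -> tuple[str, ...]:
        keys = self.sort_keys()
        return tuple(sorted(self.genes, key=lambda g: (*keys[g], g)))

    def to_frame(self) -> pd.DataFrame:
        order = self.rank_order
        return pd.DataFrame(
            {
                "gene": order,
                "arithmetic_mean": [self.arithmetic_mean[g] for g in order],
                "geometric_mean": [self.geometric_mean[g] for g in order],
                "min": [self.min_cq[g] for g in order],
                "max": [self.max_cq[g] for g in order],
                "sd": [self.sd[g] for g in order],
                "cv_percent": [self.cv[g] for g in order],
                "r": [self.r[g] for g in order],
                "p_value": [self.p_value[g] for g in order],
                "acceptable": [self.acceptable[g] for g in order],
            }
        )


def bestkeeper_analyze(cq: CqTable, config: AnalysisConfig | None = None) -> BestKeeperResult:
    """BestKeeper descriptive analysis of a raw Cq table."""
    config = config or AnalysisConfig()
    if cq.n_genes < 1:
        raise ValidationError("BestKeeper needs at least one gene")
    if cq.n_samples < MIN_SAMPLES:
        raise ValidationError(f"BestKeeper needs at least {MIN_SAMPLES} samples")
    x = cq.values
    am = x.mean(axis=1)
    gm = np.exp(np.log(x).mean(axis=1))
    sd = np.abs(x - am[:, None]).mean(axis=1)
    cv = 100.0 * sd / am
    index = np.exp(np.log(x).mean(axis=0))
    r = np.full(cq.n_genes, np.nan)
    p = np.full(cq.n_genes, np.nan)
    for i in range(cq.n_genes):
        xi = x[i]
        if np.ptp(xi) == 0 or np.ptp(index) == 0:
            continue  # correlation undefined for a constant series
        r[i], p[i] = stats.pearsonr(xi, index)
    return BestKeeperResult(
        genes=cq.genes,
        samples=cq.samples,
        arithmetic_mean={g: float(v) for g, v in zip(cq.genes, am)},
        geometric_mean={g: float(v) for g, v in zip(cq.genes, gm)},
        min_cq={g: float(v) for g, v in zip(cq.genes, x.min(axis=1))},
        max_cq={g: float(v) for g, v in zip(cq.genes, x.max(axis=1))},
        sd={g: float(v) for g, v in zip(cq.genes, sd)},
        cv={g: float(v) for g, v in zip(cq.genes, cv)},
        r={g: float(v) for g, v in zip(cq.genes, r)},
        p_value={g: float(v) for g, v in zip(cq.genes, p)},
        acceptable={g: bool(v <= config.bestkeeper_sd_cutoff) for g, v in zip(cq.genes, sd)},
        index={s: float(v) for s, v in zip(cq.samples, index)},
    )


# ---------------------------------------------------------------------------
# comparative delta-Ct


@dataclass(frozen=True)
class DeltaCtResult:
    """Pairwise Cq-difference SDs and their per-gene means."""

    genes: tuple[str, ...]
    pair_sd: np.ndarray
    mean_sd: dict[str, float]

    def scores(self) -> dict[str, float]:
        return dict(self.mean_sd)

    def to_frame(self) -> pd.DataFrame:
        order = sorted(self.mean_sd, key=lambda g: (self.mean_sd[g], g))
        return pd.DataFrame(
            {"gene": order, "mean_pair_sd": [self.mean_sd[g] for g in order]}
        )


def deltact_rank(cq: CqTable) -> DeltaCtResult:
    """Comparative delta-Ct stability: mean SD of pairwise Cq differences."""
    if cq.n_genes < 2:
        raise ValidationError("delta-Ct comparison needs at least 2 genes")
    if cq.n_samples < MIN_SAMPLES:
        raise ValidationError(f"delta-Ct comparison needs at least {MIN_SAMPLES} samples")
    diff = cq.values[:, None, :] - cq.values[None, :, :]
    pair_sd = diff.std(axis=2, ddof=1)
    np.fill_diagonal(pair_sd, 0.0)
    mean_sd = pair_sd.sum(axis=1) / (cq.n_genes - 1)
    return DeltaCtResult(
        genes=cq.genes,
        pair_sd=pair_sd,
        mean_sd={g: float(v) for g, v in zip(cq.genes, mean_sd)},
    )


# ---------------------------------------------------------------------------
# convenience driver


def run_all_methods(
    cq: CqTable,
    sheet: SampleSheet,
    eff: EfficiencyTable | None = None,
    config: AnalysisConfig | None = None,
) -> dict[str, object]:
    """Run all four stability methods on one experiment.

    Returns ``{"genorm": GeNormResult, "normfinder": NormFinderResult,
    "bestkeeper": BestKeeperResult, "deltact": DeltaCtResult}``.
    """
    config = config or AnalysisConfig()
    q = to_relative_quantity(cq, eff)
    return {
        "genorm": genorm_rank(q, v_cutoff=config.pairwise_variation_cutoff),
        "normfinder": normfinder_stability(q, sheet),
        "bestkeeper": bestkeeper_analyze(cq, config),
        "deltact": deltact_rank(cq),
    }
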
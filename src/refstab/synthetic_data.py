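"""Synthetic Cq experiments and expression tables with known ground truth.

The Cq generator emulates a multi-group qPCR study of candidate
reference genes:

    Cq(g, s) = baseline(g) + group_shift(g, group(s))
               + sample_effect(s) + noise(g, s)

Designed-stable genes have zero group shift in every group; designed-
unstable genes carry systematic, group-dependent shifts.  Sample
effects model loading/input differences shared by all genes of a
sample (which multi-gene normalization factors cancel exactly), and
the technical noise is additive Gaussian on the cycle scale, i.e.
log-normal multiplicative on quantities.  Defaults mirror a typical
abiotic-stress design: 9 genes, 5 treatment groups x 3 biological
replicates, 0.2-cycle technical noise, shifts up to 2 cycles.

The expression-table generator produces designed low-dispersion genes
(condition-level CV <= 0.2) and high-dispersion genes (CV >= 0.5) for
exercising the candidate screen, and ``recovery_experiment`` runs the
full stability + consensus pipeline over many simulated replicates to
measure how often the designed-stable genes are recovered on top.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from refstab.quant_io import (
    CQ_HIGH,
    CQ_LOW,
    CqTable,
    EfficiencyTable,
    ExpressionTable,
    SampleSheet,
    ValidationError,
)
from refstab.stability_suite import run_all_methods
from refstab.consensus_rank import comprehensive_rank, rankings_from_stability


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters of a simulated Cq experiment.

    ``baseline_cq`` has one mean Cq per gene (cycles); ``group_shift``
    is a genes x groups matrix of systematic offsets (cycles), all-zero
    rows marking designed-stable genes; ``noise_sd`` is scalar or
    per-gene.  ``sample_effect_sd`` is the SD of the per-sample loading
    offset shared across genes.
    """

    genes: tuple[str, ...]
    n_groups: int
    n_replicates: int
    baseline_cq: tuple[float, ...]
    group_shift: np.ndarray
    sample_effect_sd: float = 0.3
    noise_sd: float | tuple[float, ...] = 0.2
    efficiencies: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        shift = np.asarray(self.group_shift, dtype=float)
        if shift.shape != (len(self.genes), self.n_groups):
            raise ValidationError("group_shift must be a genes x groups matrix")
        if self.n_groups < 1 or self.n_replicates < 1:
            raise ValidationError("need at least one group and one replicate")
        if self.sample_effect_sd < 0:
            raise ValidationError("sample_effect_sd must be >= 0")
        noise = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (len(self.genes),))
        if (noise < 0).any():
            raise ValidationError("noise_sd must be >= 0")
        for b in self.baseline_cq:
            if not (CQ_LOW < b < CQ_HIGH):
                raise ValidationError(f"baseline Cq {b} outside ({CQ_LOW:g}, {CQ_HIGH:g})")
        shift = shift.copy()
        shift.setflags(write=False)
        object.__setattr__(self, "group_shift", shift)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def stable_genes(self) -> tuple[str, ...]:
        """Genes whose group shift is zero everywhere (designed stable)."""
        flat = np.all(self.group_shift == 0.0, axis=1)
        return tuple(g for g, f in zip(self.genes, flat) if f)

    @property
    def noise_sd_per_gene(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_genes,)
        ).astype(float)


def make_spec(
    n_genes: int = 9,
    n_groups: int = 5,
    n_replicates: int = 3,
    n_stable: int = 3,
    shift_max: float = 2.0,
    noise_sd: float = 0.2,
    sample_effect_sd: float = 0.3,
    seed: int = 0,
    efficiency_range: tuple[float, float] = (1.95, 2.01),
) -> SimulationSpec:
    """Draw a randomized spec with ``n_stable`` designed-stable genes.

    Unstable genes get a shift in every non-control group whose
    magnitude is drawn between ``shift_max / 4`` and ``shift_max`` with
    random sign, so the stable/unstable labels are meaningful ground
    truth rather than a matter of luck.  Baselines are uniform on
    20-27 cycles (typical reference-gene abundance); efficiencies are
    uniform on the given range.
    """
    if not (0 <= n_stable <= n_genes):
        raise ValidationError("n_stable must be between 0 and n_genes")
    rng = np.random.default_rng(seed)
    genes = tuple(
        [f"stable_{i + 1}" for i in range(n_stable)]
        + [f"variable_{i + 1}" for i in range(n_genes - n_stable)]
    )
    baseline = rng.uniform(20.0, 27.0, size=n_genes)
    shift = np.zeros((n_genes, n_groups))
    n_var = n_genes - n_stable
    if n_var and n_groups > 1 and shift_max > 0:
        mag = rng.uniform(shift_max / 4, shift_max, size=(n_var, n_groups - 1))
        sign = rng.choice([-1.0, 1.0], size=(n_var, n_groups - 1))
        shift[n_stable:, 1:] = mag * sign
    eff = rng.uniform(*efficiency_range, size=n_genes)
    return SimulationSpec(
        genes=genes,
        n_groups=n_groups,
        n_replicates=n_replicates,
        baseline_cq=tuple(baseline),
        group_shift=shift,
        sample_effect_sd=sample_effect_sd,
        noise_sd=noise_sd,
        efficiencies=tuple(eff),
        seed=seed,
    )


def simulate_cq_experiment(
    spec: SimulationSpec,
) -> tuple[CqTable, SampleSheet, EfficiencyTable]:
    """Generate one Cq experiment from a spec (deterministic given seed).

    Group 1 is named ``control``; samples are ``<group>_r<replicate>``.
    Raises if any generated Cq falls outside the valid (0, 45) range,
    with advice to adjust baselines or shrink effects.
    """
    rng = np.random.default_rng(spec.seed)
    groups = ["control"] + [f"treatment_{k}" for k in range(1, spec.n_groups)]
    sample_ids: list[str] = []
    sample_group: list[str] = []
    replicates: list[int] = []
    for group in groups:
        for r in range(1, spec.n_replicates + 1):
            sample_ids.append(f"{group}_r{r}")
            sample_group.append(group)
            replicates.append(r)
    n_samples = len(sample_ids)
    group_index = np.repeat(np.arange(spec.n_groups), spec.n_replicates)

    sample_effect = rng.normal(0.0, spec.sample_effect_sd, size=n_samples)
    noise = rng.normal(0.0, 1.0, size=(spec.n_genes, n_samples))
    noise *= spec.noise_sd_per_gene[:, None]
    cq = (
        np.asarray(spec.baseline_cq)[:, None]
        + spec.group_shift[:, group_index]
        + sample_effect[None, :]
        + noise
    )
    if (cq <= CQ_LOW).any() or (cq >= CQ_HIGH).any():
        raise ValidationError(
            "simulated Cq left the valid (0, 45) range; adjust baseline_cq or "
            "reduce shift/noise magnitudes"
        )
    table = CqTable(spec.genes, tuple(sample_ids), cq)
    sheet = SampleSheet(tuple(sample_ids), tuple(sample_group), tuple(replicates))
    eff_values = spec.efficiencies or tuple([2.0] * spec.n_genes)
    eff = EfficiencyTable(dict(zip(spec.genes, eff_values)))
    return table, sheet, eff


def simulate_expression_table(
    n_stable: int,
    n_variable: int,
    n_conditions: int,
    seed: int = 0,
) -> ExpressionTable:
    """Expression matrix with designed low- and high-dispersion genes.

    Stable genes are constructed with condition-level sample CV in
    [0.05, 0.18] (hence DPM comfortably below 0.3) and means on 20-500;
    variable genes with CV in [0.55, 0.9] (DPM above 0.3 for any
    realistic condition count) and means on 15-800.  All values are
    strictly positive.
    """
    if n_stable < 0 or n_variable < 0:
        raise ValidationError("gene counts must be >= 0")
    if n_conditions < 2:
        raise ValidationError("need at least 2 conditions")
    rng = np.random.default_rng(seed)

    def profile(mean: float, target_cv: float) -> np.ndarray:
        # exact-sample-CV construction: scale a centered unit-sd pattern
        for _ in range(100):
            u = rng.normal(size=n_conditions)
            c = u - u.mean()
            sd = c.std(ddof=1)
            if sd == 0:
                continue
            w = 1.0 + target_cv * c / sd
            if w.min() > 0.05:
                return mean * w
        raise ValidationError("could not construct a positive expression profile")

    genes, rows = [], []
    for i in range(n_stable):
        genes.append(f"stable_{i + 1}")
        rows.append(profile(rng.uniform(20, 500), rng.uniform(0.05, 0.18)))
    for i in range(n_variable):
        genes.append(f"variable_{i + 1}")
        rows.append(profile(rng.uniform(15, 800), rng.uniform(0.55, 0.9)))
    conditions = tuple(f"condition_{j + 1}" for j in range(n_conditions))
    values = np.stack(rows) if rows else np.empty((0, n_conditions))
    return ExpressionTable(
        genes=tuple(genes),
        conditions=conditions,
        values=values,
        annotated=tuple([True] * len(genes)),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Hit rates of designed-stable genes over simulation replicates."""

    per_method: dict[str, float]
    consensus_hit_rate: float
    n_replicates: int
    k: int


def recovery_experiment(
    spec: SimulationSpec, n_replicates: int, k: int
) -> RecoveryReport:
    """Fraction of replicates placing all designed-stable genes in the top k.

    Each replicate redraws sample effects and noise (seeds derived from
    ``spec.seed``), runs all four stability methods plus the consensus
    ranking, and checks whether the designed-stable set occupies the
    top ``k`` positions.
    """
    stable = set(spec.stable_genes)
    if len(stable) > k:
        raise ValidationError(f"spec has {len(stable)} stable genes but k = {k}")
    seeder = np.random.default_rng(spec.seed)
    hits = {m: 0 for m in ("genorm", "normfinder", "bestkeeper", "deltact")}
    consensus_hits = 0
    for _ in range(n_replicates):
        child = dataclasses.replace(spec, seed=int(seeder.integers(2**31)))
        cq, sheet, eff = simulate_cq_experiment(child)
        results = run_all_methods(cq, sheet, eff)
        orders = {
            "genorm": results["genorm"].stability_order,
            "normfinder": tuple(
                sorted(results["normfinder"].stability,
                       key=lambda g: (results["normfinder"].stability[g], g))
            ),
            "bestkeeper": results["bestkeeper"].rank_order,
            "deltact": tuple(
                sorted(results["deltact"].mean_sd,
                       key=lambda g: (results["deltact"].mean_sd[g], g))
            ),
        }
        for method, order in orders.items():
            if stable <= set(order[:k]):
                hits[method] += 1
        consensus = comprehensive_rank(rankings_from_stability(results))
        if stable <= set(consensus.final_order[:k]):
            consensus_hits += 1
    return RecoveryReport(
        per_method={m: h / n_replicates for m, h in hits.items()},
        consensus_hit_rate=consensus_hits / n_replicates,
        n_replicates=n_replicates,
        k=k,
    )
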
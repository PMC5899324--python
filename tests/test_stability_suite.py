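import dataclasses
import math

import numpy as np
import pytest

from refstab.quant_io import CqTable, EfficiencyTable, SampleSheet, ValidationError
from refstab.stability_suite import (
    bestkeeper_analyze,
    deltact_rank,
    genorm_pairwise_sd,
    genorm_rank,
    normfinder_stability,
    to_relative_quantity,
)
from refstab.synthetic_data import SimulationSpec, simulate_cq_experiment
from tests.conftest import random_cq
from tests.oracle_genorm import brute_genorm

SD_TOY = math.sqrt(16 / 3)  # sample SD of (-5, -5, -1), i.e. 2.3094


class TestRelativeQuantity:
    def test_powers_of_two(self):
        cq = CqTable(("g",), ("a", "b", "c"), [[20, 21, 22]])
        q = to_relative_quantity(cq)
        np.testing.assert_allclose(q.quantities[0], [1.0, 0.5, 0.25])

    def test_constant_row_gives_all_ones(self):
        cq = CqTable(("g",), ("a", "b"), [[25, 25]])
        q = to_relative_quantity(cq)
        np.testing.assert_allclose(q.quantities[0], [1.0, 1.0])

    def test_custom_efficiency(self):
        cq = CqTable(("g",), ("a", "b"), [[20, 21]])
        q = to_relative_quantity(cq, EfficiencyTable({"g": 1.9}))
        assert q.quantities[0, 1] == pytest.approx(1 / 1.9)

    def test_quantities_bounded_and_peaking_at_one(self, rng):
        q = to_relative_quantity(random_cq(rng, 6, 12))
        assert (q.quantities > 0).all() and (q.quantities <= 1).all()
        np.testing.assert_allclose(q.quantities.max(axis=1), 1.0)


class TestGeNormPairwiseSd:
    def test_hand_computed_pair_sd(self, toy_cq):
        v = genorm_pairwise_sd(to_relative_quantity(toy_cq))
        assert v[0, 1] == pytest.approx(SD_TOY, abs=1e-9)
        assert v[1, 0] == v[0, 1] and v[0, 0] == 0.0

    def test_identical_profiles_have_zero_sd(self):
        cq = CqTable(("A", "B"), ("a", "b", "c"), [[20, 21, 22], [20, 21, 22]])
        assert genorm_pairwise_sd(to_relative_quantity(cq))[0, 1] == 0.0

    def test_constant_shift_has_zero_sd(self):
        cq = CqTable(("A", "B"), ("a", "b", "c"), [[20, 21, 22], [23, 24, 25]])
        assert genorm_pairwise_sd(to_relative_quantity(cq))[0, 1] == pytest.approx(0, abs=1e-12)

    def test_too_few_samples_rejected(self):
        cq = CqTable(("A", "B"), ("a", "b"), [[20, 21], [22, 25]])
        with pytest.raises(ValidationError, match="samples"):
            genorm_pairwise_sd(to_relative_quantity(cq))


class TestGeNormRank:
    def test_final_pair_shares_one_m_value(self, rng):
        result = genorm_rank(to_relative_quantity(random_cq(rng, 5, 9)))
        a, b = result.final_pair
        assert result.m_values[a] == result.m_values[b]

    def test_noisy_gene_removed_first_among_duplicates(self, rng):
        base = rng.uniform(20, 24, size=8)
        noisy = base + rng.normal(0, 1.5, size=8)
        cq = CqTable(
            ("dup1", "dup2", "dup3", "noisy"),
            tuple(f"s{i}" for i in range(8)),
            np.vstack([base, base + 1, base + 2, noisy]),
        )
        result = genorm_rank(to_relative_quantity(cq))
        assert result.exclusion_order[0] == "noisy"

    @pytest.mark.parametrize("n_genes", [4, 5, 6])
    def test_matches_brute_force_oracle(self, n_genes, rng):
        for _ in range(7):  # 21 tables over the three sizes
            cq = random_cq(rng, n_genes, 10)
            eff = {g: float(e) for g, e in zip(cq.genes, rng.uniform(1.9, 2.1, n_genes))}
            result = genorm_rank(to_relative_quantity(cq, EfficiencyTable(eff)))
            rows = {g: list(cq.values[i]) for i, g in enumerate(cq.genes)}
            removal, m_at_removal, final_pair, final_m = brute_genorm(rows, eff)
            assert list(result.exclusion_order) == removal
            assert tuple(sorted(result.final_pair)) == tuple(sorted(final_pair))
            for gene, m in zip(removal, m_at_removal):
                assert result.m_values[gene] == pytest.approx(m, abs=1e-9)
            assert result.m_values[final_pair[0]] == pytest.approx(final_m, abs=1e-9)

    def test_adding_a_copy_to_copies_gives_zero_pairwise_variation(self, rng):
        # genes a, b, c share one profile (constant shifts); d is noisy.
        # The top-3 normalization factor equals the top-2 one up to a
        # constant, so V(2/3) vanishes.
        base = rng.uniform(20, 26, size=9)
        noisy = base + rng.normal(0, 1.0, size=9)
        values = np.vstack([base, base + 1, base + 2, noisy])
        cq = CqTable(("a", "b", "c", "d"), tuple(f"s{i}" for i in range(9)), values)
        result = genorm_rank(to_relative_quantity(cq))
        assert set(result.stability_order[:3]) == {"a", "b", "c"}
        assert result.pairwise_variation[2] == pytest.approx(0, abs=1e-12)

    def test_recommended_n_respects_cutoff(self, rng):
        values = 22 + np.arange(5)[:, None] * 0.5 + rng.normal(0, 0.02, (5, 12))
        cq = CqTable(tuple("abcde"), tuple(f"s{i}" for i in range(12)), values)
        result = genorm_rank(to_relative_quantity(cq))
        assert result.recommended_n == 2  # tiny noise: two genes suffice

    def test_fewer_than_three_genes_rejected(self, toy_cq):
        with pytest.raises(ValidationError, match="3 genes"):
            genorm_rank(to_relative_quantity(toy_cq))

    def test_shift_invariance_of_m_values(self, rng):
        cq = random_cq(rng, 5, 9)
        shifted = np.array(cq.values, copy=True)
        shifted[2] += 3.0
        cq2 = CqTable(cq.genes, cq.samples, shifted)
        r1 = genorm_rank(to_relative_quantity(cq))
        r2 = genorm_rank(to_relative_quantity(cq2))
        for g in cq.genes:
            assert r1.m_values[g] == pytest.approx(r2.m_values[g], abs=1e-9)


class TestNormFinder:
    def test_constant_genes_all_minimal(self):
        cq = CqTable(
            ("a", "b", "c"), tuple(f"s{i}" for i in range(6)),
            np.array([[20.0] * 6, [22.0] * 6, [24.0] * 6]),
        )
        sheet = SampleSheet(cq.samples, ("g1",) * 3 + ("g2",) * 3, (1, 2, 3, 1, 2, 3))
        result = normfinder_stability(to_relative_quantity(cq), sheet)
        assert all(v == 0.0 for v in result.stability.values())

    def test_group_shifted_gene_has_largest_sv(self):
        rng = np.random.default_rng(42)
        values = 22.0 + rng.normal(0, 0.1, size=(5, 12))
        values[0, 6:] += 2.5  # gene a shifts in group 2
        cq = CqTable(tuple("abcde"), tuple(f"s{i}" for i in range(12)), values)
        sheet = SampleSheet(cq.samples, ("g1",) * 6 + ("g2",) * 6, (1, 2, 3, 4, 5, 6) * 2)
        result = normfinder_stability(to_relative_quantity(cq), sheet)
        assert max(result.stability, key=result.stability.get) == "a"

    def test_singleton_group_instructs_single_group_mode(self):
        cq = CqTable(
            ("a", "b", "c"), ("s1", "s2", "s3"),
            [[20, 21, 20], [22, 21, 22], [23, 24, 23]],
        )
        sheet = SampleSheet(("s1", "s2", "s3"), ("g1", "g1", "g2"), (1, 2, 1))
        with pytest.raises(ValidationError, match="single-group"):
            normfinder_stability(to_relative_quantity(cq), sheet)

    def test_single_group_mode_reduces_to_variation(self, rng):
        cq = random_cq(rng, 4, 8)
        sheet = SampleSheet(cq.samples, ("only",) * 8, tuple(range(1, 9)))
        result = normfinder_stability(to_relative_quantity(cq), sheet)
        assert not result.grouped and result.inter_dev == {}
        for g in cq.genes:
            assert result.stability[g] == pytest.approx(
                math.sqrt(result.intra_var[g]["all"])
            )

    def test_sv_tracks_true_total_variation(self):
        """Parameter recovery: over 100 simulated experiments with known
        per-gene noise and group shifts, SV rank-correlates >= 0.9 with
        the true total variation."""
        from scipy.stats import spearmanr

        n_genes, n_rep = 9, 6
        # NormFinder identifies deviations relative to the gene-average
        # shift (they sum to zero), so the design fixes well-separated
        # deviation magnitudes with mixed signs that nearly cancel
        mags = 0.2 * np.arange(1, n_genes + 1)
        signs = np.array([1, 1, 1, 1, 1, -1, 1, -1, -1])
        shifts = mags * signs + 2.0
        noise = 0.15 + 0.03 * np.arange(n_genes)
        truth = np.abs(shifts - shifts.mean()) / 2 + noise / np.sqrt(n_rep)
        rhos = []
        for seed in range(100):
            spec = SimulationSpec(
                genes=tuple(f"g{i}" for i in range(n_genes)),
                n_groups=2,
                n_replicates=n_rep,
                baseline_cq=tuple([24.0] * n_genes),
                group_shift=np.column_stack([np.zeros(n_genes), shifts]),
                sample_effect_sd=0.3,
                noise_sd=tuple(noise),
                seed=seed,
            )
            cq, sheet, eff = simulate_cq_experiment(spec)
            result = normfinder_stability(to_relative_quantity(cq, eff), sheet)
            sv = np.array([result.stability[g] for g in spec.genes])
            rhos.append(spearmanr(sv, truth).statistic)
        assert np.mean(rhos) >= 0.9

    def test_sv_nondecreasing_in_shift_magnitude(self):
        base_shift = np.zeros((5, 2))
        base_shift[0, 1] = 0.5
        svs = []
        for scale in (1.0, 2.0, 4.0):
            spec = SimulationSpec(
                genes=tuple("abcde"),
                n_groups=2,
                n_replicates=5,
                baseline_cq=tuple([23.0] * 5),
                group_shift=base_shift * scale,
                noise_sd=0.2,
                seed=99,
            )
            cq, sheet, eff = simulate_cq_experiment(spec)
            result = normfinder_stability(to_relative_quantity(cq, eff), sheet)
            svs.append(result.stability["a"])
        assert svs[0] <= svs[1] <= svs[2]


class TestBestKeeper:
    def test_hand_computed_descriptives(self):
        cq = CqTable(("g", "h"), ("a", "b", "c"), [[20, 21, 22], [24, 24, 24]])
        result = bestkeeper_analyze(cq)
        assert result.arithmetic_mean["g"] == pytest.approx(21.0)
        assert result.sd["g"] == pytest.approx(2 / 3)
        assert result.cv["g"] == pytest.approx(100 * (2 / 3) / 21)

    def test_single_gene_correlates_perfectly_with_index(self):
        cq = CqTable(("g",), ("a", "b", "c", "d"), [[20, 21, 22, 23]])
        result = bestkeeper_analyze(cq)
        assert result.index == {s: pytest.approx(v) for s, v in zip("abcd", [20, 21, 22, 23])}
        assert result.r["g"] == pytest.approx(1.0)

    def test_sd_above_one_cycle_unacceptable(self):
        cq = CqTable(("g", "h"), ("a", "b", "c"),
                     [[20, 21.8, 23.2], [24, 24.1, 23.9]])
        result = bestkeeper_analyze(cq)
        assert result.sd["g"] > 1 and not result.acceptable["g"]
        assert result.acceptable["h"]

    def test_zero_variance_gene_ranks_first_with_nan_r(self):
        cq = CqTable(("flat", "wavy"), ("a", "b", "c"),
                     [[22, 22, 22], [20, 25, 21]])
        result = bestkeeper_analyze(cq)
        assert math.isnan(result.r["flat"])
        assert result.acceptable["flat"]
        assert result.rank_order[0] == "flat"

    def test_geometric_mean_at_most_arithmetic(self, rng):
        result = bestkeeper_analyze(random_cq(rng, 7, 10))
        for g in result.genes:
            assert result.geometric_mean[g] <= result.arithmetic_mean[g]

    def test_shift_changes_cv_and_index_predictably(self, rng):
        cq = random_cq(rng, 3, 8)
        shifted = np.array(cq.values, copy=True)
        shifted[1] += 2.0
        r1 = bestkeeper_analyze(cq)
        r2 = bestkeeper_analyze(CqTable(cq.genes, cq.samples, shifted))
        g = cq.genes[1]
        assert r2.sd[g] == pytest.approx(r1.sd[g], abs=1e-12)  # MAD shift-invariant
        assert r2.cv[g] < r1.cv[g]  # same spread over larger mean


class TestDeltaCt:
    def test_two_gene_toy_mean_sd(self, toy_cq):
        result = deltact_rank(toy_cq)
        assert result.pair_sd[0, 1] == pytest.approx(SD_TOY, abs=1e-9)
        assert result.mean_sd["A"] == pytest.approx(SD_TOY, abs=1e-9)
        assert result.mean_sd["B"] == pytest.approx(SD_TOY, abs=1e-9)

    def test_duplicate_genes_have_zero_pair_sd(self):
        cq = CqTable(("A", "B"), ("a", "b", "c"), [[20, 21, 22], [20, 21, 22]])
        assert deltact_rank(cq).pair_sd[0, 1] == 0.0

    def test_equals_initial_genorm_m_when_efficiency_two(self, rng):
        """Algebraic identity: with E = 2 for all genes, log2 quantity
        ratios equal Cq differences up to a constant, so delta-Ct mean
        pair-SD is the initial geNorm M."""
        for _ in range(50):
            cq = random_cq(rng, 6, 9)
            d = deltact_rank(cq)
            g = genorm_rank(to_relative_quantity(cq))
            initial_m = g.m_trajectory[0]
            for gene in cq.genes:
                assert d.mean_sd[gene] == pytest.approx(initial_m[gene], abs=1e-9)


class TestPermutationInvariance:
    def test_reordering_samples_and_genes_permutes_scores(self, rng):
        cq = random_cq(rng, 5, 8)
        perm_g = rng.permutation(5)
        perm_s = rng.permutation(8)
        cq2 = CqTable(
            tuple(cq.genes[i] for i in perm_g),
            tuple(cq.samples[j] for j in perm_s),
            cq.values[np.ix_(perm_g, perm_s)],
        )
        for result_fn in (
            lambda t: deltact_rank(t).mean_sd,
            lambda t: genorm_rank(to_relative_quantity(t)).m_values,
            lambda t: bestkeeper_analyze(t).sd,
        ):
            s1, s2 = result_fn(cq), result_fn(cq2)
            for g in cq.genes:
                assert s1[g] == pytest.approx(s2[g], abs=1e-9)
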
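from __future__ import annotations


import numpy as np
import pytest

from refstab import genorm
from refstab.qpcr_data import EfficiencyTable, compute_rq, log_rq

from conftest import random_cq


def brute_force_m(logq: np.ndarray) -> np.ndarray:
    """Oracle: explicit double loop over gene pairs."""
    g = logq.shape[0]
    m = np.zeros(g)
    for j in range(g):
        sds = []
        for k in range(g):
            if k == j:
                continue
            sds.append(np.std(logq[j] - logq[k], ddof=1))
        m[j] = np.mean(sds)
    return m


def brute_force_exclusion(logq: np.ndarray) -> list[int]:
    """Oracle: literal exclusion loop returning removed row indices."""
    remaining = list(range(logq.shape[0]))
    removed = []
    while len(remaining) > 2:
        m = brute_force_m(logq[remaining])
        best = None
        for pos, idx in enumerate(remaining):
            if best is None or m[pos] > m[best[0]] or (
                m[pos] == m[best[0]] and idx > remaining[best[0]]
            ):
                best = (pos, idx)
        removed.append(best[1])
        remaining.remove(best[1])
    return removed


class TestMValues:
    def test_constant_offset_pair_has_zero_m(self):
        logq = np.vstack([np.linspace(-3, 0, 5), np.linspace(-3, 0, 5) + 1.3])
        np.testing.assert_allclose(genorm.m_values(logq), 0.0, atol=1e-12)

    def test_matches_brute_force_on_toy_matrix(self, rng):
        logq = rng.normal(size=(3, 4))
        np.testing.assert_allclose(genorm.m_values(logq), brute_force_m(logq), atol=1e-12)

    def test_shift_invariance(self, rng):
        logq = rng.normal(size=(4, 6))
        shifted = logq.copy()
        shifted[2] += 5.0
        np.testing.assert_allclose(
            genorm.m_values(logq), genorm.m_values(shifted), atol=1e-12
        )

    def test_too_small_inputs_rejected(self):
        with pytest.raises(ValueError):
            genorm.m_values(np.ones((1, 5)))
        with pytest.raises(ValueError):
            genorm.m_values(np.ones((3, 1)))


class TestRankGenes:
    def test_needs_three_genes(self, rng):
        with pytest.raises(ValueError):
            genorm.rank_genes(rng.normal(size=(2, 5)))

    def test_top_tie_of_size_two(self, rng):
        logq = rng.normal(size=(6, 8))
        res = genorm.rank_genes(logq)
        tie_genes = [g for g, lab in res.ranking.labels.items() if lab == frozenset({1, 2})]
        assert len(tie_genes) == 2
        assert sorted(tie_genes) == sorted(res.final_pair)

    def test_exclusion_order_is_permutation(self, rng):
        res = genorm.rank_genes(rng.normal(size=(5, 6)), ["a", "b", "c", "d", "e"])
        assert sorted(res.exclusion_order + res.final_pair) == ["a", "b", "c", "d", "e"]

    def test_noisy_gene_excluded_first(self):
        """A gene with an independent SD-1.0 noise term on an otherwise
        proportional panel is removed first in >=99% of 200 seeds."""
        hits = 0
        for seed in range(200):
            gen = np.random.default_rng(seed)
            shared = gen.normal(0, 1, size=10)
            logq = np.vstack([shared + c for c in (0.0, 0.5, 1.0, 1.5)])
            logq = np.vstack([logq, shared + gen.normal(0, 1.0, size=10)])
            res = genorm.rank_genes(logq)
            hits += res.exclusion_order[0] == "g5"
        assert hits >= 198

    def test_exact_tie_removes_later_gene(self):
        # three identical genes plus one noisy: perfectly symmetric ties
        base = np.linspace(-2, 0, 6)
        noise = np.array([0.4, -0.2, 0.1, -0.5, 0.3, -0.1])
        logq = np.vstack([base, base, base, base + noise])
        res = genorm.rank_genes(logq)
        assert res.exclusion_order[0] == "g4"  # highest M
        assert res.exclusion_order[1] == "g3"  # tie among g1-g3: later input first
        assert res.final_pair == ("g1", "g2")

    def test_reported_m_is_value_at_removal(self, rng):
        logq = rng.normal(size=(5, 7))
        res = genorm.rank_genes(logq)
        first_out = res.exclusion_order[0]
        assert res.m_final[first_out] == pytest.approx(
            res.m_trajectory[0][first_out]
        )
        # final pair reports the common pair SD
        a, b = res.final_pair
        ia, ib = res.genes.index(a), res.genes.index(b)
        pair_v = np.std(logq[ia] - logq[ib], ddof=1)
        assert res.m_final[a] == pytest.approx(pair_v)
        assert res.m_final[b] == pytest.approx(pair_v)

    def test_matches_exhaustive_oracle_on_random_matrices(self):
        for seed in range(30):
            gen = np.random.default_rng(seed)
            g = int(gen.integers(3, 6))
            n = int(gen.integers(3, 7))
            logq = gen.normal(size=(g, n))
            res = genorm.rank_genes(logq)
            expected = [f"g{i+1}" for i in brute_force_exclusion(logq)]
            assert list(res.exclusion_order) == expected

    def test_scale_invariance_of_ranking(self, rng):
        cq = random_cq(rng, 5, 8)
        rq = compute_rq(cq, EfficiencyTable.uniform(cq.genes, 1.95))
        lq = log_rq(rq)
        scaled = lq.copy()
        scaled[1] += np.log2(7.3)  # multiply gene 2's RQ row by 7.3
        res_a = genorm.rank_genes(lq, list(cq.genes))
        res_b = genorm.rank_genes(scaled, list(cq.genes))
        assert res_a.ranking.labels == res_b.ranking.labels
        np.testing.assert_allclose(
            [res_a.m_final[g] for g in cq.genes],
            [res_b.m_final[g] for g in cq.genes],
            atol=1e-12,
        )


class TestPairwiseVariation:
    def test_proportional_panel_gives_zero_v(self):
        base = np.linspace(-4, 0, 6)
        logq = np.vstack([base + c for c in (0.0, 0.3, 0.9, 1.7)])
        res = genorm.rank_genes(logq)
        curve = genorm.pairwise_variation_curve(logq, res)
        np.testing.assert_allclose(curve.v_values, 0.0, atol=1e-12)
        assert curve.optimal_n == 2

    def test_matches_direct_recomputation(self, rng):
        logq = rng.normal(size=(4, 6))
        res = genorm.rank_genes(logq)
        curve = genorm.pairwise_variation_curve(logq, res)
        order = genorm.stability_order(res)
        idx = [res.genes.index(g) for g in order]
        for n, v in zip(curve.n_values, curve.v_values):
            log_nf_n = logq[idx[:n]].mean(axis=0)
            log_nf_n1 = logq[idx[: n + 1]].mean(axis=0)
            assert v == pytest.approx(
                np.std(log_nf_n - log_nf_n1, ddof=1), abs=1e-12
            )

    def test_undefined_optimal_n_with_advisory(self, rng):
        logq = rng.normal(0, 5.0, size=(4, 6))  # huge noise: V never < 0.15
        res = genorm.rank_genes(logq)
        curve = genorm.pairwise_variation_curve(logq, res, cutoff=0.15)
        if all(v >= 0.15 for v in curve.v_values):
            assert curve.optimal_n is None
            assert "visual" in curve.advisory

    def test_v_count_is_g_minus_two(self, rng):
        logq = rng.normal(size=(6, 7))
        res = genorm.rank_genes(logq)
        curve = genorm.pairwise_variation_curve(logq, res)
        assert curve.n_values == (2, 3, 4, 5)
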
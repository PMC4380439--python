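from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.qpcr_data import (
    CqMatrix,
    EfficiencyTable,
    QpcrDataError,
    compute_rq,
    log_rq,
    read_cq,
    read_efficiency,
    read_groups,
    write_cq,
)

from conftest import random_cq


class TestCqMatrix:
    def test_rejects_shape_mismatch(self):
        with pytest.raises(QpcrDataError, match="shape"):
            CqMatrix(("g1",), ("s1", "s2"), np.ones((2, 2)) * 25)

    def test_rejects_duplicate_genes(self):
        with pytest.raises(QpcrDataError, match="duplicate gene"):
            CqMatrix(("g1", "g1"), ("s1",), np.ones((2, 1)) * 25)

    def test_rejects_nan(self):
        with pytest.raises(QpcrDataError, match="incomplete"):
            CqMatrix(("g1",), ("s1", "s2"), np.array([[25.0, np.nan]]))

    def test_rejects_out_of_range_cq(self):
        with pytest.raises(QpcrDataError, match="cycles"):
            CqMatrix(("g1",), ("s1",), np.array([[47.0]]))

    def test_groups_must_cover_samples(self):
        with pytest.raises(QpcrDataError, match="without group"):
            CqMatrix(("g1",), ("s1", "s2"), np.full((1, 2), 25.0), {"s1": "a"})

    def test_group_labels_aligned(self):
        cq = CqMatrix(
            ("g1",), ("s1", "s2"), np.full((1, 2), 25.0), {"s2": "b", "s1": "a"}
        )
        assert list(cq.group_labels()) == ["a", "b"]


class TestReadWrite:
    def test_long_triplicate_mean(self, tmp_path):
        p = tmp_path / "cq.csv"
        p.write_text(
            "sample,gene,replicate,cq\n"
            "s1,g1,1,24.1\ns1,g1,2,24.3\ns1,g1,3,24.2\n"
            "s2,g1,1,25.0\ns2,g1,2,25.0\ns2,g1,3,25.0\n"
        )
        cq = read_cq(p, layout="long")
        assert cq.values[0, 0] == pytest.approx(24.2)
        assert cq.values[0, 1] == pytest.approx(25.0)

    def test_wide_round_trip_preserves_order_and_values(self, tmp_path, rng):
        cq = random_cq(rng, 3, 4)
        p = tmp_path / "cq.tsv"
        write_cq(cq, p)
        back = read_cq(p, layout="wide")
        assert back.genes == cq.genes
        assert back.samples == cq.samples
        np.testing.assert_allclose(back.values, cq.values, atol=1e-6)

    def test_long_missing_cell_is_fatal(self, tmp_path):
        p = tmp_path / "cq.csv"
        p.write_text(
            "sample,gene,cq\ns1,g1,24\ns2,g1,25\ns1,g2,30\n"  # (g2, s2) missing
        )
        with pytest.raises(QpcrDataError, match="incomplete matrix"):
            read_cq(p, layout="long")

    def test_duplicate_triple_rejected(self, tmp_path):
        p = tmp_path / "cq.csv"
        p.write_text("sample,gene,replicate,cq\ns1,g1,1,24\ns1,g1,1,25\n")
        with pytest.raises(QpcrDataError, match="duplicate"):
            read_cq(p, layout="long")

    def test_non_numeric_cq_rejected(self, tmp_path):
        p = tmp_path / "cq.csv"
        p.write_text("gene,s1,s2\ng1,24.0,oops\n")
        with pytest.raises(QpcrDataError, match="non-numeric"):
            read_cq(p, layout="wide")

    def test_replicate_spread_warning(self, tmp_path):
        p = tmp_path / "cq.csv"
        p.write_text("sample,gene,replicate,cq\ns1,g1,1,24.0\ns1,g1,2,24.9\n")
        with pytest.warns(UserWarning, match="spread"):
            read_cq(p, layout="long", max_spread=0.5)

    def test_efficiency_and_groups_readers(self, tmp_path):
        eff_p = tmp_path / "eff.csv"
        eff_p.write_text("gene,efficiency\ng1,1.95\ng2,2.0\n")
        eff = read_efficiency(eff_p)
        assert eff["g1"] == pytest.approx(1.95)
        pct_p = tmp_path / "eff_pct.csv"
        pct_p.write_text("gene,efficiency\ng1,93\n")
        assert read_efficiency(pct_p, unit="percent")["g1"] == pytest.approx(1.93)
        grp_p = tmp_path / "groups.tsv"
        grp_p.write_text("sample\tgroup\ns1\ta\ns2\tb\n")
        assert read_groups(grp_p) == {"s1": "a", "s2": "b"}


class TestEfficiencyTable:
    def test_out_of_bounds_rejected(self):
        with pytest.raises(QpcrDataError):
            EfficiencyTable({"g1": 1.4})

    def test_unusual_value_warns(self):
        with pytest.warns(UserWarning, match="outside usual range"):
            EfficiencyTable({"g1": 1.7})

    def test_percent_mapping(self):
        eff = EfficiencyTable.from_percent({"g1": 100.0})
        assert eff["g1"] == 2.0


class TestComputeRQ:
    def test_min_cq_sample_gets_one(self, rng):
        cq = random_cq(rng, 4, 6)
        rq = compute_rq(cq, EfficiencyTable.uniform(cq.genes, 1.9))
        np.testing.assert_allclose(rq.values.max(axis=1), 1.0)
        assert np.all(rq.values > 0)
        assert np.all(rq.values <= 1.0)

    def test_one_doubling_cycle_halves(self):
        cq = CqMatrix(("g1",), ("s1", "s2"), np.array([[24.0, 25.0]]))
        rq = compute_rq(cq, efficiency_mode="E2")
        assert rq.values[0, 1] == pytest.approx(0.5)

    def test_derived_power_example(self):
        # E = 1.9, minCq = 22, Cq = 25 -> RQ = 1.9 ** -3
        cq = CqMatrix(("g1",), ("s1", "s2"), np.array([[22.0, 25.0]]))
        rq = compute_rq(cq, EfficiencyTable({"g1": 1.9}))
        assert rq.values[0, 1] == pytest.approx(1.9**-3)
        assert rq.values[0, 1] == pytest.approx(0.145794, abs=5e-7)

    def test_missing_gene_in_efficiency_table(self):
        cq = CqMatrix(("g1", "g2"), ("s1", "s2"), np.full((2, 2), 25.0))
        with pytest.raises(QpcrDataError, match="absent"):
            compute_rq(cq, EfficiencyTable({"g1": 2.0}))

    def test_e2_mode_equals_all_two_table_bitwise(self, rng):
        cq = random_cq(rng, 5, 7)
        a = compute_rq(cq, efficiency_mode="E2")
        b = compute_rq(cq, EfficiencyTable.uniform(cq.genes, 2.0))
        assert np.array_equal(a.values, b.values)


class TestLogRQ:
    def test_reference_sample_is_zero(self, rng):
        cq = random_cq(rng, 3, 5)
        lq = log_rq(compute_rq(cq, efficiency_mode="E2"))
        np.testing.assert_allclose(lq.max(axis=1), 0.0, atol=1e-12)

    def test_e2_identity_with_cq_deviation(self, rng):
        cq = random_cq(rng, 3, 5)
        lq = log_rq(compute_rq(cq, efficiency_mode="E2"))
        expected = cq.values.min(axis=1, keepdims=True) - cq.values
        np.testing.assert_allclose(lq, expected, atol=1e-12)

    def test_derived_log_example(self):
        cq = CqMatrix(("g1",), ("s1", "s2"), np.array([[22.0, 25.0]]))
        lq = log_rq(compute_rq(cq, EfficiencyTable({"g1": 1.9})))
        assert lq[0, 1] == pytest.approx(-3 * np.log2(1.9))
        assert lq[0, 1] == pytest.approx(-2.777998, abs=5e-6)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_exponent_sign_robustness(seed):
    """Negating the log-quantity matrix (the reciprocal reading of the
    RQ exponent) changes no stability value in the SD/variance-based
    methods and no ranking."""
    from refstab import genorm, normfinder

    gen = np.random.default_rng(seed)
    cq = random_cq(gen, 5, 8)
    eff = EfficiencyTable({g: float(gen.uniform(1.8, 2.1)) for g in cq.genes})
    lq = log_rq(compute_rq(cq, eff))

    np.testing.assert_allclose(genorm.m_values(lq), genorm.m_values(-lq), atol=1e-12)
    res_pos = genorm.rank_genes(lq, list(cq.genes))
    res_neg = genorm.rank_genes(-lq, list(cq.genes))
    assert res_pos.ranking.labels == res_neg.ranking.labels

    nf_pos = normfinder.stability_ungrouped(lq, cq.genes)
    nf_neg = normfinder.stability_ungrouped(-lq, cq.genes)
    assert nf_pos.ranking.labels == nf_neg.ranking.labels
    for g in cq.genes:
        assert nf_pos.rho[g] == pytest.approx(nf_neg.rho[g], abs=1e-12)
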
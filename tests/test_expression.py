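import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_expression
from lncnet.expression import (
    benjamini_hochberg,
    compute_fpkm,
    compute_mirna_tpm,
    nb_differential_test,
)
from lncnet.simulate.counts import nb_draw
from oracles import bh_reference

SAMPLES = ["a1", "a2", "a3", "b1", "b2", "b3"]
GROUPS = {s: ("A" if s.startswith("a") else "B") for s in SAMPLES}


def counts_matrix(array, n_features=None):
    array = np.asarray(array)
    ids = [f"f{i}" for i in range(array.shape[0])]
    samples = SAMPLES[: array.shape[1]]
    groups = {s: GROUPS[s] for s in samples}
    return make_expression(dict(zip(ids, array.tolist())), samples, groups)


class TestFpkm:
    def test_unit_case(self):
        # library of exactly 1e6 reads, 1 kb transcript, 100 counts -> 100
        m = make_expression(
            {"t1": [100], "fill": [999_900]}, ["s1"], unit="count"
        )
        fpkm = compute_fpkm(m, {"t1": 1000, "fill": 1000})
        assert fpkm.values.loc["t1", "s1"] == pytest.approx(100.0)
        assert fpkm.unit == "FPKM"

    def test_scale_invariance_of_ratios(self, rng):
        counts = rng.integers(1, 1000, (20, 2))
        m = counts_matrix(counts)
        lengths = {f"f{i}": int(rng.integers(200, 3000)) for i in range(20)}
        f1 = compute_fpkm(m, lengths).values
        doubled = counts.copy()
        doubled[:, 0] *= 2
        f2 = compute_fpkm(counts_matrix(doubled), lengths).values
        ratios1 = f1.iloc[:, 0] / f1.iloc[0, 0]
        ratios2 = f2.iloc[:, 0] / f2.iloc[0, 0]
        np.testing.assert_allclose(ratios1, ratios2, rtol=1e-12)

    def test_zero_count_zero_fpkm(self):
        m = make_expression({"t1": [0], "t2": [10]}, ["s1"])
        fpkm = compute_fpkm(m, {"t1": 500, "t2": 500})
        assert fpkm.values.loc["t1", "s1"] == 0.0

    def test_empty_library_raises(self):
        m = make_expression({"t1": [0], "t2": [0]}, ["s1"])
        with pytest.raises(ValueError, match="empty"):
            compute_fpkm(m, {"t1": 500, "t2": 500})


class TestTpm:
    def test_symmetric_split(self):
        tpm = compute_mirna_tpm(make_expression({"a": [50], "b": [50]}, ["s1"]))
        assert tpm.values.loc["a", "s1"] == pytest.approx(500_000.0)

    def test_single_feature_full_million(self):
        tpm = compute_mirna_tpm(make_expression({"a": [7]}, ["s1"]))
        assert tpm.values.loc["a", "s1"] == pytest.approx(1e6)

    def test_direct_formula(self):
        tpm = compute_mirna_tpm(make_expression({"a": [1], "b": [9]}, ["s1"]))
        assert tpm.values.loc["a", "s1"] == pytest.approx(100_000.0)
        assert tpm.values.loc["b", "s1"] == pytest.approx(900_000.0)

    def test_column_sum_conservation(self, rng):
        counts = rng.integers(0, 500, (30, 6))
        counts[0] += 1  # keep libraries non-empty
        tpm = compute_mirna_tpm(counts_matrix(counts))
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-9)


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        # p(i) * m / i from the largest rank with a cumulative minimum:
        # {0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4} -> all 0.04
        out = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg(np.array([0.123])), [0.123])

    def test_all_ones_capped(self):
        np.testing.assert_allclose(benjamini_hochberg(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([0.5, 1.5]))

    def test_nan_passthrough(self):
        out = benjamini_hochberg(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_monotone_and_dominating(self, rng):
        p = rng.uniform(0, 1, 200)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_reference_implementation(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(1, 60)))
            np.testing.assert_allclose(
                benjamini_hochberg(p), bh_reference(p), atol=1e-12
            )

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_reference_property(self, values):
        p = np.array(values)
        np.testing.assert_allclose(benjamini_hochberg(p), bh_reference(p), atol=1e-12)


class TestDifferentialTest:
    def test_identical_groups_null(self):
        counts = np.tile([[100, 120, 90, 100, 120, 90]], (5, 1))
        res = nb_differential_test(counts_matrix(counts), "A", "B", "mRNA")
        for r in res:
            assert r.log2_fold_change == pytest.approx(0.0)
            assert r.call == "not_DE"

    def test_group_swap_antisymmetry(self, rng):
        counts = rng.integers(0, 2000, (30, 6))
        m = counts_matrix(counts)
        ab = nb_differential_test(m, "A", "B", "mRNA")
        ba = nb_differential_test(m, "B", "A", "mRNA")
        for r1, r2 in zip(ab, ba):
            assert r1.log2_fold_change == pytest.approx(-r2.log2_fold_change)
            assert r1.p_value == pytest.approx(r2.p_value, nan_ok=True)

    def test_all_zero_feature_excluded(self):
        counts = np.array([[0, 0, 0, 0, 0, 0], [50, 60, 40, 500, 480, 510]])
        res = nb_differential_test(counts_matrix(counts), "A", "B", "mRNA")
        assert np.isnan(res[0].p_value) and res[0].call == "not_DE"
        assert not np.isnan(res[1].p_value)

    def test_all_zero_group_raises(self):
        counts = np.array([[0, 0, 0, 10, 12, 9], [0, 0, 0, 5, 6, 4]])
        with pytest.raises(ValueError, match="all-zero"):
            nb_differential_test(counts_matrix(counts), "A", "B", "mRNA")

    def test_too_few_replicates_raises(self):
        m = make_expression(
            {"f0": [1, 2]}, ["a1", "b1"], {"a1": "A", "b1": "B"}
        )
        with pytest.raises(ValueError, match="replicates"):
            nb_differential_test(m, "A", "B", "mRNA")

    def test_mirna_gates_on_adjusted_p(self, rng):
        counts = rng.integers(50, 150, (40, 6))
        counts[0] = [1000, 1100, 900, 50, 60, 40]
        res = nb_differential_test(counts_matrix(counts), "A", "B", "miRNA")
        assert res[0].call == "up"
        # miRNA rule has no fold-change gate; others not significant
        assert all(r.call == "not_DE" for r in res[1:])

    def test_padj_geq_p(self, rng):
        counts = rng.integers(0, 800, (50, 6))
        res = nb_differential_test(counts_matrix(counts), "A", "B", "mRNA")
        for r in res:
            if not np.isnan(r.p_value):
                assert r.p_adjusted >= r.p_value - 1e-15

    def test_sensitivity_and_fdr_regression(self):
        """Pinned Monte-Carlo operating point: sensitivity 1.00, FDR ~0 at
        planted |log2FC| = 2, mean 500, dispersion 0.05, 3 vs 3 (mixed into
        a null background). Tolerance +-5 percentage points."""
        sens, fdr = [], []
        for seed in range(5):
            rng = np.random.default_rng(7_000 + seed)
            n, nde = 400, 80
            base = 500 * np.exp(rng.normal(0, 0.6, n))
            lfc = np.zeros(n)
            lfc[: nde // 2] = 2.0
            lfc[nde // 2:nde] = -2.0
            mu_a = base * 2.0 ** (lfc / 2)
            mu_b = base * 2.0 ** (-lfc / 2)
            a = nb_draw(rng, np.repeat(mu_a[:, None], 3, 1), 0.05)
            b = nb_draw(rng, np.repeat(mu_b[:, None], 3, 1), 0.05)
            res = nb_differential_test(
                counts_matrix(np.concatenate([a, b], axis=1)), "A", "B", "mRNA"
            )
            called = np.array([r.call != "not_DE" for r in res])
            sens.append(called[:nde].mean())
            fdr.append(called[nde:].sum() / max(called.sum(), 1))
        assert np.mean(sens) >= 0.95
        assert np.mean(fdr) <= 0.05
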
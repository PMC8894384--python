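"""Effective numbers, extended-Simes combination, and Omega estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import overallgene as og
from overallgene.combine import PValueCorrelation, overall_pvalue_batch


def make_omega(mat, labels=None):
    mat = np.asarray(mat, float)
    labels = labels or [f"t{i}" for i in range(mat.shape[0])]
    return PValueCorrelation(labels=tuple(labels), Omega=np.ascontiguousarray(mat))


class TestEffectiveNumber:
    @pytest.mark.parametrize("l", [1, 2, 5, 15])
    def test_independent_tests_count_fully(self, l):
        assert og.effective_number(np.eye(l)) == pytest.approx(l, abs=1e-10)

    @pytest.mark.parametrize("l", [2, 5, 15])
    def test_perfect_dependence_counts_once(self, l):
        assert og.effective_number(np.ones((l, l))) == pytest.approx(1.0, abs=1e-9)

    def test_two_by_two_half_correlation(self):
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert og.effective_number(m) == pytest.approx(1.5, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(2, 10), st.integers(0, 10_000))
    def test_bounded_between_one_and_l(self, l, seed):
        # random correlation matrix from random data
        g = np.random.default_rng(seed)
        data = g.standard_normal((l + 5, l))
        corr = np.corrcoef(data, rowvar=False)
        me = og.effective_number(corr)
        assert 1.0 - 1e-8 <= me <= l + 1e-8


class TestOverallPvalue:
    def test_independent_omega_reduces_to_classical_simes(self):
        p = {"t0": 0.01, "t1": 0.02, "t2": 0.03}
        res = og.overall_pvalue(p, make_omega(np.eye(3)))
        assert res.p_overall == pytest.approx(0.03, abs=1e-12)
        assert res.m_e == pytest.approx(3.0, abs=1e-10)

    def test_perfect_dependence_returns_smallest_p(self):
        p = {"t0": 0.2, "t1": 0.07, "t2": 0.9}
        res = og.overall_pvalue(p, make_omega(np.ones((3, 3))))
        assert res.p_overall == pytest.approx(0.07, abs=1e-9)

    def test_two_test_hand_computation(self):
        # m_e(1) = 1, m_e = m_e(2) = 1.5: min(1.5*0.01/1, 1.5*0.5/1.5) = 0.015
        p = {"t0": 0.01, "t1": 0.5}
        res = og.overall_pvalue(p, make_omega([[1, 0.5], [0.5, 1]]))
        assert res.p_overall == pytest.approx(0.015, abs=1e-12)
        assert list(res.m_e_per_rank) == pytest.approx([1.0, 1.5], abs=1e-12)
        assert res.ordering == ("t0", "t1")

    def test_capped_at_one(self):
        p = {"t0": 0.95, "t1": 0.99}
        res = og.overall_pvalue(p, make_omega(np.eye(2)))
        assert res.p_overall <= 1.0

    def test_label_permutation_invariance(self, rng):
        labels = [f"t{i}" for i in range(6)]
        data = rng.standard_normal((30, 6))
        om = make_omega(np.corrcoef(data, rowvar=False), labels)
        pv = dict(zip(labels, rng.uniform(0, 1, 6)))
        res1 = og.overall_pvalue(pv, om)
        shuffled = {k: pv[k] for k in reversed(labels)}
        res2 = og.overall_pvalue(shuffled, om)
        assert res1.p_overall == pytest.approx(res2.p_overall, abs=1e-14)

    def test_bounded_by_smallest_p_scaled(self, rng):
        labels = [f"t{i}" for i in range(5)]
        data = rng.standard_normal((40, 5))
        om = make_omega(np.corrcoef(data, rowvar=False), labels)
        pv = dict(zip(labels, rng.uniform(0, 1, 5)))
        res = og.overall_pvalue(pv, om)
        assert res.p_overall >= min(pv.values()) - 1e-12
        assert res.p_overall <= res.m_e * min(pv.values()) + 1e-12

    def test_label_mismatch_raises(self):
        with pytest.raises(ValueError):
            og.overall_pvalue({"x": 0.5, "y": 0.5}, make_omega(np.eye(2)))

    def test_batch_matches_scalar_path(self, rng):
        labels = [f"t{i}" for i in range(4)]
        om = make_omega(np.corrcoef(rng.standard_normal((30, 4)), rowvar=False), labels)
        pmat = rng.uniform(0, 1, (20, 4))
        batch = overall_pvalue_batch(pmat, om)
        for i in range(20):
            res = og.overall_pvalue(dict(zip(labels, pmat[i])), om)
            assert batch[i] == pytest.approx(res.p_overall, abs=1e-12)


class TestEstimateNullCorrelation:
    def test_duplicated_studies_are_perfectly_correlated(self, rng):
        m = 6
        R = og.synth_ld(m, "ar1", 0.5)
        raw = rng.standard_normal(m)
        ws = og.WeightSet.from_raw(np.column_stack([raw, raw]), labels=["s1", "s2"])
        om = og.estimate_null_correlation(R, ws, B=60, seed=3)
        i = om.labels.index("BT_s1")
        j = om.labels.index("BT_s2")
        assert om.Omega[i, j] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.diag(om.Omega), 1.0)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        R = og.synth_ld(5, "ar1", 0.4)
        ws = og.WeightSet.from_raw(rng.standard_normal((5, 2)))
        om = og.estimate_null_correlation(R, ws, B=80, seed=4)
        assert np.allclose(om.Omega, om.Omega.T)
        assert np.all(np.abs(om.Omega) <= 1.0 + 1e-12)

    def test_small_b_estimate_converges_to_reference(self, rng):
        R = og.synth_ld(10, "ar1", 0.5)
        ws = og.WeightSet.from_raw(rng.standard_normal((10, 2)))
        om_ref = og.estimate_null_correlation(R, ws, B=4000, seed=11)
        om_1k = og.estimate_null_correlation(R, ws, B=1000, seed=12)
        diff = np.abs(om_1k.Omega - om_ref.Omega)
        assert np.mean(diff <= 0.1) >= 0.95

    def test_requires_two_replications(self, rng):
        ws = og.WeightSet.from_raw(rng.standard_normal((3, 1)))
        with pytest.raises(ValueError):
            og.estimate_null_correlation(np.eye(3), ws, B=1, seed=0)


class TestOmegaConvergence:
    def test_reference_b_has_zero_distance_and_one_row_per_b(self, rng):
        R = og.synth_ld(6, "ar1", 0.5)
        ws = og.WeightSet.from_raw(rng.standard_normal((6, 1)))
        tab = og.omega_convergence(R, ws, B_grid=[16, 64, 200], B_ref=200, seed=5)
        assert list(tab["B"]) == [16, 64, 200]
        assert tab["max_abs_diff"].iloc[-1] == pytest.approx(0.0, abs=1e-14)

    def test_distances_shrink_with_b_on_average(self, rng):
        R = og.synth_ld(6, "ar1", 0.5)
        ws = og.WeightSet.from_raw(rng.standard_normal((6, 1)))
        small, large = [], []
        for seed in range(3):
            tab = og.omega_convergence(R, ws, B_grid=[16, 400], B_ref=800, seed=seed)
            small.append(tab["frobenius"].iloc[0])
            large.append(tab["frobenius"].iloc[1])
        assert np.mean(large) < np.mean(small)
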
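"""Burden/SKAT/SKAT-O: worked examples, oracles, and invariances."""

import numpy as np
import pytest
from scipy.stats import chi2, kstest, norm

import overallgene as og
from overallgene import DegenerateTestError
from overallgene._quadform import _qf_quantile_upper

from conftest import mvn_draws


class TestStandardizeWeights:
    def test_unit_absolute_sum_with_signs(self):
        assert np.allclose(og.standardize_weights([2.0, -2.0]), [0.5, -0.5])
        assert np.allclose(og.standardize_weights([1.0]), [1.0])

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            og.standardize_weights([0.0, 0.0])

    def test_scale_invariance_of_all_three_tests(self, rng):
        m = 5
        U = og.synth_ld(m, "ar1", 0.4)
        Z = rng.standard_normal(m)
        raw = rng.standard_normal(m)
        for c in (3.0, -2.0, 0.01):
            w1 = og.standardize_weights(raw)
            w2 = og.standardize_weights(c * raw)
            for test in (og.bt_test, og.skat_test, og.skato_test):
                assert test(Z, U, w1) == pytest.approx(test(Z, U, w2), rel=1e-9)


class TestBurden:
    def test_single_variant_is_two_sided_normal(self):
        p = og.bt_test([2.0], np.eye(1), [1.0])
        assert p == pytest.approx(2 * norm.sf(2.0), abs=1e-12)

    def test_hand_computed_null_variance(self):
        # v = sum_ij w_i w_j U_ij = 0.25 * (1 + 0.5 + 0.5 + 1) = 0.75
        U = np.array([[1.0, 0.5], [0.5, 1.0]])
        p = og.bt_test([2.0, 2.0], U, [0.5, 0.5])
        assert p == pytest.approx(chi2.sf(4.0 / 0.75, 1), abs=1e-12)

    def test_zero_z_gives_p_one(self):
        assert og.bt_test([0.0, 0.0], np.eye(2), [0.5, 0.5]) == 1.0

    def test_null_pvalues_are_uniform(self, rng):
        m = 6
        U = og.synth_ld(m, "ar1", 0.5)
        w = np.ones(m)
        zs = mvn_draws(U, 10_000, rng)
        v = float(w @ U @ w)
        q = (zs @ w) ** 2
        ps = chi2.sf(q / v, 1)
        # spot-check the vectorized form against the public function
        assert og.bt_test(zs[0], U, w) == pytest.approx(ps[0], abs=1e-10)
        assert kstest(ps, "uniform").pvalue > 1e-3


class TestSkat:
    def test_single_variant_equals_burden(self):
        Z, U, w = [2.0], np.eye(1), [1.0]
        assert og.skat_test(Z, U, w) == pytest.approx(og.bt_test(Z, U, w), abs=1e-12)

    def test_two_variant_eigenvalues_by_hand(self, rng):
        # W = I, U offdiag 0.5 -> eigenvalues 1.5 and 0.5, Q = 2
        U = np.array([[1.0, 0.5], [0.5, 1.0]])
        p = og.skat_test([1.0, 1.0], U, [1.0, 1.0])
        assert p == pytest.approx(og.quad_form_pvalue(2.0, [1.5, 0.5]), abs=1e-12)
        draws = mvn_draws(U, 300_000, rng)
        p_mc = float(((draws**2).sum(axis=1) > 2.0).mean())
        se = np.sqrt(p_mc * (1 - p_mc) / draws.shape[0])
        assert abs(p - p_mc) < 3 * se

    def test_zero_z_gives_p_one(self):
        assert og.skat_test([0.0, 0.0], np.eye(2), [1.0, 1.0]) == 1.0

    def test_random_instances_match_monte_carlo(self, rng):
        for _ in range(4):
            m = int(rng.integers(2, 7))
            U = og.synth_ld(m, "ar1", float(rng.uniform(0.1, 0.7)))
            w = og.standardize_weights(rng.standard_normal(m))
            Z = mvn_draws(U, 1, rng)[0] * rng.uniform(0.8, 1.5)
            p = og.skat_test(Z, U, w)
            q = float(np.sum((w * Z) ** 2))
            draws = mvn_draws(U, 200_000, rng)
            p_mc = float((((draws * w) ** 2).sum(axis=1) > q).mean())
            se = max(np.sqrt(p_mc * (1 - p_mc) / draws.shape[0]), 1e-6)
            assert abs(p - p_mc) < 3 * se


def skato_minp_oracle(Z, U, w, rho, n_draw, seed):
    """Null distribution of the min-p statistic via per-rho thresholds."""
    m = len(Z)
    w = np.asarray(w, float)
    sigma = (w[:, None] * U) * w[None, :]
    evals, evecs = np.linalg.eigh(sigma)
    ut = np.sqrt(np.clip(evals, 0, None)) * (evecs.T @ np.ones(m))
    q_skat = float(np.sum((w * Z) ** 2))
    q_bt = float(w @ Z) ** 2
    prho, thresholds = [], []
    for r in rho:
        A = (1 - r) * np.diag(np.clip(evals, 0, None)) + r * np.outer(ut, ut)
        lam = np.linalg.eigvalsh(A)
        lam = np.ascontiguousarray(lam[lam > 1e-10 * lam.max()])
        prho.append(og.quad_form_pvalue((1 - r) * q_skat + r * q_bt, lam))
    t_obs = min(prho)
    for r in rho:
        A = (1 - r) * np.diag(np.clip(evals, 0, None)) + r * np.outer(ut, ut)
        lam = np.linalg.eigvalsh(A)
        lam = np.ascontiguousarray(lam[lam > 1e-10 * lam.max()])
        thresholds.append(float(_qf_quantile_upper(t_obs, lam)))
    g = np.random.default_rng(seed)
    count = total = 0
    for _ in range(10):
        zs = mvn_draws(U, n_draw // 10, g)
        wz = zs * w
        qs = (wz**2).sum(axis=1)
        s2 = wz.sum(axis=1) ** 2
        rej = np.zeros(len(qs), bool)
        for r, thr in zip(rho, thresholds):
            rej |= ((1 - r) * qs + r * s2) >= thr
        count += int(rej.sum())
        total += len(qs)
    p = count / total
    return t_obs, p, np.sqrt(max(p * (1 - p), 1e-12) / total)


class TestSkatO:
    def test_single_variant_reduces_to_burden(self):
        Z, U, w = [1.7], np.eye(1), [1.0]
        assert og.skato_test(Z, U, w) == pytest.approx(og.bt_test(Z, U, w), abs=1e-12)

    def test_endpoint_grids_reduce_to_skat_and_burden(self, rng):
        m = 4
        U = og.synth_ld(m, "exchangeable", 0.3)
        w = og.standardize_weights(rng.standard_normal(m))
        Z = mvn_draws(U, 1, rng)[0]
        assert og.skato_test(Z, U, w, grid=[0.0]) == og.skat_test(Z, U, w)
        assert og.skato_test(Z, U, w, grid=[1.0]) == og.bt_test(Z, U, w)

    def test_spec_instance_matches_min_p_oracle(self):
        U = og.synth_ld(3, "exchangeable", 0.3)
        w = np.full(3, 1 / 3)
        Z = np.array([1.0, 2.0, 0.5])
        grid = np.linspace(0, 1, 8)
        p = og.skato_test(Z, U, w, grid=grid)
        _, p_mc, se = skato_minp_oracle(Z, U, w, grid, 400_000, seed=1)
        assert abs(p - p_mc) < 3 * se

    def test_bonferroni_envelope(self, rng):
        m = 5
        U = og.synth_ld(m, "ar1", 0.5)
        w = og.standardize_weights(rng.standard_normal(m))
        Z = mvn_draws(U, 1, rng)[0] * 1.5
        grid = og.DEFAULT_RHO_GRID
        sigma = (np.asarray(w)[:, None] * U) * np.asarray(w)[None, :]
        evals, evecs = np.linalg.eigh(sigma)
        ut = np.sqrt(np.clip(evals, 0, None)) * (evecs.T @ np.ones(m))
        q_skat = float(np.sum((w * Z) ** 2))
        q_bt = float(w @ Z) ** 2
        prho = []
        for r in grid:
            A = (1 - r) * np.diag(np.clip(evals, 0, None)) + r * np.outer(ut, ut)
            lam = np.linalg.eigvalsh(A)
            lam = lam[lam > 1e-10 * lam.max()]
            prho.append(og.quad_form_pvalue((1 - r) * q_skat + r * q_bt, lam))
        p = og.skato_test(Z, U, w)
        assert min(prho) - 1e-12 <= p <= min(1.0, len(grid) * min(prho)) + 1e-12


class TestAllTests:
    @pytest.mark.parametrize("k,expected_l", [(4, 15), (20, 63), (0, 3)])
    def test_battery_size(self, rng, k, expected_l):
        m = 8
        raw = rng.standard_normal((m, k)) if k else np.empty((m, 0))
        ws = og.WeightSet.from_raw(raw)
        labels, pvals = og.all_tests(mvn_draws(np.eye(m), 1, rng)[0], np.eye(m), ws)
        assert len(labels) == expected_l
        assert pvals.shape == (expected_l,)
        assert np.all((pvals > 0) & (pvals <= 1))

    def test_label_order_and_agreement_with_single_tests(self, rng):
        m = 5
        U = og.synth_ld(m, "ar1", 0.4)
        Z = mvn_draws(U, 1, rng)[0]
        ws = og.WeightSet.from_raw(rng.standard_normal((m, 2)), labels=["a", "b"])
        labels, pvals = og.all_tests(Z, U, ws)
        assert labels[:3] == ["BT_unweighted", "SKAT_unweighted", "SKATO_unweighted"]
        assert labels[3] == "BT_a"
        got = dict(zip(labels, pvals))
        assert got["BT_unweighted"] == pytest.approx(og.bt_test(Z, U, np.ones(m)), abs=1e-10)
        w_a = ws.W[1]
        assert got["SKAT_a"] == pytest.approx(og.skat_test(Z, U, w_a), abs=1e-10)
        assert got["SKATO_a"] == pytest.approx(og.skato_test(Z, U, w_a), abs=1e-10)
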
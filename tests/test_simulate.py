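"""Synthetic-data generators: structures, contracts, and distributions."""

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

import overallgene as og
from overallgene.simulate import expression_from_weights


class TestSynthLd:
    def test_ar1_structures(self):
        assert np.allclose(og.synth_ld(4, "ar1", 0.0), np.eye(4))
        R = og.synth_ld(3, "ar1", 0.5)
        assert R[0, 1] == pytest.approx(0.5)
        assert R[0, 2] == pytest.approx(0.25)

    def test_exchangeable_psd_bound(self):
        with pytest.raises(ValueError):
            og.synth_ld(4, "exchangeable", -0.5)
        R = og.synth_ld(4, "exchangeable", -0.2)
        assert np.linalg.eigvalsh(R)[0] > -1e-10

    def test_block_structure(self):
        R = og.synth_ld(6, "block", 0.7, block_size=3)
        assert R[0, 2] == pytest.approx(0.7)
        assert R[0, 3] == pytest.approx(0.0)

    def test_all_structures_are_valid_correlations(self):
        for s in ("ar1", "block", "exchangeable"):
            R = og.synth_ld(7, s, 0.4, block_size=3)
            assert np.allclose(R, R.T)
            assert np.allclose(np.diag(R), 1.0)
            assert np.linalg.eigvalsh(R)[0] > -1e-10


class TestHaplotypesAndGenotypes:
    def test_single_haplotype_pool_doubles(self):
        h = np.array([[1, 0, 1, 0]], dtype=np.int8)
        pool = og.HaplotypePool(H=h)
        X, kept = og.generate_genotypes(pool, 50, maf_floor=0.0, seed=0)
        assert np.all(X == 2 * h[0, kept])

    def test_heterozygous_site_is_binomial(self):
        h = np.array([[0, 1], [1, 1]], dtype=np.int8)
        pool = og.HaplotypePool(H=h)
        X, kept = og.generate_genotypes(pool, 10_000, maf_floor=0.0, seed=1)
        col = X[:, list(kept).index(0)]
        counts = [np.sum(col == k) for k in (0, 1, 2)]
        expected = np.array([0.25, 0.5, 0.25]) * len(col)
        assert chisquare(counts, expected).pvalue > 1e-3

    def test_rare_variants_filtered(self):
        g = np.random.default_rng(2)
        h = (g.uniform(size=(400, 5)) < [0.01, 0.3, 0.5, 0.02, 0.2]).astype(np.int8)
        pool = og.HaplotypePool(H=h)
        X, kept = og.generate_genotypes(pool, 5000, maf_floor=0.05, seed=3)
        assert 0 not in kept and 3 not in kept
        maf = np.minimum(X.mean(0) / 2, 1 - X.mean(0) / 2)
        assert np.all(maf >= 0.05)

    def test_pool_generator_reproducible_and_in_range(self):
        p1 = og.synth_haplotype_pool(M=10, n_hap=100, seed=7)
        p2 = og.synth_haplotype_pool(M=10, n_hap=100, seed=7)
        assert np.array_equal(p1.H, p2.H)
        assert set(np.unique(p1.H)) <= {0, 1}


class TestWeightsAndExpression:
    def test_rescaling_hits_target_heritability_exactly(self, rng):
        pool = og.synth_haplotype_pool(M=12, n_hap=200, seed=4)
        X, _ = og.generate_genotypes(pool, 3000, seed=5)
        cfg = og.SimulationConfig(M=X.shape[1], K=3, p_causal=0.3, h_e2=0.2, seed=6)
        W, E = og.generate_weights_and_expression(X, cfg)
        for k in range(3):
            assert (X @ W[:, k]).var() == pytest.approx(0.2, abs=1e-10)

    def test_zero_heritability_gives_pure_noise(self):
        pool = og.synth_haplotype_pool(M=8, n_hap=200, seed=4)
        X, _ = og.generate_genotypes(pool, 2000, seed=5)
        cfg = og.SimulationConfig(M=X.shape[1], K=2, h_e2=0.0, seed=6)
        W, E = og.generate_weights_and_expression(X, cfg)
        assert np.all(W == 0.0)
        assert E.std() == pytest.approx(1.0, abs=0.05)

    def test_large_n_regression_recovers_r_squared(self):
        pool = og.synth_haplotype_pool(M=15, n_hap=300, seed=8)
        X, _ = og.generate_genotypes(pool, 100_000, seed=9)
        cfg = og.SimulationConfig(M=X.shape[1], K=1, p_causal=0.3, h_e2=0.2, seed=10)
        W, E = og.generate_weights_and_expression(X, cfg)
        score = X @ W[:, 0]
        r2 = np.corrcoef(score, E[:, 0])[0, 1] ** 2
        assert r2 == pytest.approx(0.2, abs=0.02)

    def test_fixed_weight_expression_matches_model(self, rng):
        X = rng.integers(0, 3, size=(5000, 6)).astype(float)
        w = rng.standard_normal((6, 2)) * 0.1
        E = expression_from_weights(X, w, 0.2, rng)
        resid = E - X @ w
        assert resid.std() == pytest.approx(np.sqrt(0.8), abs=0.05)


class TestPhenotype:
    def test_zero_heritability_zero_effects(self):
        cfg = og.SimulationConfig(K=4, h_p2=0.0, seed=1)
        Y, beta = og.generate_phenotype(np.zeros((100, 4)), cfg)
        assert np.all(beta == 0.0)

    def test_uni_effects_equal_beta0(self):
        cfg = og.SimulationConfig(K=4, h_p2=0.2, scenario="uni", seed=1)
        _, beta = og.generate_phenotype(np.zeros((10, 4)), cfg)
        assert np.allclose(beta, np.sqrt(0.05))

    def test_bi_effects_split_signs(self):
        cfg = og.SimulationConfig(K=4, h_p2=0.2, scenario="bi", seed=1)
        _, beta = og.generate_phenotype(np.zeros((10, 4)), cfg)
        b0 = np.sqrt(0.05)
        assert np.allclose(beta, [b0, b0, -b0, -b0])

    def test_noise_scenarios_require_four_studies(self):
        with pytest.raises(ValueError):
            og.SimulationConfig(K=3, scenario="uni_noise")

    def test_noise_scenario_centering(self):
        cfg = og.SimulationConfig(K=4, h_p2=0.2, scenario="uni_noise", seed=None)
        g = np.random.default_rng(0)
        betas = np.array(
            [og.generate_phenotype(np.zeros((2, 4)), cfg, rng=g)[1] for _ in range(400)]
        )
        b0 = np.sqrt(0.05)
        # means within ~3 standard errors of beta0 (sd up to sqrt(0.5 h_p2))
        assert betas.mean(axis=0) == pytest.approx([b0] * 4, abs=0.05)
        # the designated relevant tissue gets the smaller perturbation
        assert betas[:, 0].std() == pytest.approx(np.sqrt(0.1 * 0.2), rel=0.2)
        assert betas[:, 1].std() == pytest.approx(np.sqrt(0.5 * 0.2), rel=0.2)

    def test_bi_noise_sign_pattern(self):
        cfg = og.SimulationConfig(K=4, h_p2=0.2, scenario="bi_noise", seed=None)
        g = np.random.default_rng(1)
        betas = np.array(
            [og.generate_phenotype(np.zeros((2, 4)), cfg, rng=g)[1] for _ in range(400)]
        )
        b0 = np.sqrt(0.05)
        assert betas.mean(axis=0) == pytest.approx([-b0, -b0, b0, b0], abs=0.05)


class TestZScores:
    def test_null_z_scores_standard_normal(self, rng):
        X = rng.integers(0, 3, size=(10_000, 8)).astype(float)
        Y = rng.standard_normal(10_000)
        z = og.compute_z_scores(X, Y)
        assert kstest(z, "norm").pvalue > 1e-3

    def test_perfect_fit_is_capped(self):
        X = np.arange(20, dtype=float).reshape(-1, 1)
        z = og.compute_z_scores(X, X[:, 0])
        assert z[0] == pytest.approx(1e8)

    def test_duplicating_individuals_keeps_sign(self, rng):
        X = rng.integers(0, 3, size=(200, 3)).astype(float)
        Y = X[:, 0] * 0.5 + rng.standard_normal(200)
        z1 = og.compute_z_scores(X, Y)
        z2 = og.compute_z_scores(np.vstack([X, X]), np.concatenate([Y, Y]))
        assert np.all(np.sign(z1) == np.sign(z2))

    def test_constant_column_is_nan(self, rng):
        X = np.column_stack([np.ones(100), rng.integers(0, 3, 100).astype(float)])
        z = og.compute_z_scores(X, rng.standard_normal(100))
        assert np.isnan(z[0]) and np.isfinite(z[1])


class TestReproducibility:
    def test_same_seed_same_cohort(self):
        pool = og.synth_haplotype_pool(M=10, n_hap=120, seed=3)
        cfg = og.SimulationConfig(M=10, K=2, n=500, seed=42)
        c1 = og.simulate_cohort(pool, cfg)
        c2 = og.simulate_cohort(pool, cfg)
        assert np.array_equal(c1.X, c2.X)
        assert np.array_equal(c1.Y, c2.Y)
        assert np.array_equal(c1.w_true, c2.w_true)

    def test_end_to_end_signal_flows(self):
        # strong setting: the oracle-weighted linear test must be highly
        # significant in nearly every replicate
        pool = og.synth_haplotype_pool(M=23, n_hap=458, seed=13)
        cfg = og.SimulationConfig(M=23, K=1, p_causal=0.3, h_e2=0.2, h_p2=0.3, n=100_000,
                                  scenario="uni")
        g = np.random.default_rng(77)
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            cohort = og.simulate_cohort(pool, cfg, rng=g)
            z = og.compute_z_scores(cohort.X, cohort.Y)
            R = np.corrcoef(cohort.X, rowvar=False)
            _, p = og.s_twas(z, R, cohort.w_true[:, 0])
            hits += p < 1.75e-6
        assert hits >= 0.95 * n_rep
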
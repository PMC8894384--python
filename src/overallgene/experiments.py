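"""Simulation experiment drivers: type-I error calibration and power.

The type-I driver draws null Z-vectors directly from MVN(0, R), reruns the
full analysis pipeline (per-replicate shrinkage refit, all tests, the
extended-Simes and Cauchy combinations) and reports empirical rejection
rates with binomial standard errors.

The power driver generates full cohorts (haplotype-sampled genotypes,
expression, phenotype), computes GWAS-style Z-scores, estimates LD from the
generated genotypes, and reports the proportion of replicates significant
at the gene-based threshold, together with the BEST / S-TWAS.B /
S-PrediXcan.B reporting maxima.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._kernels import _all_pvalues, _overall_batch, _overall_p, _pvalue_matrix
from .combine import estimate_null_correlation
from .comparators import cauchy_combine, s_predixcan, s_twas, PredixcanInput
from .gene_tests import DEFAULT_RHO_GRID, WeightSet
from .simulate import compute_z_scores, simulate_cohort

__all__ = ["type1_experiment", "power_experiment"]


def _ot_batch(pmat):
    p = np.clip(pmat, 1e-15, 1.0 - 1e-15)
    q = np.tan((0.5 - p) * np.pi).mean(axis=1)
    return 0.5 - np.arctan(q) / np.pi


def type1_experiment(R, weights, n_rep, alphas=(1e-2, 1e-3, 1e-4), seed=None, omega_B=1000,
                     grid=None, refit_a=False):
    """Empirical type-I error rates of every test plus Overall and OT.

    Omega is estimated once with ``omega_B`` replications before the rate
    loop. Returns a tidy DataFrame (method, alpha, rate, se, n_rep).

    Null Z-vectors are drawn directly from MVN(0, R), so R is the exact
    null covariance and the shrinkage truth is a = 1; by default the
    battery therefore runs with the shrinkage inert (with a noisy real LD
    matrix the likelihood pins a near 1 in exactly this way). Setting
    ``refit_a=True`` re-estimates a from every simulated Z-vector instead,
    which injects estimation noise and makes the burden test mildly
    anti-conservative on well-conditioned LD — useful for quantifying that
    effect, not for calibration checks.
    """
    if not isinstance(weights, WeightSet):
        raise TypeError("weights must be a WeightSet")
    R = np.asarray(R, dtype=float)
    rho = DEFAULT_RHO_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    omega = estimate_null_correlation(
        R, weights, B=omega_B, seed=rng, grid=rho, refit_a=refit_a
    )
    evals, evecs = np.linalg.eigh(R)
    chol = evecs * np.sqrt(np.clip(evals, 0.0, None))
    zs = rng.standard_normal((int(n_rep), R.shape[0])) @ chol.T
    pmat, _ = _pvalue_matrix(
        np.ascontiguousarray(zs),
        np.ascontiguousarray(evecs),
        np.ascontiguousarray(evals),
        np.ascontiguousarray(weights.W),
        np.ascontiguousarray(rho),
        bool(refit_a),
        1.0,
        1e-4,
    )
    labels = weights.test_labels()
    if list(omega.labels) != labels:
        # persistent degeneracy: restrict the battery to the surviving tests
        idx = [labels.index(lab) for lab in omega.labels]
        pmat = pmat[:, idx]
        labels = list(omega.labels)
    pmat = np.nan_to_num(pmat, nan=1.0)
    p_overall = _overall_batch(np.ascontiguousarray(pmat), np.ascontiguousarray(omega.Omega))
    p_ot = _ot_batch(pmat)
    columns = {lab: pmat[:, i] for i, lab in enumerate(labels)}
    columns["Overall"] = p_overall
    columns["OT"] = p_ot
    rows = []
    n_rep = int(n_rep)
    for method, pv in columns.items():
        for alpha in alphas:
            rate = float(np.mean(pv < alpha))
            rows.append(
                {
                    "method": method,
                    "alpha": float(alpha),
                    "rate": rate,
                    "se": float(np.sqrt(max(rate * (1 - rate), alpha) / n_rep)),
                    "n_rep": n_rep,
                }
            )
    return pd.DataFrame(rows)


def _analysis_weightset(w_true):
    labels = [f"study{k + 1}" for k in range(w_true.shape[1])]
    return WeightSet.from_raw(w_true, labels=labels)


def power_experiment(pool, config_grid, n_rep=1000, alpha=1.75e-6, seed=None, omega_B=1000,
                     grid=None, refit_a=True, reference_ld=None, fix_weights=False):
    """Power of every method over a grid of simulation cells.

    Each of the ``n_rep`` cohorts per cell is generated afresh (genotypes,
    causal sets, true eQTL weights, expression, phenotype), GWAS-style
    Z-scores are computed, and every method runs against the LD estimated
    from that cohort's own genotypes (or against ``reference_ld`` when a
    mismatched panel is injected), with the cohort's true weights as the
    analysis weights. The null p-value correlation Omega is estimated once
    per cell from a reference cohort, mirroring the once-per-gene
    replication design; cells differing only in phenotypic heritability or
    effect-direction scenario share the reference architecture so their
    powers are directly comparable. ``fix_weights=True`` instead freezes
    the reference cohort's weights and variant set across replicates
    (a fixed-gene view). The output includes the reporting maxima BEST
    (over the 3(K+1) battery), S-TWAS.B and S-PrediXcan.B.
    """
    from .simulate import HaplotypePool, expression_from_weights, generate_genotypes, generate_phenotype

    rho = DEFAULT_RHO_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    arch_root = int(rng.integers(2**31))
    arch_cache = {}
    frames = []
    for cell_id, config in enumerate(config_grid):
        # the gene architecture (variant set, weights, Omega) is a fixed
        # property of (M, K, p_causal, h_e2, n); cells differing only in
        # h_p2 or effect-direction scenario share it, so power is
        # comparable across those axes
        arch_key = (
            config.M,
            config.K,
            round(config.p_causal * 1e6),
            round(config.h_e2 * 1e6),
            config.n,
        )
        if arch_key in arch_cache:
            ref, r_ref, ws_ref, omega, pool_cell = arch_cache[arch_key]
        else:
            arch_rng = np.random.default_rng(
                np.random.SeedSequence([arch_root, *(int(k) for k in arch_key)])
            )
            ref = simulate_cohort(pool, config, rng=arch_rng)
            r_ref = np.corrcoef(ref.X, rowvar=False) if reference_ld is None else reference_ld
            ws_ref = _analysis_weightset(ref.w_true)
            omega = estimate_null_correlation(
                r_ref, ws_ref, B=omega_B, seed=arch_rng, grid=rho, refit_a=refit_a
            )
            pool_cell = HaplotypePool(
                H=pool.H[:, ref.kept_variants], frequencies=pool.frequencies
            )
            arch_cache[arch_key] = (ref, r_ref, ws_ref, omega, pool_cell)
        labels = ws_ref.test_labels()
        omega_idx = np.array([labels.index(lab) for lab in omega.labels])
        batt = np.empty((n_rep, len(labels)))
        pov = np.empty(n_rep)
        pot = np.empty(n_rep)
        ptwas = np.empty((n_rep, config.K))
        ppred = np.empty((n_rep, config.K))
        for b in range(n_rep):
            if fix_weights:
                # fresh cohort over the fixed variant set and architecture
                X, _ = generate_genotypes(pool_cell, config.n, 0.0, seed=rng)
                E = expression_from_weights(X, ref.w_true, config.h_e2, rng)
                Y, _ = generate_phenotype(E, config, rng=rng)
                z = compute_z_scores(X, Y)
                ws = ws_ref
                w_true = ref.w_true
            else:
                cohort = simulate_cohort(pool, config, rng=rng)
                X, Y, w_true = cohort.X, cohort.Y, cohort.w_true
                z = compute_z_scores(X, Y)
                ws = _analysis_weightset(w_true)
            ok = np.isfinite(z)
            z, X = z[ok], X[:, ok]
            if not ok.all():
                ws = _analysis_weightset(w_true[ok])
            r_hat = np.corrcoef(X, rowvar=False) if reference_ld is None else reference_ld
            evals, evecs = np.linalg.eigh(r_hat)
            pv, _ = _all_pvalues(
                np.ascontiguousarray(z),
                np.ascontiguousarray(evecs),
                np.ascontiguousarray(evals),
                np.ascontiguousarray(ws.W),
                np.ascontiguousarray(rho),
                bool(refit_a),
                1.0,
                1e-4,
                True,
            )
            pv = np.nan_to_num(pv, nan=1.0)
            batt[b] = pv
            pov[b] = _overall_p(
                np.ascontiguousarray(pv[omega_idx]), np.ascontiguousarray(omega.Omega)
            )
            pot[b] = cauchy_combine(pv)
            for k in range(config.K):
                w_k = ws.W[k + 1]
                ptwas[b, k] = s_twas(z, r_hat, w_k)[1]
                ppred[b, k] = s_predixcan(z, PredixcanInput(), w_k, R=r_hat)[1]
        def _pw(p):
            return float(np.mean(p < alpha))

        rows = []
        meta = {
            "cell": cell_id,
            "scenario": config.scenario,
            "p_causal": config.p_causal,
            "h_e2": config.h_e2,
            "h_p2": config.h_p2,
            "n": config.n,
        }
        batt_powers = {lab: _pw(batt[:, i]) for i, lab in enumerate(labels)}
        for lab, pw in batt_powers.items():
            rows.append({**meta, "method": lab, "power": pw})
        rows.append({**meta, "method": "BEST", "power": max(batt_powers.values())})
        rows.append({**meta, "method": "Overall", "power": _pw(pov)})
        rows.append({**meta, "method": "OT", "power": _pw(pot)})
        for k in range(config.K):
            rows.append({**meta, "method": f"S-TWAS_study{k + 1}", "power": _pw(ptwas[:, k])})
            rows.append({**meta, "method": f"S-PrediXcan_study{k + 1}", "power": _pw(ppred[:, k])})
        rows.append({**meta, "method": "S-TWAS.B", "power": float(max(_pw(ptwas[:, k]) for k in range(config.K)))})
        rows.append({**meta, "method": "S-PrediXcan.B", "power": float(max(_pw(ppred[:, k]) for k in range(config.K)))})
        df = pd.DataFrame(rows)
        df["se"] = np.sqrt(df["power"] * (1 - df["power"]) / n_rep)
        df["n_rep"] = n_rep
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
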
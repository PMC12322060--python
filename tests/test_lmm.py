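"""Mixed-model engine: GLS oracles, variance-component recovery, q-values and
eGene calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sceqtl import (
    KinshipMatrix,
    call_egenes,
    fit_null_lmm,
    map_cis,
    permutation_pass,
    qvalues,
    rank_inverse_normal,
    simulate_genotypes,
)
from sceqtl.lmm import _gls_scan


def _identity_K(n):
    return KinshipMatrix(ids=np.array([f"s{i}" for i in range(n)], dtype=object),
                         values=np.eye(n))


class TestNullFit:
    def test_identity_kinship_pins_h2_zero_and_matches_ols(self):
        rng = np.random.default_rng(0)
        n = 30
        y = rng.standard_normal(n)
        g = rng.binomial(2, 0.3, n).astype(float)
        W = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fit = fit_null_lmm(y, W, _identity_K(n))
        assert fit.h2 == 0.0

        X = np.column_stack([W, g])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        df = n - X.shape[1]
        s2 = (r @ r) / df
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[-1, -1])
        p_ols = 2 * stats.t.sf(abs(beta[-1] / se), df)
        b, _, p = _gls_scan(y, W, g[:, None], fit.weights, df)
        assert p[0] == pytest.approx(p_ols, abs=1e-8)

    def test_gls_matches_dense_v_inverse_oracle(self):
        rng = np.random.default_rng(1)
        n = 30
        geno, _ = simulate_genotypes(n, 80, ld_rho=0.4, seed=2)
        from sceqtl import compute_grm

        K = compute_grm(geno)
        u = np.linalg.cholesky(0.6 * K.values + 0.4 * np.eye(n) + 1e-8 * np.eye(n))
        y = u @ rng.standard_normal(n)
        W = np.ones((n, 1))
        fit = fit_null_lmm(y, W, K)
        V = fit.sigma_g2 * K.values + fit.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        df = n - 2
        s, U = K.eig()
        yt, Wt = U.T @ y, U.T @ W
        for j in (0, 7, 40):
            g = geno.dosages[:, j]
            X = np.column_stack([W, g])
            bet = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ bet
            s2 = (r @ Vi @ r) / df
            se = np.sqrt(s2 * np.linalg.inv(X.T @ Vi @ X)[-1, -1])
            p_oracle = 2 * stats.t.sf(abs(bet[-1] / se), df)
            b, _, p = _gls_scan(yt, Wt, (U.T @ g)[:, None], fit.weights, df)
            assert b[0] == pytest.approx(bet[-1], abs=1e-8)
            assert p[0] == pytest.approx(p_oracle, abs=1e-8)

    def test_h2_recovery_with_block_kinship(self):
        # equal genetic and residual variance: h2_hat near 0.5
        rng = np.random.default_rng(3)
        n, d = 300, 75
        Z = np.zeros((n, d))
        Z[np.arange(n), np.repeat(np.arange(d), 4)] = 1.0
        K = KinshipMatrix(ids=np.array([f"s{i}" for i in range(n)], dtype=object),
                          values=Z @ Z.T)
        hits = 0
        for s in range(60):
            rs = np.random.default_rng(s)
            y = Z @ rs.standard_normal(d) + rs.standard_normal(n)
            fit = fit_null_lmm(y, np.ones((n, 1)), K)
            hits += 0.3 <= fit.h2 <= 0.7
        assert hits >= 54  # >= 90%

    def test_intercept_shift_leaves_h2_unchanged(self):
        rng = np.random.default_rng(4)
        n = 50
        geno, _ = simulate_genotypes(n, 100, seed=5)
        from sceqtl import compute_grm

        K = compute_grm(geno)
        y = rng.standard_normal(n)
        W = np.ones((n, 1))
        assert fit_null_lmm(y, W, K).h2 == pytest.approx(
            fit_null_lmm(y + 7.3, W, K).h2, abs=1e-6)

    def test_singular_design_fatal(self):
        n = 20
        y = np.random.default_rng(6).standard_normal(n)
        W = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError):
            fit_null_lmm(y, W, _identity_K(n))


class TestMapCis:
    def test_window_inclusive_and_maf_strict(self):
        geno, _ = simulate_genotypes(60, 3, seed=7, start_pos=11_000_000, spacing=1)
        geno.variants.loc[1, "pos"] = 11_000_001
        geno.variants.loc[2, "pos"] = 11_500_000
        geno.variants.loc[2, "maf"] = 0.05   # exactly at the bound -> excluded
        ga = pd.DataFrame({"chrom": ["1"], "tss": [10_000_000]}, index=["gene"])
        donors = list(geno.donors)
        meta = pd.DataFrame({"donor": donors}, index=donors)
        expr = pd.DataFrame(
            {"gene": np.random.default_rng(8).standard_normal(60)}, index=donors)
        assoc = map_cis(expr, meta, ga, geno, None)
        tested = set(assoc["variant"])
        assert "rs1" in tested          # distance exactly 1 Mb: included
        assert "rs2" not in tested      # 1 Mb + 1: excluded
        assert "rs3" not in tested      # MAF == 0.05: excluded

    def test_p_consistent_with_beta_se_df(self, cis_geno, bg_kinship, null_cohort, gene_annot, sample_kinship):
        _, pb, _ = null_cohort
        expr, meta = pb.context("monocyte")
        assoc = map_cis(expr.iloc[:, :10], meta, gene_annot, cis_geno[0], sample_kinship)
        t = (assoc["beta"] / assoc["se"]).abs()
        p = 2 * stats.t.sf(t, assoc["df"])
        assert np.allclose(p, assoc["p"], atol=1e-8)

    def test_rank_int_is_odd_and_gaussian(self):
        y = np.random.default_rng(9).exponential(size=101)
        z = rank_inverse_normal(y)
        assert np.allclose(np.sort(z), -np.sort(-z)[::-1], atol=1e-12)
        assert abs(z.mean()) < 1e-12


class TestPermutationPass:
    def test_strong_signal_floor_and_determinism(self, cis_geno, gene_annot, null_cohort, sample_kinship):
        geno, _ = cis_geno
        _, pb, _ = null_cohort
        expr, meta = pb.context("monocyte")
        expr = expr.iloc[:, :3].copy()
        # plant an overwhelming signal on the first gene
        didx = {d: i for i, d in enumerate(geno.donors)}
        g = np.array([geno.dosages[didx[d], 10] for d in meta["donor"]])
        expr.iloc[:, 0] = g + 0.01 * np.random.default_rng(1).standard_normal(len(g))
        perm = permutation_pass(expr, meta, gene_annot, geno, sample_kinship,
                                B=100, seed=5)
        row = perm[perm["gene"] == expr.columns[0]].iloc[0]
        assert row["p_emp"] == pytest.approx(1 / 101)
        perm2 = permutation_pass(expr, meta, gene_annot, geno, sample_kinship,
                                 B=100, seed=5)
        pd.testing.assert_frame_equal(perm, perm2)

    def test_different_seed_small_jitter_for_strong_gene(self, cis_geno, gene_annot, null_cohort, sample_kinship):
        geno, _ = cis_geno
        _, pb, _ = null_cohort
        expr, meta = pb.context("monocyte")
        expr = expr.iloc[:, :1].copy()
        didx = {d: i for i, d in enumerate(geno.donors)}
        g = np.array([geno.dosages[didx[d], 10] for d in meta["donor"]])
        expr.iloc[:, 0] = g + 0.5 * np.random.default_rng(2).standard_normal(len(g))
        a = permutation_pass(expr, meta, gene_annot, geno, sample_kinship, B=150, seed=1)
        b = permutation_pass(expr, meta, gene_annot, geno, sample_kinship, B=150, seed=2)
        assert abs(a["p_emp"].iloc[0] - b["p_emp"].iloc[0]) <= 5 / 151


class TestQvalues:
    def test_all_ones(self):
        assert np.allclose(qvalues(np.ones(10)), 1.0)

    def test_bh_hand_computation_with_forced_pi0(self):
        q = qvalues(np.array([0.01, 0.04]), pi0=1.0)
        assert np.allclose(q, [0.02, 0.04])

    def test_order_preserving_and_bounded(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(5, 200))
            q = qvalues(p)
            assert (q <= 1 + 1e-12).all() and (q > 0).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()


class TestCallEgenes:
    def _inputs(self):
        perm = pd.DataFrame({
            "gene": ["a", "b", "c"],
            "p_obs": [1e-6, 1e-5, 0.4],
            "p_emp": [0.001, 0.002, 0.9],
            "n_perm": 1000, "seed": 0,
        })
        assoc = pd.DataFrame({
            "gene": ["a"] * 3 + ["b"] * 3 + ["c"] * 2,
            "variant": [f"v{i}" for i in range(8)],
            "pos": range(8),
            "beta": 0.1, "se": 0.05,
            "p": [1e-6, 5e-6, 0.2, 1e-5, 2e-5, 0.5, 0.4, 0.9],
        })
        return perm, assoc

    def test_max_top_p_rule_defines_evariants(self):
        perm, assoc = self._inputs()
        cs = call_egenes(perm, assoc, q_threshold=0.05)
        assert set(cs.egenes["gene"]) == {"a", "b"}
        assert cs.nominal_threshold == pytest.approx(1e-5)
        # the 1e-5 cutoff applies to both eGenes; gene c contributes nothing
        assert set(cs.evariants["variant"]) == {"v0", "v1", "v3"}

    def test_nonsignificant_gene_does_not_move_cutoff(self):
        perm, assoc = self._inputs()
        perm.loc[2, "p_emp"] = 0.9  # stays out even with small nominal p
        assoc.loc[assoc["gene"] == "c", "p"] = 1e-9
        cs = call_egenes(perm, assoc)
        assert "c" not in set(cs.egenes["gene"])
        assert cs.nominal_threshold == pytest.approx(1e-5)

    def test_empty_call_set_valid(self):
        perm, assoc = self._inputs()
        perm["p_emp"] = [0.5, 0.6, 0.9]
        cs = call_egenes(perm, assoc)
        assert len(cs.egenes) == 0 and len(cs.evariants) == 0
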
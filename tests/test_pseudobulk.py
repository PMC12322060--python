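"""Cell QC, pseudobulk aggregation, latent factors, DE and module scores."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sceqtl import (
    differential_expression,
    latent_factors,
    module_score,
    pathway_correlation,
    pseudobulk_aggregate,
    qc_and_normalize,
)


def _adata(X, donors=None, conditions=None, cell_types=None, mito=None):
    X = np.asarray(X)
    n, g = X.shape
    obs = pd.DataFrame({
        "donor": donors or ["d0"] * n,
        "condition": conditions or ["T0-RPMI"] * n,
        "cell_type": cell_types or ["monocyte"] * n,
    }, index=[f"c{i}" for i in range(n)])
    var = pd.DataFrame({"mito": mito if mito is not None else [False] * g},
                       index=[f"g{i}" for i in range(g)])
    return ad.AnnData(X=X.astype(np.int32), obs=obs, var=var)


class TestQcNormalize:
    def test_mito_threshold_boundary(self):
        # 26% mito removed, 25% kept (rule is "> 25%")
        X = np.array([[26, 74], [25, 75], [10, 90]])
        cells = _adata(X, mito=[True, False])
        out = qc_and_normalize(cells, min_genes=1)
        assert out.n_obs == 2

    def test_detected_gene_boundaries(self):
        X = np.zeros((3, 150), dtype=int)
        X[0, :100] = 1   # exactly 100 detected -> kept
        X[1, :99] = 1    # 99 -> removed
        X[2, :120] = 1
        out = qc_and_normalize(_adata(X))
        assert out.n_obs == 2

    def test_normalized_value_formula(self):
        # counts {1,1}, total 2, scale 1e4 -> both ln(1 + 5000)
        out = qc_and_normalize(_adata(np.array([[1, 1]])), min_genes=1)
        assert np.allclose(out.layers["lognorm"], np.log(1 + 5000))

    def test_all_removed_fatal(self):
        with pytest.raises(ValueError):
            qc_and_normalize(_adata(np.array([[1, 1]])), min_genes=10)


class TestPseudobulk:
    def test_mean_of_two_cells(self):
        cells = _adata(np.array([[1, 0], [3, 0]]))
        cells.layers["lognorm"] = np.array([[1.0, 0.0], [3.0, 0.0]])
        pb = pseudobulk_aggregate(cells, min_donor_frac=0.0)
        assert pb.expr.iloc[0, 0] == 2.0

    def test_donor_fraction_filter_boundary(self):
        # gene nonzero in exactly 30% of 10 donors retained; 29%-like (2/10) dropped
        n_donors = 10
        rows, donors = [], []
        for d in range(n_donors):
            rows.append([1 if d < 3 else 0, 1 if d < 2 else 0, 5])
            donors.append(f"d{d}")
        cells = _adata(np.array(rows), donors=donors)
        cells.layers["lognorm"] = np.array(rows, dtype=float)
        pb = pseudobulk_aggregate(cells, min_donor_frac=0.30)
        kept = pb.retained["monocyte"]
        assert "g0" in kept and "g2" in kept and "g1" not in kept

    def test_matches_groupby_loop_oracle(self, null_cohort):
        cells, pb, _ = null_cohort
        L = np.asarray(cells.layers["lognorm"])
        obs = cells.obs
        for sample in pb.expr.index[:5]:
            d, c, ct = sample.split("|")
            mask = ((obs["donor"] == d) & (obs["condition"] == c)
                    & (obs["cell_type"] == ct)).to_numpy()
            assert np.allclose(pb.expr.loc[sample], L[mask].mean(axis=0))

    def test_zero_cell_samples_absent(self, null_cohort):
        _, pb, _ = null_cohort
        assert (pb.meta["n_cells"] > 0).all()


class TestLatentFactors:
    def test_orthonormal_standardized(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((30, 50)))
        out = latent_factors(expr, None, k=5)
        F = out[[f"factor{i+1}" for i in range(5)]].to_numpy()
        assert np.allclose(F.mean(0), 0, atol=1e-8)
        assert np.allclose(F.std(0), 1, atol=1e-8)
        C = F.T @ F / 30
        assert np.allclose(C - np.diag(np.diag(C)), 0, atol=1e-8)

    def test_planted_batch_captured_by_first_factor(self):
        rng = np.random.default_rng(1)
        expr = rng.standard_normal((40, 80))
        batch = np.repeat([0.0, 1.0], 20)
        expr += np.outer(batch, np.full(80, 3.0))
        out = latent_factors(pd.DataFrame(expr), None, k=3)
        r = np.corrcoef(out["factor1"], batch)[0, 1]
        assert abs(r) > 0.9

    def test_k_too_large_fatal(self):
        expr = pd.DataFrame(np.random.default_rng(2).standard_normal((4, 10)))
        with pytest.raises(ValueError):
            latent_factors(expr, None, k=4)


class TestDifferentialExpression:
    def _cells(self, A, B):
        X = np.vstack([A, B])
        cells = _adata(X)
        tot = X.sum(1, keepdims=True).clip(min=1)
        cells.layers["lognorm"] = np.log1p(X * 1e4 / tot)
        return cells, np.arange(len(A)), len(A) + np.arange(len(B))

    def test_identical_groups_null(self):
        rng = np.random.default_rng(3)
        A = rng.poisson(5, (50, 10))
        cells, ia, ib = self._cells(A, A)
        table, sig = differential_expression(cells, ia, ib)
        assert np.allclose(table["log2fc"], 0)
        assert sig == []

    def test_planted_twofold_shift_recovered(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(20, (200, 20))
        shifted = base.copy()
        found = 0
        for s in range(20):
            A = rng.poisson(40, (200, 1))
            B = rng.poisson(20, (200, 1))
            bgA = rng.poisson(20, (200, 19))
            bgB = rng.poisson(20, (200, 19))
            cells, ia, ib = self._cells(np.hstack([A, bgA]), np.hstack([B, bgB]))
            _, sig = differential_expression(cells, ia, ib)
            found += "g0" in sig
        assert found >= 19

    def test_lfc_threshold_excludes_small_shifts(self):
        rng = np.random.default_rng(5)
        # large n makes a ~7% shift significant but below the 0.15 log2FC bound
        A = rng.poisson(64, (3000, 2))
        B = rng.poisson(60, (3000, 2))
        cells, ia, ib = self._cells(A, B)
        table, sig = differential_expression(cells, ia, ib)
        small = table[(table["p_adj"] < 0.05) & (table["log2fc"].abs() <= 0.15)]
        assert all(g not in sig for g in small["gene"])

    def test_small_group_fatal(self):
        rng = np.random.default_rng(6)
        cells, ia, ib = self._cells(rng.poisson(5, (2, 4)), rng.poisson(5, (10, 4)))
        with pytest.raises(ValueError):
            differential_expression(cells, ia, ib)

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(7)
        cells, ia, ib = self._cells(rng.poisson(8, (40, 30)), rng.poisson(9, (40, 30)))
        table, _ = differential_expression(cells, ia, ib)
        t = table.sort_values("p")
        assert (t["p_adj"].diff().dropna() >= -1e-12).all()
        assert (t["p_adj"] >= t["p"] - 1e-12).all()


class TestModuleScore:
    def _cells(self, n=200, g=120, seed=8):
        rng = np.random.default_rng(seed)
        X = rng.poisson(5, (n, g))
        cells = _adata(X, donors=[f"d{i % 10}" for i in range(n)])
        cells.layers["lognorm"] = np.log1p(X.astype(float))
        return cells

    def test_same_seed_reproducible(self):
        cells = self._cells()
        s1 = module_score(cells, ["g0", "g1", "g2"], seed=5)
        s2 = module_score(cells, ["g0", "g1", "g2"], seed=5)
        assert s1.equals(s2)

    def test_random_set_score_centered(self):
        cells = self._cells()
        rng = np.random.default_rng(9)
        means = []
        for i in range(100):
            gs = list(rng.choice(cells.var_names, 8, replace=False))
            means.append(module_score(cells, gs, seed=i).mean())
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-3

    def test_spiked_cells_score_positive(self):
        # heterogeneous gene means so the set genes share bins with controls
        rng = np.random.default_rng(20)
        rates = rng.uniform(1, 20, 300)
        X = rng.poisson(rates, (200, 300))
        cells = _adata(X)
        L = np.log1p(X.astype(float))
        gene_set = [f"g{i}" for i in range(100, 110)]
        L[:100, 100:110] += 0.5  # spike the set in half the cells
        cells.layers["lognorm"] = L
        s = module_score(cells, gene_set, seed=1)
        assert s.iloc[:100].mean() > s.iloc[100:].mean() + 0.1

    def test_empty_set_fatal(self):
        with pytest.raises(ValueError):
            module_score(self._cells(), [])


class TestPathwayCorrelation:
    def test_null_count_and_self_correlation(self):
        cells = TestModuleScore()._cells(n=300, g=60)
        sc = module_score(cells, ["g0", "g1", "g2"], seed=0)
        donor_score = sc.groupby(cells.obs["donor"].to_numpy()).mean()
        res = pathway_correlation(cells, ["g0", "g1", "g2"], donor_score,
                                  n_null_sets=50, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert len(res["null_r"]) == 50

    def test_zero_variance_signal_fatal(self):
        cells = TestModuleScore()._cells()
        sig = pd.Series(1.0, index=[f"d{i}" for i in range(10)])
        with pytest.raises(ValueError):
            pathway_correlation(cells, ["g0"], sig, n_null_sets=5, seed=0)
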
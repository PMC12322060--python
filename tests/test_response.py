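"""Genotype-by-condition interaction tests, two-step response calling and
trained-immunity fold-change QTLs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sceqtl import (
    CONTRASTS,
    KinshipMatrix,
    Pseudobulk,
    compute_grm,
    expand_kinship,
    map_cis,
    map_response,
    map_ti,
    simulate_genotypes,
    ti_fold_change,
)
from sceqtl import test_interaction as interaction_wald  # avoid pytest collection


def _identity_K(ids):
    return KinshipMatrix(ids=np.asarray(ids, dtype=object), values=np.eye(len(ids)))


class TestInteraction:
    def test_label_swap_flips_tau_exactly(self):
        rng = np.random.default_rng(0)
        n = 60
        g = np.repeat(rng.binomial(2, 0.3, n // 2), 2).astype(float)
        c = np.tile([0.0, 1.0], n // 2)
        y = 0.3 * g + 0.8 * g * c + rng.standard_normal(n)
        K = _identity_K([f"s{i}" for i in range(n)])
        a = interaction_wald(y, None, K, g, c)
        b = interaction_wald(y, None, K, g, 1 - c)
        assert a["beta"] == pytest.approx(-b["beta"], abs=1e-10)
        assert a["p"] == pytest.approx(b["p"], abs=1e-10)

    def test_constant_condition_fatal(self):
        n = 20
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            interaction_wald(rng.standard_normal(n), None,
                             _identity_K([f"s{i}" for i in range(n)]),
                             rng.binomial(2, 0.3, n).astype(float), np.zeros(n))

    def test_null_interaction_p_uniform_with_shared_additive_effect(self):
        # additive effect equal in both conditions: interaction p stays uniform
        rng = np.random.default_rng(2)
        n_donors = 60
        ps = []
        K = _identity_K([f"s{i}" for i in range(2 * n_donors)])
        for _ in range(200):
            g_d = rng.binomial(2, 0.3, n_donors).astype(float)
            g = np.repeat(g_d, 2)
            c = np.tile([0.0, 1.0], n_donors)
            y = 0.5 * g + rng.standard_normal(2 * n_donors)
            ps.append(interaction_wald(y, None, K, g, c)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def _response_cohort(tau=0.0, beta_both=0.0, beta_stim=0.0, n_donors=40,
                     n_genes=8, seed=3):
    """Pseudobulk fixture for one cell type over the LPS contrast."""
    rng = np.random.default_rng(seed)
    geno, _ = simulate_genotypes(n_donors, 60, ld_rho=0.4, seed=seed + 100)
    donors = list(geno.donors)
    samples, rows = [], []
    conds = ["T0-RPMI", "T0-LPS"]
    for d in donors:
        for c in conds:
            samples.append(f"{d}|{c}")
            rows.append((d, c, "monocyte", 20))
    meta = pd.DataFrame(rows, index=samples,
                        columns=["donor", "condition", "cell_type", "n_cells"])
    genes = [f"g{i}" for i in range(n_genes)]
    ga = pd.DataFrame({"chrom": "1",
                       "tss": np.linspace(1.0e6, 1.3e6, n_genes).astype(int)},
                      index=genes)
    stim = (meta["condition"] == "T0-LPS").to_numpy(float)
    didx = {d: i for i, d in enumerate(donors)}
    expr = pd.DataFrame(0.3 * rng.standard_normal((len(samples), n_genes)),
                        index=samples, columns=genes)
    cis_variant = {}
    for gi, gene in enumerate(genes):
        j = int(np.argmin(np.abs(geno.variants["pos"] - ga.loc[gene, "tss"])))
        cis_variant[gene] = geno.variants.at[j, "rsid"]
        g = np.array([geno.dosages[didx[s.split("|")[0]], j] for s in samples])
        expr[gene] += beta_both * g + beta_stim * g * stim + tau * g * stim
    return geno, Pseudobulk(expr=expr, meta=meta,
                            retained={"monocyte": genes}), ga, cis_variant


class TestMapResponse:
    def test_stim_only_effect_called(self):
        geno, pb, ga, _ = _response_cohort(beta_stim=0.8)
        Kd = compute_grm(geno)
        out = map_response(pb, ga, geno, Kd, CONTRASTS["LPS"], "monocyte",
                           transform="none")
        assert out["response_eqtl"].sum() >= 6  # most of 8 planted genes

    def test_shared_effect_not_called(self):
        geno, pb, ga, _ = _response_cohort(beta_both=0.8)
        Kd = compute_grm(geno)
        out = map_response(pb, ga, geno, Kd, CONTRASTS["LPS"], "monocyte",
                           transform="none")
        assert out["response_eqtl"].sum() == 0

    def test_global_null_false_call_rate(self):
        geno, pb, ga, _ = _response_cohort(n_genes=60, seed=5)
        Kd = compute_grm(geno)
        out = map_response(pb, ga, geno, Kd, CONTRASTS["LPS"], "monocyte",
                           transform="none")
        frac = out["response_eqtl"].mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(out))

    def test_step2_matches_map_cis_on_subset(self):
        geno, pb, ga, cis = _response_cohort(beta_stim=0.8, seed=7)
        Kd = compute_grm(geno)
        out = map_response(pb, ga, geno, Kd, CONTRASTS["LPS"], "monocyte",
                           transform="none")
        cand = out[out["candidate"]].iloc[0]
        expr, meta = pb.context("monocyte")
        msub = meta[meta["condition"] == "T0-LPS"]
        sub = map_cis(expr.loc[msub.index, [cand["gene"]]], msub, ga, geno,
                      expand_kinship(Kd, msub["donor"]), None, transform="none")
        row = sub[sub["variant"] == cand["variant"]].iloc[0]
        assert cand["p_stim"] == pytest.approx(row["p"], rel=1e-10)

    def test_baseline_significance_vetoes_call(self):
        # strong in both arms, slightly stronger on stimulation: interaction
        # can pass but the baseline arm is significant, vetoing the call
        geno, pb, ga, _ = _response_cohort(beta_both=0.6, beta_stim=0.6, seed=9)
        Kd = compute_grm(geno)
        out = map_response(pb, ga, geno, Kd, CONTRASTS["LPS"], "monocyte",
                           transform="none")
        called = out[out["response_eqtl"]]
        assert (called["p_baseline"] >= 0.05).all()
        assert len(called) == 0


class TestTi:
    def test_fold_change_formula(self):
        samples = ["d0|T3m-LPS", "d0|T0-LPS"]
        meta = pd.DataFrame(
            {"donor": ["d0", "d0"], "condition": ["T3m-LPS", "T0-LPS"],
             "cell_type": ["monocyte"] * 2, "n_cells": 5},
            index=samples)
        expr = pd.DataFrame({"g0": [3.0, 1.0]}, index=samples)
        pb = Pseudobulk(expr=expr, meta=meta, retained={"monocyte": ["g0"]})
        fc = ti_fold_change(pb, scale="log")
        assert fc.loc["d0", "g0"] == pytest.approx(1.0)  # log2(4/2)

    def _ti_cohort(self, effect=0.0, n_donors=100, n_genes=6, seed=11):
        rng = np.random.default_rng(seed)
        geno, _ = simulate_genotypes(n_donors, 40, ld_rho=0.5,
                                     maf_range=(0.3, 0.5), seed=seed + 50)
        donors = list(geno.donors)
        genes = [f"g{i}" for i in range(n_genes)]
        ga = pd.DataFrame({"chrom": "1",
                           "tss": np.linspace(1.0e6, 1.2e6, n_genes).astype(int)},
                          index=genes)
        rows, samples = [], []
        for d in donors:
            for c in ("T0-LPS", "T3m-LPS"):
                samples.append(f"{d}|{c}")
                rows.append((d, c, "monocyte", 20))
        meta = pd.DataFrame(rows, index=samples,
                            columns=["donor", "condition", "cell_type", "n_cells"])
        expr = pd.DataFrame(rng.uniform(1, 2, (len(samples), n_genes)),
                            index=samples, columns=genes)
        didx = {d: i for i, d in enumerate(donors)}
        after = meta["condition"].eq("T3m-LPS").to_numpy(float)
        for gi, gene in enumerate(genes):
            j = int(np.argmin(np.abs(geno.variants["pos"] - ga.loc[gene, "tss"])))
            g = np.array([geno.dosages[didx[s.split("|")[0]], j] for s in samples])
            # allele shifts the post/pre fold change
            expr[gene] = expr[gene] * 2 ** (effect * g * after)
        return geno, Pseudobulk(expr=expr, meta=meta, retained={"monocyte": genes}), ga

    def test_antisymmetry_under_visit_swap(self):
        geno, pb, ga = self._ti_cohort(effect=0.4, n_donors=40)
        Kd = compute_grm(geno)
        a, _ = map_ti(pb, list(pb.retained["monocyte"]), ga, geno, Kd)
        # swap the visits by relabeling conditions
        pb2 = Pseudobulk(expr=pb.expr.copy(), meta=pb.meta.copy(),
                         retained=pb.retained)
        pb2.meta["condition"] = pb2.meta["condition"].map(
            {"T0-LPS": "T3m-LPS", "T3m-LPS": "T0-LPS"})
        b, _ = map_ti(pb2, list(pb.retained["monocyte"]), ga, geno, Kd)
        m = a.merge(b, on=["gene", "variant"], suffixes=("_a", "_b"))
        # FC is exactly antisymmetric under the visit swap, so betas flip sign
        assert np.allclose(m["beta_a"], -m["beta_b"], atol=1e-10)
        assert np.allclose(m["p_a"], m["p_b"], atol=1e-10)

    def test_planted_fc_qtl_recovered(self):
        geno, pb, ga = self._ti_cohort(effect=0.3)
        Kd = compute_grm(geno)
        _, sig = map_ti(pb, list(pb.retained["monocyte"]), ga, geno, Kd)
        assert len(set(sig["gene"])) >= 5  # of 6 planted

    def test_too_few_donors_fatal(self):
        geno, pb, ga = self._ti_cohort(n_donors=8, seed=13)
        with pytest.raises(ValueError):
            map_ti(pb, list(pb.retained["monocyte"]), ga, geno, compute_grm(geno))
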
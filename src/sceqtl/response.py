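"""Response (genotype x condition) eQTLs and trained-immunity fold-change QTLs.

A response eQTL is a genetic effect on expression that differs between a
baseline and a stimulated condition.  Calling follows a two-step procedure:
step 1 screens genes on the GxC interaction term of the mixed model; step 2
re-estimates the additive effect separately in the two conditions and keeps
pairs that are significant upon stimulation but not at baseline.

Trained-immunity (TI) QTLs associate genotype with the per-donor log2 fold
change of monocyte expression between the post-vaccination and
pre-vaccination LPS responses, over the panel of TI-response genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotype import GenotypeMatrix, KinshipMatrix, expand_kinship
from .lmm import _CisWorkspace, _fit_rotated, map_cis, qvalues
from .pseudobulk import Pseudobulk

logger = logging.getLogger("sceqtl")

__all__ = [
    "ContrastSpec",
    "CONTRASTS",
    "test_interaction",
    "map_response",
    "ti_fold_change",
    "map_ti",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A baseline/stimulated condition pair for response-eQTL mapping."""

    name: str
    baseline: str
    stimulated: str


CONTRASTS = {
    "BCG": ContrastSpec("BCG", "T0-RPMI", "T3m-RPMI"),
    "LPS": ContrastSpec("LPS", "T0-RPMI", "T0-LPS"),
    "LPS_postBCG": ContrastSpec("LPS_postBCG", "T3m-RPMI", "T3m-LPS"),
}


# ---------------------------------------------------------------------------
# interaction Wald test
# ---------------------------------------------------------------------------

def test_interaction(
    y: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
    dosage: np.ndarray,
    condition_indicator: np.ndarray,
) -> dict:
    """Wald test of the genotype x condition coefficient.

    Fixed effects: intercept + covariates + condition + dosage +
    dosage*condition; variance components from the null model (intercept +
    covariates + condition) are held fixed for the test.
    """
    y = np.asarray(y, float)
    g = np.asarray(dosage, float)
    c = np.asarray(condition_indicator, float)
    if np.all(c == c[0]):
        raise ValueError("condition indicator is constant")
    n = len(y)
    base = [np.ones(n)]
    if covariates is not None and np.size(covariates):
        base.append(np.asarray(covariates, float).reshape(n, -1))
    base.append(c[:, None])
    Wnull = np.column_stack(base)

    s, U = kinship.eig()
    yt = U.T @ y
    fit = _fit_rotated(yt, U.T @ Wnull, s)
    w = fit.weights
    sw = np.sqrt(w)

    X = np.column_stack([Wnull, g, g * c])
    Xw = (U.T @ X) * sw[:, None]
    yw = yt * sw
    XtX = Xw.T @ Xw
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        raise ValueError("singular interaction design (dosage constant?)")
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    tau = float(beta[-1])
    se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
    t = tau / se
    p = float(2 * stats.t.sf(abs(t), df))
    return {"beta": tau, "se": se, "p": p, "df": df, "term": "interaction", "h2": fit.h2}


# ---------------------------------------------------------------------------
# two-step response-eQTL mapping
# ---------------------------------------------------------------------------

def map_response(
    pseudobulk: Pseudobulk,
    gene_annot: pd.DataFrame,
    geno: GenotypeMatrix,
    K_donor: KinshipMatrix,
    contrast: ContrastSpec,
    cell_type: str,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    maf: float = 0.05,
    q: float = 0.05,
    raw_p: float = 5e-6,
    baseline_p: float = 0.05,
    transform: str = "int",
) -> pd.DataFrame:
    """Two-step response-eQTL calls for one contrast in one cell type.

    Step 1: per gene, the minimum interaction p over cis variants,
    Bonferroni-corrected by the tested-variant count, then Storey q across
    genes; candidates pass q < ``q`` OR raw min p < ``raw_p``.  Step 2: the
    candidate variant's additive effect is re-fit separately in the two
    conditions; the pair is a response eQTL iff the stimulated-condition p
    passes the step-1 thresholds and the baseline p >= ``baseline_p``.
    Donors missing one arm of the contrast are dropped listwise.
    """
    expr_all, meta_all = pseudobulk.context(cell_type)
    use = meta_all["condition"].isin([contrast.baseline, contrast.stimulated])
    meta = meta_all[use]
    # listwise-complete donors only
    per_donor = meta.groupby("donor")["condition"].nunique()
    complete = per_donor[per_donor == 2].index
    dropped = sorted(set(meta["donor"]) - set(complete))
    if dropped:
        logger.info("map_response[%s]: dropped %d incomplete donors", contrast.name, len(dropped))
    meta = meta[meta["donor"].isin(complete)]
    expr = expr_all.loc[meta.index]
    if meta.empty:
        raise ValueError(f"no complete donors for contrast {contrast.name}")

    K_samples = expand_kinship(K_donor, meta["donor"])
    ws = _CisWorkspace(expr, meta, gene_annot, geno, K_samples, covariates,
                       window, maf, transform)
    cond = (meta["condition"] == contrast.stimulated).to_numpy(float)
    donor_dos = geno.dosages[ws.donor_idx]

    cov_arr = None
    if covariates is not None:
        cov_arr = covariates.loc[meta.index].to_numpy(float)

    step1 = []
    for gene in expr.columns:
        idx = ws.cis.get(gene)
        if idx is None or len(idx) == 0:
            continue
        y = ws.phenotype(gene)
        best = None
        for j in idx:
            g = donor_dos[:, j]
            if np.std(g) == 0:
                continue
            r = test_interaction(y, cov_arr, K_samples, g, cond)
            if best is None or r["p"] < best[1]["p"]:
                best = (j, r)
        if best is None:
            continue
        j, r = best
        step1.append({
            "gene": gene,
            "variant": geno.variants.at[int(j), "rsid"],
            "tau": r["beta"],
            "tau_se": r["se"],
            "interaction_p": r["p"],
            "n_tested": int(len(idx)),
        })
    s1 = pd.DataFrame(step1)
    if s1.empty:
        return s1
    s1["p_bonf"] = np.minimum(1.0, s1["interaction_p"] * s1["n_tested"])
    s1["q_step1"] = qvalues(s1["p_bonf"].to_numpy())
    s1["candidate"] = (s1["q_step1"] < q) | (s1["interaction_p"] < raw_p)

    # step 2: per-condition additive fits via the standard cis scan
    cand = s1[s1["candidate"]]
    per_cond = {}
    for cname in (contrast.baseline, contrast.stimulated):
        msub = meta[meta["condition"] == cname]
        esub = expr.loc[msub.index, list(cand["gene"])] if len(cand) else None
        if esub is not None and len(cand):
            per_cond[cname] = map_cis(
                esub, msub, gene_annot, geno,
                expand_kinship(K_donor, msub["donor"]),
                covariates.loc[msub.index] if covariates is not None else None,
                window, maf, transform, context=cname,
            )

    def _pair_stats(cname, gene, variant):
        tab = per_cond.get(cname)
        if tab is None:
            return np.nan, np.nan
        row = tab[(tab["gene"] == gene) & (tab["variant"] == variant)]
        if row.empty:
            return np.nan, np.nan
        return float(row["beta"].iloc[0]), float(row["p"].iloc[0])

    out = s1.copy()
    out["beta_baseline"] = np.nan
    out["p_baseline"] = np.nan
    out["beta_stim"] = np.nan
    out["p_stim"] = np.nan
    for i in out.index[out["candidate"]]:
        gene, variant = out.at[i, "gene"], out.at[i, "variant"]
        out.loc[i, ["beta_baseline", "p_baseline"]] = _pair_stats(contrast.baseline, gene, variant)
        out.loc[i, ["beta_stim", "p_stim"]] = _pair_stats(contrast.stimulated, gene, variant)

    cand_mask = out["candidate"] & out["p_stim"].notna()
    stim_p = out.loc[cand_mask, "p_stim"].to_numpy()
    stim_bonf = np.minimum(1.0, stim_p * out.loc[cand_mask, "n_tested"].to_numpy())
    stim_pass = np.zeros(len(out), bool)
    if cand_mask.any():
        qs = qvalues(stim_bonf)
        stim_pass[np.flatnonzero(cand_mask.to_numpy())] = (qs < q) | (stim_p < raw_p)
    out["response_eqtl"] = (
        stim_pass & (out["p_baseline"] >= baseline_p).to_numpy()
    )
    out["contrast"] = contrast.name
    out["cell_type"] = cell_type
    return out


# ---------------------------------------------------------------------------
# trained-immunity fold-change QTLs
# ---------------------------------------------------------------------------

def ti_fold_change(
    pseudobulk: Pseudobulk,
    genes: list[str] | None = None,
    cell_type: str = "monocyte",
    after: str = "T3m-LPS",
    before: str = "T0-LPS",
    scale: str = "linear",
) -> pd.DataFrame:
    """Per-donor log2((pseudobulk_after + 1)/(pseudobulk_before + 1)).

    Defined only for donors with both LPS samples present.  With
    ``scale='linear'`` (default) the stored log-normalized pseudobulk means
    are de-logged (expm1) before the ratio, so the fold change is on the
    expression scale; ``scale='log'`` applies the formula to the stored
    values as-is.
    """
    expr, meta = pseudobulk.context(cell_type)
    if genes is not None:
        genes = [g for g in genes if g in expr.columns]
        expr = expr[genes]
    if scale == "linear":
        expr = np.expm1(expr)
    elif scale != "log":
        raise ValueError(f"unknown scale {scale!r}")
    pieces = {}
    for cond in (after, before):
        m = meta[meta["condition"] == cond]
        pieces[cond] = expr.loc[m.index].set_index(m["donor"].to_numpy())
    common = pieces[after].index.intersection(pieces[before].index)
    fc = np.log2((pieces[after].loc[common] + 1) / (pieces[before].loc[common] + 1))
    fc.index.name = "donor"
    return fc


def map_ti(
    pseudobulk: Pseudobulk,
    ti_gene_set: list[str],
    gene_annot: pd.DataFrame,
    geno: GenotypeMatrix,
    K_donor: KinshipMatrix,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    maf: float = 0.05,
    alpha: float = 0.05,
    cell_type: str = "monocyte",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TI eQTLs: donor-level fold-change phenotypes against cis variants.

    The phenotype is the per-donor log2 FC of each TI-response gene between
    the post- and pre-vaccination LPS conditions; the LMM uses the donor
    kinship with age and sex as covariates, and BH adjustment across all
    tested gene x variant pairs defines the significant set.
    """
    fc = ti_fold_change(pseudobulk, ti_gene_set, cell_type)
    if len(fc) < 10:
        raise ValueError(f"only {len(fc)} donors with both LPS visits (need >= 10)")
    donors = list(fc.index)
    meta = pd.DataFrame({"donor": donors}, index=fc.index)
    cov = covariates.loc[donors] if covariates is not None else None
    K = KinshipMatrix(
        ids=np.asarray(donors, dtype=object),
        values=expand_kinship(K_donor, meta["donor"]).values,
    )
    assoc = map_cis(fc, meta, gene_annot, geno, K, cov, window, maf,
                    transform="none", context=f"TI:{cell_type}")
    if assoc.empty:
        return assoc, assoc
    assoc = assoc.copy()
    assoc["p_adj"] = multipletests(assoc["p"].to_numpy(), method="fdr_bh")[1]
    sig = assoc[assoc["p_adj"] < alpha].reset_index(drop=True)
    return assoc, sig
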
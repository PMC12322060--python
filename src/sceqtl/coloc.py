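"""Bayesian colocalization of eQTL and GWAS signals via approximate Bayes
factors (single-causal-variant configuration model, PP0..PP4)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger("sceqtl")

__all__ = ["ColocResult", "harmonize", "wakefield_labf", "coloc_posteriors", "coloc_scan"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ColocResult:
    locus: str
    n_variants: int
    pp: dict            # {"PP0": .., ..., "PP4": ..}
    priors: tuple       # (p1, p2, p12)
    labf: pd.DataFrame  # per-variant log-ABFs for both traits


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    eqtl_p_max: float = 0.5,
    drop_palindromic: bool = True,
) -> pd.DataFrame:
    """Match eQTL and GWAS variants and align effect alleles.

    eQTL rows need rsid (as 'variant'), beta, se, p and ref/alt alleles; the
    eQTL beta refers to the alt allele.  If the GWAS effect allele is the
    eQTL ref (directly or via strand complement) the eQTL beta is
    sign-flipped; strand-ambiguous A/T and C/G variants are dropped.  eQTL
    rows with p >= ``eqtl_p_max`` are excluded before matching.
    """
    e = eqtl[eqtl["p"] < eqtl_p_max].copy()
    e = e.rename(columns={"variant": "rsid"}) if "variant" in e.columns else e
    merged = e.merge(gwas, on="rsid", suffixes=("_eqtl", "_gwas"))
    rows = []
    dropped = {"palindromic": 0, "allele_mismatch": 0}
    for _, r in merged.iterrows():
        ref, alt = str(r["ref"]), str(r["alt"])
        ea, oa = str(r["effect_allele"]), str(r["other_allele"])
        if drop_palindromic and _is_palindromic(ref, alt):
            dropped["palindromic"] += 1
            continue
        flip = None
        if (ea, oa) in {(alt, ref)} or (ea, oa) == (_COMPLEMENT.get(alt), _COMPLEMENT.get(ref)):
            flip = False
        elif (ea, oa) in {(ref, alt)} or (ea, oa) == (_COMPLEMENT.get(ref), _COMPLEMENT.get(alt)):
            flip = True
        if flip is None:
            dropped["allele_mismatch"] += 1
            continue
        rows.append({
            "rsid": r["rsid"],
            "beta_eqtl": -r["beta_eqtl"] if flip else r["beta_eqtl"],
            "se_eqtl": r["se_eqtl"],
            "beta_gwas": r["beta_gwas"],
            "se_gwas": r["se_gwas"],
            "flipped": flip,
        })
    if dropped["palindromic"] or dropped["allele_mismatch"]:
        logger.info("harmonize: dropped %s", dropped)
    out = pd.DataFrame(rows)
    if len(out) < 2:
        logger.info("harmonize: < 2 shared variants, locus unusable")
    return out


def wakefield_labf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Wakefield approximate log Bayes factor per variant.

    log ABF = 0.5 [ log(1 - r) + z^2 r ] with r = W/(W + se^2), W = prior_sd^2.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if (se <= 0).any():
        raise ValueError("nonpositive standard errors")
    z2 = (beta / se) ** 2
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * (np.log1p(-r) + z2 * r)


def coloc_posteriors(
    locus: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    sd_quant: float = 0.15,
    sd_cc: float = 0.2,
    trait_type_gwas: str = "quantitative",
    locus_id: str = "",
) -> ColocResult:
    """Posterior probabilities of the five sharing hypotheses.

    H0 no association; H1/H2 only trait 1/2; H3 both, distinct causal
    variants; H4 both, one shared causal variant.  Per-variant ABFs are
    summed over single-causal configurations in log space.
    """
    if len(locus) < 2:
        raise ValueError("need >= 2 harmonized variants")
    ok = (locus["se_eqtl"] > 0) & (locus["se_gwas"] > 0)
    if (~ok).any():
        logger.info("coloc_posteriors: dropped %d variants with bad se", int((~ok).sum()))
        locus = locus[ok]
    l1 = wakefield_labf(locus["beta_eqtl"], locus["se_eqtl"], sd_quant)
    sd_g = sd_cc if trait_type_gwas == "case-control" else sd_quant
    l2 = wakefield_labf(locus["beta_gwas"], locus["se_gwas"], sd_g)

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over i != j of exp(l1_i + l2_j), in log space
    both = s1 + s2
    if both > s12:
        s_distinct = both + np.log1p(-np.exp(s12 - both))
    else:  # degenerate single-variant-dominated locus
        s_distinct = -np.inf

    lh = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + s_distinct,
        np.log(p12) + s12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    labf = pd.DataFrame({"rsid": locus["rsid"].to_numpy(),
                         "labf_eqtl": np.asarray(l1), "labf_gwas": np.asarray(l2)})
    return ColocResult(
        locus=locus_id,
        n_variants=len(locus),
        pp={f"PP{i}": float(pp[i]) for i in range(5)},
        priors=(p1, p2, p12),
        labf=labf,
    )


def coloc_scan(
    egene_assoc: dict[str, pd.DataFrame],
    geno_variants: pd.DataFrame,
    gwas: pd.DataFrame,
    gwas_p_max: float = 5e-5,
    pp4_candidate: float = 0.5,
    eqtl_p_max: float = 0.5,
    trait: str = "trait",
    **coloc_kwargs,
) -> pd.DataFrame:
    """Colocalize each eGene's cis summary statistics against one GWAS.

    ``egene_assoc`` maps gene -> full cis AssocRecord table (nominal stats).
    A locus is analyzed only if the minimum GWAS p within its cis window is
    below ``gwas_p_max``; candidates are flagged at PP4 >= ``pp4_candidate``.
    """
    allele_map = geno_variants.set_index("rsid")[["ref", "alt"]]
    rows = []
    for gene, assoc in egene_assoc.items():
        cis_rsids = assoc["variant"]
        g_sub = gwas[gwas["rsid"].isin(cis_rsids)]
        if g_sub.empty or g_sub["p"].min() >= gwas_p_max:
            logger.info("coloc_scan: %s skipped (GWAS gate)", gene)
            continue
        e = assoc.rename(columns={"variant": "rsid"})[["rsid", "beta", "se", "p"]].copy()
        e = e.join(allele_map, on="rsid")
        h = harmonize(e, g_sub, eqtl_p_max=eqtl_p_max)
        if len(h) < 2:
            continue
        tt = str(g_sub["trait_type"].iloc[0]) if "trait_type" in g_sub else "quantitative"
        res = coloc_posteriors(h, trait_type_gwas=tt, locus_id=gene, **coloc_kwargs)
        rows.append({
            "gene": gene, "trait": trait, "n_variants": res.n_variants,
            **res.pp, "candidate": res.pp["PP4"] >= pp4_candidate,
        })
    return pd.DataFrame(rows)
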
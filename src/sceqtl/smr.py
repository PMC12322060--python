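"""Summary-based Mendelian randomization (Wald ratio) and the HEIDI test.

SMR asks whether the effect of a variant on a trait is mediated by gene
expression: b_xy = beta_GWAS / beta_eQTL at the top eQTL instrument, tested
with T = z_e^2 z_g^2 / (z_e^2 + z_g^2) against chi-square(1).  HEIDI asks
whether nearby variants in LD imply the same b_xy (pleiotropy / causality)
or heterogeneous ratios (linkage between distinct causal variants).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix, ld_r

logger = logging.getLogger("sceqtl")

__all__ = ["smr_test", "heidi_test", "smr_scan"]


def smr_test(beta_e: float, se_e: float, beta_g: float, se_g: float) -> dict:
    """Wald-ratio effect of expression on trait with the SMR chi-square p.

    b_xy = beta_g / beta_e; the delta-method se uses
    se^2 = b_xy^2 (se_g^2/beta_g^2 + se_e^2/beta_e^2), falling back to the
    direct ratio-variance form se_g/|beta_e| when beta_g = 0.
    """
    if se_e <= 0 or se_g <= 0:
        raise ValueError("standard errors must be positive")
    if beta_e == 0:
        raise ValueError("beta_e = 0: no instrument")
    b_xy = beta_g / beta_e
    # stable expansion of b_xy^2 (se_g^2/beta_g^2 + se_e^2/beta_e^2):
    # no division by beta_g, and beta_g = 0 reduces to se_g/|beta_e|
    se = np.sqrt(se_g**2 / beta_e**2 + b_xy**2 * se_e**2 / beta_e**2)
    z_e = beta_e / se_e
    z_g = beta_g / se_g
    T = (z_e**2 * z_g**2) / (z_e**2 + z_g**2)
    p = float(stats.chi2.sf(T, df=1))
    return {"b_xy": float(b_xy), "se": float(se), "T": float(T), "p_smr": p}


def heidi_test(
    locus: pd.DataFrame,
    ld: np.ndarray,
    top: int,
    r2_bounds: tuple[float, float] = (0.05, 0.9),
    m_max: int = 20,
    eqtl_p_screen: float = 1.57e-3,
) -> tuple[float | None, int]:
    """Heterogeneity-in-dependent-instruments p-value.

    ``locus`` has per-variant beta_eqtl/se_eqtl/beta_gwas/se_gwas rows; ``ld``
    is the signed correlation matrix over the same rows; ``top`` indexes the
    instrument.  Up to ``m_max`` non-top variants with r2 to the instrument
    inside ``r2_bounds`` and eQTL p below the screen contribute deviations
    d_i = b_xy(i) - b_xy(top); their covariance follows from the delta
    method and LD, and the statistic sum z_d^2 is referred to a
    two-moment-matched scaled chi-square.  Returns (p or None, m used).
    """
    be = locus["beta_eqtl"].to_numpy(float)
    se_e = locus["se_eqtl"].to_numpy(float)
    bg = locus["beta_gwas"].to_numpy(float)
    se_g = locus["se_gwas"].to_numpy(float)
    z_e2 = (be / se_e) ** 2
    p_e = stats.chi2.sf(z_e2, df=1)

    r_top = ld[top]
    elig = (
        (np.arange(len(locus)) != top)
        & (r_top**2 >= r2_bounds[0])
        & (r_top**2 <= r2_bounds[1])
        & (p_e < eqtl_p_screen)
        & (be != 0)
    )
    idx = np.flatnonzero(elig)
    if len(idx) < 3:
        logger.info("heidi_test: only %d eligible variants (need >= 3)", len(idx))
        return None, len(idx)
    if len(idx) > m_max:
        idx = idx[np.argsort(p_e[idx])[:m_max]]
    sel = np.concatenate([[top], idx])

    b_xy = bg[sel] / be[sel]
    d = b_xy[1:] - b_xy[0]

    # delta-method covariance of the b_xy vector over `sel`
    R = ld[np.ix_(sel, sel)]
    g_term = np.outer(se_g[sel] / be[sel], se_g[sel] / be[sel]) * R
    e_term = (
        np.outer(bg[sel] * se_e[sel] / be[sel] ** 2, bg[sel] * se_e[sel] / be[sel] ** 2) * R
    )
    V_bxy = g_term + e_term
    k = len(sel) - 1
    # cov(d_i, d_j) = V_ij - V_i0 - V_j0 + V_00
    Vd = V_bxy[1:, 1:] - V_bxy[1:, :1] - V_bxy[:1, 1:] + V_bxy[0, 0]
    sd = np.sqrt(np.clip(np.diag(Vd), 1e-300, None))
    zd = d / sd
    stat = float((zd**2).sum())

    C = Vd / np.outer(sd, sd)
    lam = np.linalg.eigvalsh((C + C.T) / 2)
    lam = np.clip(lam, 0.0, None)
    tr, tr2 = lam.sum(), (lam**2).sum()
    if tr2 <= 0:
        return 1.0, k
    scale = tr2 / tr
    dof = tr**2 / tr2
    p = float(stats.chi2.sf(stat / scale, df=dof))
    return p, k


def smr_scan(
    egene_assoc: dict[str, pd.DataFrame],
    gwas: pd.DataFrame,
    geno: GenotypeMatrix,
    instrument_p: float = 5e-8,
    trait: str = "trait",
    **heidi_kwargs,
) -> pd.DataFrame:
    """SMR + HEIDI for every eGene with a genome-wide-significant instrument.

    ``egene_assoc`` maps gene -> harmonizable cis AssocRecord table (columns
    variant, beta, se, p).  LD is computed from the analysis genotypes.
    """
    rows = []
    for gene, assoc in egene_assoc.items():
        merged = assoc.rename(columns={"variant": "rsid"}).merge(
            gwas[["rsid", "beta", "se"]].rename(
                columns={"beta": "beta_gwas", "se": "se_gwas"}),
            on="rsid",
        ).rename(columns={"beta": "beta_eqtl", "se": "se_eqtl"})
        if merged.empty:
            continue
        top = int(merged["p"].idxmin())
        if merged.at[top, "p"] >= instrument_p:
            logger.info("smr_scan: %s skipped (no instrument below %g)", gene, instrument_p)
            continue
        res = smr_test(
            merged.at[top, "beta_eqtl"], merged.at[top, "se_eqtl"],
            merged.at[top, "beta_gwas"], merged.at[top, "se_gwas"],
        )
        gidx = geno.index_of(merged["rsid"])
        R = ld_r(geno.dosages[:, gidx])
        p_heidi, m = heidi_test(merged, R, merged.index.get_loc(top), **heidi_kwargs)
        rows.append({
            "gene": gene, "trait": trait,
            "instrument": merged.at[top, "rsid"],
            "b_xy": res["b_xy"], "se": res["se"],
            "p_smr": res["p_smr"],
            "p_heidi": np.nan if p_heidi is None else p_heidi,
            "m_heidi": m,
        })
    return pd.DataFrame(rows)
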
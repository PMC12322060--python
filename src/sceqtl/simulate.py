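"""Synthetic cohorts with the statistical structure the eQTL pipeline assumes.

The generators emulate a vaccination-challenge design: tens of donors sampled
before (T0) and three months after (T3m) BCG vaccination, each sample split
into an unstimulated (RPMI) and an LPS-stimulated fraction, profiled by
droplet scRNA-seq over a handful of major PBMC cell types.  Every simulator
is a pure function of its parameters and seed and emits a ``SimTruth`` with
the planted ground truth so recovery and calibration are directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix, compute_maf

__all__ = [
    "CONDITIONS",
    "CELL_TYPES",
    "SimTruth",
    "CellTruthSpec",
    "default_design",
    "simulate_genotypes",
    "simulate_cells",
    "simulate_gwas_summary",
    "simulate_allelic_counts",
]

# the four-level stimulation x vaccination design
CONDITIONS = ["T0-RPMI", "T0-LPS", "T3m-RPMI", "T3m-LPS"]
STIM_CONDITIONS = {"T0-LPS", "T3m-LPS"}
CELL_TYPES = ["monocyte", "CD4T", "CD8T", "NK", "B"]


@dataclass
class SimTruth:
    """Ground-truth parameters planted by a simulator."""

    params: dict = field(default_factory=dict)
    per_gene: pd.DataFrame | None = None
    per_variant: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genotypes: Hardy-Weinberg draws on an AR(1) latent Gaussian copula
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_donors: int = 38,
    n_variants: int = 500,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.6,
    n_duplicate_pairs: int = 0,
    seed: int = 0,
    block_size: int = 50,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    spacing: int = 5_000,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Hard-call dosages with geometric adjacent-variant LD and optional twins.

    Each haplotype is a latent AR(1) Gaussian (parameter ``ld_rho``,
    restarting at every ``block_size``-variant block boundary) thresholded at
    the allele-frequency quantile, so adjacent-variant LD decays
    geometrically and blocks are independent.  ``n_duplicate_pairs`` appends
    genotype-identical donor pairs to create relatedness.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must be within (0, 0.5], got {maf_range}")
    if not (0 <= ld_rho < 1):
        raise ValueError(f"ld_rho must be in [0,1), got {ld_rho}")
    if n_donors < 2:
        raise ValueError("need at least 2 donors")
    rng = np.random.default_rng(seed)

    target_maf = rng.uniform(lo, hi, size=n_variants)
    thresh = stats.norm.ppf(target_maf)

    n_base = n_donors - n_duplicate_pairs
    if n_base < n_duplicate_pairs:
        raise ValueError("too many duplicate pairs for the donor count")
    # two haplotypes per donor
    z = rng.standard_normal((2 * n_base, n_variants))
    for j in range(1, n_variants):
        if j % block_size != 0:
            z[:, j] = ld_rho * z[:, j - 1] + np.sqrt(1 - ld_rho**2) * z[:, j]
    dosage = (z[0::2] < thresh).astype(float) + (z[1::2] < thresh).astype(float)

    if n_duplicate_pairs:
        dosage = np.vstack([dosage, dosage[:n_duplicate_pairs]])

    donors = np.array([f"donor{i:03d}" for i in range(n_donors)], dtype=object)
    variants = pd.DataFrame(
        {
            "rsid": [f"rs{i + 1}" for i in range(n_variants)],
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n_variants),
            "ref": "A",
            "alt": "G",
            "maf": compute_maf(dosage),
            "missingness": 0.0,
        }
    )
    geno = GenotypeMatrix(donors=donors, variants=variants, dosages=dosage)
    dup_pairs = [
        (donors[i], donors[n_base + i]) for i in range(n_duplicate_pairs)
    ]
    truth = SimTruth(
        params={
            "seed": seed,
            "ld_rho": ld_rho,
            "duplicate_pairs": dup_pairs,
            "target_maf": target_maf,
        }
    )
    return geno, truth


# ---------------------------------------------------------------------------
# single cells: negative-binomial counts with donor/condition/genotype effects
# ---------------------------------------------------------------------------

@dataclass
class CellTruthSpec:
    """Effect structure for :func:`simulate_cells`.

    Log-scale linear predictor per cell and gene:

        log mu = base + cell-type effect + condition effect + donor intercept
                 + beta * dosage + tau * dosage * 1[stimulated] + log lib factor

    ``beta`` / ``tau`` map gene index -> (variant rsid, effect size).  Effects
    are in natural-log expression units per alt allele.  ``sd_*`` are the
    standard deviations of the corresponding random effects; defaults mirror
    a cohort where cell lineage dominates expression variance, then
    condition, then donor.
    """

    n_genes: int = 100
    base_log_mean: tuple[float, float] = (1.0, 2.5)   # log mean count range
    sd_cell_type: float = 0.8
    sd_condition: float = 0.25
    sd_donor: float = 0.15
    nb_dispersion_log_mean: float = np.log(10.0)       # NB size parameter
    nb_dispersion_log_sd: float = 0.5
    lib_size_log_sd: float = 0.25
    beta: dict[int, tuple[str, float]] = field(default_factory=dict)
    tau: dict[int, tuple[str, float]] = field(default_factory=dict)
    ti_fc: dict[int, tuple[str, float]] = field(default_factory=dict)
    exact_variance: bool = True  # rescale drawn level effects to their target SD


def default_design(
    donors,
    cells_per_sample: int = 30,
    cell_types=("monocyte",),
    conditions=CONDITIONS,
) -> pd.DataFrame:
    rows = [
        (d, c, ct, cells_per_sample)
        for d in donors for c in conditions for ct in cell_types
    ]
    return pd.DataFrame(rows, columns=["donor", "condition", "cell_type", "n_cells"])


def _scaled_effects(rng, levels, sd, exact):
    e = rng.standard_normal(len(levels))
    if len(levels) > 1 and exact and sd > 0:
        e = (e - e.mean()) / e.std() * sd
    else:
        e = e * sd
    return dict(zip(levels, e))


def simulate_cells(
    geno: GenotypeMatrix,
    design: pd.DataFrame,
    truth_spec: CellTruthSpec | None = None,
    seed: int = 0,
) -> tuple[ad.AnnData, SimTruth]:
    """Simulate UMI counts for the (donor, condition, cell type) design.

    Returns an AnnData with raw integer counts, cell metadata in ``obs`` and
    gene annotation (chrom, tss) in ``var``; gene TSSs are placed at the
    position of their cis variant (if any) so the 1 Mb window always covers
    the planted signal, and spread across the simulated region otherwise.
    """
    spec = truth_spec or CellTruthSpec()
    rng = np.random.default_rng(seed)
    missing = set(design["donor"]) - set(geno.donors)
    if missing:
        raise KeyError(f"design donors absent from genotypes: {sorted(missing)[:5]}")
    bad = set(design["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"conditions outside the design: {sorted(bad)}")

    G = spec.n_genes
    genes = [f"gene{g:04d}" for g in range(G)]
    base = rng.uniform(*spec.base_log_mean, size=G)
    ct_eff = {
        ct: _scaled_effects(rng, genes, spec.sd_cell_type, spec.exact_variance)
        for ct in design["cell_type"].unique()
    }
    cond_eff = {
        c: _scaled_effects(rng, genes, spec.sd_condition, spec.exact_variance)
        for c in design["condition"].unique()
    }
    donor_eff = {
        d: _scaled_effects(rng, genes, spec.sd_donor, spec.exact_variance)
        for d in design["donor"].unique()
    }
    dispersion = np.exp(
        rng.normal(spec.nb_dispersion_log_mean, spec.nb_dispersion_log_sd, size=G)
    )

    beta_vec = np.zeros(G)
    tau_vec = np.zeros(G)
    beta_var = np.full(G, "", dtype=object)
    tau_var = np.full(G, "", dtype=object)
    dos = {}

    def _dosage(rsid):
        if rsid not in dos:
            j = int(geno.index_of([rsid])[0])
            dos[rsid] = dict(zip(geno.donors, geno.dosages[:, j]))
        return dos[rsid]

    ti_vec = np.zeros(G)
    ti_var = np.full(G, "", dtype=object)
    for g, (rsid, b) in spec.beta.items():
        beta_vec[g], beta_var[g] = b, rsid
        _dosage(rsid)
    for g, (rsid, t) in spec.tau.items():
        tau_vec[g], tau_var[g] = t, rsid
        _dosage(rsid)
    for g, (rsid, t) in spec.ti_fc.items():
        ti_vec[g], ti_var[g] = t, rsid
        _dosage(rsid)

    obs_rows = []
    count_blocks = []
    cell_i = 0
    for _, row in design.iterrows():
        d, c, ct, n = row["donor"], row["condition"], row["cell_type"], int(row["n_cells"])
        stim = 1.0 if c in STIM_CONDITIONS else 0.0
        eta = base.copy()
        eta += np.array([ct_eff[ct][g] for g in genes])
        eta += np.array([cond_eff[c][g] for g in genes])
        eta += np.array([donor_eff[d][g] for g in genes])
        post_lps = 1.0 if c == "T3m-LPS" else 0.0
        for g in range(G):
            if beta_var[g]:
                eta[g] += beta_vec[g] * _dosage(beta_var[g])[d]
            if tau_var[g]:
                eta[g] += tau_vec[g] * _dosage(tau_var[g])[d] * stim
            if ti_var[g]:
                # fold-change QTL: shifts only the trained (post-BCG) LPS response
                eta[g] += ti_vec[g] * _dosage(ti_var[g])[d] * post_lps
        lib = np.exp(rng.normal(0.0, spec.lib_size_log_sd, size=n))
        mu = lib[:, None] * np.exp(eta)[None, :]
        # NB via gamma-Poisson mixture, size parameter per gene
        lam = rng.gamma(shape=dispersion[None, :], scale=mu / dispersion[None, :])
        counts = rng.poisson(lam)
        count_blocks.append(counts)
        for k in range(n):
            obs_rows.append((f"cell{cell_i + k:06d}", d, c, ct))
        cell_i += n

    X = np.vstack(count_blocks)
    obs = pd.DataFrame(obs_rows, columns=["cell", "donor", "condition", "cell_type"]).set_index("cell")
    # TSS at the cis variant when one is planted, otherwise spread over the region
    pos = geno.variants["pos"].to_numpy()
    tss = np.interp(np.arange(G), [0, max(G - 1, 1)], [pos.min(), pos.max()]).astype(int)
    for g in range(G):
        rsid = beta_var[g] or tau_var[g] or ti_var[g]
        if rsid:
            tss[g] = int(geno.variants.loc[geno.index_of([rsid])[0], "pos"])
    var = pd.DataFrame(
        {"chrom": geno.variants["chrom"].iloc[0], "tss": tss, "mito": False},
        index=pd.Index(genes, name="gene"),
    )
    adata = ad.AnnData(X=X.astype(np.int32), obs=obs, var=var)

    per_gene = pd.DataFrame(
        {
            "gene": genes,
            "beta": beta_vec,
            "beta_variant": beta_var,
            "tau": tau_vec,
            "tau_variant": tau_var,
            "ti_fc": ti_vec,
            "ti_fc_variant": ti_var,
            "base_log_mean": base,
            "nb_dispersion": dispersion,
        }
    )
    truth = SimTruth(
        params={
            "seed": seed,
            "sd_cell_type": spec.sd_cell_type,
            "sd_condition": spec.sd_condition,
            "sd_donor": spec.sd_donor,
        },
        per_gene=per_gene,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics: z ~ N(R z_causal, R)
# ---------------------------------------------------------------------------

def simulate_gwas_summary(
    geno: GenotypeMatrix,
    causal_config: str = "shared",
    n_gwas: int = 100_000,
    h2_locus: float = 5e-4,
    seed: int = 0,
    eqtl_causal: str | None = None,
    max_r2_distinct: float = 0.3,
    trait_type: str = "quantitative",
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-SNP GWAS beta/se from the multivariate-normal summary model.

    z = R z_c + e with e ~ N(0, R), R the dosage correlation of the supplied
    genotypes; the causal z has noncentrality sqrt(n h2 / (1 - h2)).
    ``causal_config``: 'shared' reuses ``eqtl_causal``; 'distinct' picks a
    variant with r2 < ``max_r2_distinct`` to it; 'none' plants nothing.
    """
    if causal_config not in {"shared", "distinct", "none"}:
        raise ValueError(f"unknown causal_config {causal_config!r}")
    if not (0 <= h2_locus < 1):
        raise ValueError("h2_locus must be in [0,1)")
    if n_gwas < 100:
        raise ValueError("n_gwas must be >= 100")
    rng = np.random.default_rng(seed)

    from .genotype import ld_r

    R = ld_r(geno.dosages)
    m = geno.n_variants
    R_reg = 0.95 * R + 0.05 * np.eye(m)  # keep the draw covariance PD

    zc = np.zeros(m)
    causal = None
    if causal_config != "none":
        if eqtl_causal is None:
            causal = int(rng.integers(m))
        else:
            e_idx = int(geno.index_of([eqtl_causal])[0])
            if causal_config == "shared":
                causal = e_idx
            else:
                far = np.flatnonzero(R[e_idx] ** 2 < max_r2_distinct)
                if len(far) == 0:
                    raise ValueError("no variant in low LD with the eQTL causal")
                causal = int(rng.choice(far))
        sign = rng.choice([-1.0, 1.0])
        zc[causal] = sign * np.sqrt(n_gwas * h2_locus / (1 - h2_locus))

    L = np.linalg.cholesky(R_reg)
    z = R @ zc + L @ rng.standard_normal(m)

    maf = geno.variants["maf"].to_numpy()
    se = 1.0 / np.sqrt(n_gwas * 2 * maf * (1 - maf))
    gwas = pd.DataFrame(
        {
            "rsid": geno.variants["rsid"],
            "chrom": geno.variants["chrom"],
            "pos": geno.variants["pos"],
            "effect_allele": geno.variants["alt"],
            "other_allele": geno.variants["ref"],
            "beta": z * se,
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(z)),
            "n": n_gwas,
            "trait_type": trait_type,
        }
    )
    truth = SimTruth(
        params={
            "seed": seed,
            "causal_config": causal_config,
            "causal_rsid": None if causal is None else geno.variants.at[causal, "rsid"],
            "causal_z": float(zc.sum()),
            "h2_locus": h2_locus,
        }
    )
    return gwas, truth


# ---------------------------------------------------------------------------
# allele-specific read counts: beta-binomial
# ---------------------------------------------------------------------------

def simulate_allelic_counts(
    n_sites: int,
    depth_spec: int | tuple[str, float] = 50,
    mu: float = 0.5,
    rho: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Reference read counts ~ BetaBinomial(depth, mu, rho).

    ``depth_spec``: an int for fixed depth, or ("poisson", mean).  Zero-depth
    sites are emitted with total 0 and flagged untestable.
    """
    if not (0 < mu < 1):
        raise ValueError("mu must be in (0,1)")
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0,1)")
    rng = np.random.default_rng(seed)
    if isinstance(depth_spec, (int, np.integer)):
        depth = np.full(n_sites, int(depth_spec))
    else:
        kind, mean = depth_spec
        if kind != "poisson":
            raise ValueError(f"unknown depth spec {depth_spec!r}")
        depth = rng.poisson(mean, size=n_sites)

    if rho == 0:
        ref = rng.binomial(depth, mu)
    else:
        a = mu * (1 / rho - 1)
        b = (1 - mu) * (1 / rho - 1)
        ref = rng.binomial(depth, rng.beta(a, b, size=n_sites))
    counts = pd.DataFrame(
        {
            "site": [f"site{i:05d}" for i in range(n_sites)],
            "ref_count": ref,
            "alt_count": depth - ref,
            "total": depth,
            "testable": depth > 0,
        }
    )
    truth = SimTruth(params={"seed": seed, "mu": mu, "rho": rho})
    return counts, truth
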
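"""Variant QC, LD pruning, kinship (GRM) construction and LD clumping.

The kinship matrix built here is the covariance of the donor random effect in
the eQTL mixed model: it absorbs both cryptic relatedness between donors and,
after expansion to the sample level, the repeated sampling of each donor
across stimulation/vaccination conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("sceqtl")

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "ClumpSet",
    "qc_variants",
    "hwe_exact_test",
    "prune_ld",
    "compute_grm",
    "expand_kinship",
    "clump",
    "ld_r",
]

VARIANT_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "maf", "missingness"]


@dataclass
class GenotypeMatrix:
    """Donor x variant dosage matrix with per-variant metadata.

    dosages are allele counts in [0, 2] (possibly fractional after imputation
    or when read from a DS field); positions are 1-based; ``maf`` is computed
    from the dosages of the donors actually present.
    """

    donors: np.ndarray            # (n_donors,) str
    variants: pd.DataFrame        # columns VARIANT_COLUMNS, one row per variant
    dosages: np.ndarray           # (n_donors, n_variants) float

    def __post_init__(self) -> None:
        self.donors = np.asarray(self.donors, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.donors), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.donors)} donors x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)
        key = self.variants[["chrom", "pos", "ref", "alt"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, ref, alt) variant records")

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            donors=self.donors,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def subset_donors(self, donor_ids) -> "GenotypeMatrix":
        pos = {d: i for i, d in enumerate(self.donors)}
        missing = [d for d in donor_ids if d not in pos]
        if missing:
            raise KeyError(f"donors absent from genotype matrix: {missing}")
        idx = np.array([pos[d] for d in donor_ids])
        out = GenotypeMatrix(
            donors=np.asarray(list(donor_ids), dtype=object),
            variants=self.variants.copy(),
            dosages=self.dosages[idx],
        )
        out.variants["maf"] = compute_maf(out.dosages)
        return out

    def index_of(self, rsids) -> np.ndarray:
        pos = pd.Index(self.variants["rsid"])
        idx = pos.get_indexer(rsids)
        if (idx < 0).any():
            bad = np.asarray(rsids)[idx < 0]
            raise KeyError(f"variants not found: {list(bad[:5])}")
        return idx


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency from dosages (alt frequency folded at 0.5)."""
    af = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(af, 1.0 - af)


@dataclass
class KinshipMatrix:
    """Symmetric PSD relationship matrix with a cached eigendecomposition."""

    ids: np.ndarray
    values: np.ndarray
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.shape[0] != K.shape[1] or K.shape[0] != len(self.ids):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric (tol 1e-10)")
        self.values = (K + K.T) / 2.0

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending, clamped at 0) and eigenvectors."""
        if self._eig is None:
            s, U = np.linalg.eigh(self.values)
            if s.min() < -1e-8 * max(1.0, abs(s.max())):
                raise ValueError(f"kinship matrix not PSD: min eigenvalue {s.min():.3g}")
            s = np.clip(s, 0.0, None)
            self._eig = (s, U)
        return self._eig


@dataclass
class ClumpSet:
    """Greedy p-value clumps: independent index variants with their LD satellites."""

    clumps: pd.DataFrame   # index_rsid, index_p, n_members
    members: pd.DataFrame  # index_rsid, rsid, r2


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def qc_variants(
    geno: GenotypeMatrix,
    min_minor_genotype_count: int = 3,
    require_rsid: bool = True,
) -> GenotypeMatrix:
    """Drop variants without an rsID and variants with too few carriers.

    The carrier rule counts donors whose hard-called genotype (dosage rounded
    to 0/1/2) is not the majority homozygote; variants with fewer than
    ``min_minor_genotype_count`` such donors are uninformative for association
    and removed.
    """
    hard = np.rint(np.clip(geno.dosages, 0, 2)).astype(int)
    keep = np.ones(geno.n_variants, dtype=bool)
    reasons = {"missing_rsid": 0, "low_carrier_count": 0}

    if require_rsid:
        rsid = geno.variants["rsid"].astype(str)
        no_id = rsid.isin(["", ".", "nan", "None"]) | ~rsid.str.startswith("rs")
        reasons["missing_rsid"] = int(no_id.sum())
        keep &= ~no_id.to_numpy()

    counts = np.stack([(hard == g).sum(axis=0) for g in (0, 1, 2)])  # (3, m)
    major = counts.argmax(axis=0)
    carriers = counts.sum(axis=0) - counts[major, np.arange(geno.n_variants)]
    low = carriers < min_minor_genotype_count
    reasons["low_carrier_count"] = int((low & keep).sum())
    keep &= ~low

    if not keep.any():
        raise ValueError(f"all variants dropped by QC: {reasons}")
    logger.info("qc_variants: kept %d/%d (%s)", keep.sum(), geno.n_variants, reasons)
    return geno.subset_variants(keep)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Wigginton et al. 2005), mid-p off
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value from genotype counts."""
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_minor, n_hom_major) + n_het
    # enumerate all heterozygote counts with the same allele counts
    het_candidates = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(len(het_candidates))
    # unnormalized log-probability of each het count under the exact HWE law
    from scipy.special import gammaln

    for i, h in enumerate(het_candidates):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        logp[i] = (
            h * np.log(2.0)
            + gammaln(n + 1) - gammaln(h + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.searchsorted(het_candidates, n_het)
    p = probs[probs <= probs[obs] + 1e-12].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# LD pruning (windowed greedy, plink --indep-pairwise semantics)
# ---------------------------------------------------------------------------

def ld_r(dosages: np.ndarray) -> np.ndarray:
    """Signed Pearson correlation between variant dosage columns."""
    X = dosages - dosages.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.nan
    X = X / sd
    r = (X.T @ X) / X.shape[0]
    return np.nan_to_num(r, nan=0.0)


def prune_ld(
    geno: GenotypeMatrix,
    window_variants: int = 250,
    step: int = 50,
    r2: float = 0.2,
    maf: float = 0.05,
    hwe_p: float = 1e-6,
) -> list[str]:
    """Greedy windowed LD pruning; returns surviving rsids.

    MAF and exact HWE filters are applied first.  Within each sliding window
    of ``window_variants`` variants, while any alive pair exceeds the r2
    threshold, the pair with the largest r2 is resolved by removing its
    lower-MAF member (ties: later position).  The window slides by ``step``.
    """
    mafs = geno.variants["maf"].to_numpy()
    alive = mafs > maf
    hard = np.rint(np.clip(geno.dosages, 0, 2)).astype(int)
    for j in np.flatnonzero(alive):
        n_het = int((hard[:, j] == 1).sum())
        n_alt = int((hard[:, j] == 2).sum())
        n_ref = int((hard[:, j] == 0).sum())
        n_hom_minor, n_hom_major = (n_alt, n_ref) if n_alt <= n_ref else (n_ref, n_alt)
        if hwe_exact_test(n_het, n_hom_minor, n_hom_major) < hwe_p:
            alive[j] = False

    order = np.lexsort((geno.variants["pos"].to_numpy(), geno.variants["chrom"].to_numpy()))
    pos = geno.variants["pos"].to_numpy()
    m = geno.n_variants
    start = 0
    while start < m:
        win = order[start:start + window_variants]
        win = win[alive[win]]
        if len(win) > 1:
            R2 = ld_r(geno.dosages[:, win]) ** 2
            np.fill_diagonal(R2, 0.0)
            local_alive = np.ones(len(win), dtype=bool)
            while True:
                R2v = np.where(np.outer(local_alive, local_alive), R2, 0.0)
                i, j = np.unravel_index(np.argmax(R2v), R2v.shape)
                if R2v[i, j] <= r2:
                    break
                a, b = win[i], win[j]
                # remove the lower-MAF member; ties -> later position
                if (mafs[a], -pos[a]) < (mafs[b], -pos[b]):
                    drop_local, drop = i, a
                else:
                    drop_local, drop = j, b
                local_alive[drop_local] = False
                alive[drop] = False
        if start + window_variants >= m:
            break
        start += step

    survivors = geno.variants.loc[alive, "rsid"].tolist()
    logger.info("prune_ld: %d/%d variants survive", len(survivors), m)
    return survivors


# ---------------------------------------------------------------------------
# genetic relationship matrix
# ---------------------------------------------------------------------------

def compute_grm(geno: GenotypeMatrix, pruned_ids: list[str] | None = None) -> KinshipMatrix:
    """Allele-frequency standardized relationship matrix.

    K_jk = (1/M) sum_m (g_jm - 2 p_m)(g_km - 2 p_m) / (2 p_m (1 - p_m)),
    with p_m the alt-allele frequency in the supplied donors.  Monomorphic
    variants are excluded (zero denominator).
    """
    if pruned_ids is not None:
        geno = geno.subset_variants(geno.index_of(pruned_ids))
    G = geno.dosages
    p = G.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic variants for the GRM")
    if (~poly).any():
        logger.info("compute_grm: excluded %d monomorphic variants", int((~poly).sum()))
    G = G[:, poly]
    p = p[poly]
    Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
    K = (Z @ Z.T) / Z.shape[1]
    return KinshipMatrix(ids=geno.donors, values=K)


def expand_kinship(K_donor: KinshipMatrix, sample_to_donor: pd.Series) -> KinshipMatrix:
    """Lift a donor-level kinship to repeated samples: K_s = Z K Z'."""
    pos = {d: i for i, d in enumerate(K_donor.ids)}
    unmapped = [d for d in sample_to_donor if d not in pos]
    if unmapped:
        raise KeyError(f"samples map to donors absent from kinship: {sorted(set(unmapped))[:5]}")
    idx = np.array([pos[d] for d in sample_to_donor])
    return KinshipMatrix(
        ids=np.asarray(sample_to_donor.index, dtype=object),
        values=K_donor.values[np.ix_(idx, idx)],
    )


# ---------------------------------------------------------------------------
# LD clumping (plink --clump semantics)
# ---------------------------------------------------------------------------

def clump(
    summary: pd.DataFrame,
    geno: GenotypeMatrix,
    p1: float = 5e-5,
    r2: float = 0.1,
    kb: float = 500.0,
) -> ClumpSet:
    """Greedy p-value clumping into independent loci.

    ``summary`` needs columns rsid and p.  Variants are processed in ascending
    p (ties: smaller position first); each unassigned variant with p <= p1
    seeds a clump and captures all unassigned variants within +-kb whose r2
    with it is >= the threshold.  Variants absent from the genotypes are
    excluded with a log message.
    """
    have = summary["rsid"].isin(geno.variants["rsid"])
    if (~have).any():
        logger.info("clump: %d summary variants absent from genotypes", int((~have).sum()))
    summary = summary.loc[have].copy()
    gidx = geno.index_of(summary["rsid"])
    summary["pos"] = geno.variants["pos"].to_numpy()[gidx]
    summary["chrom"] = geno.variants["chrom"].to_numpy()[gidx]
    summary["_gidx"] = gidx
    summary = summary.sort_values(["p", "pos"], kind="mergesort").reset_index(drop=True)

    assigned = np.zeros(len(summary), dtype=bool)
    clump_rows, member_rows = [], []
    for i in range(len(summary)):
        if assigned[i] or summary.at[i, "p"] > p1:
            continue
        assigned[i] = True
        idx_rsid = summary.at[i, "rsid"]
        near = (
            ~assigned
            & (summary["chrom"] == summary.at[i, "chrom"]).to_numpy()
            & (np.abs(summary["pos"].to_numpy() - summary.at[i, "pos"]) <= kb * 1000)
        )
        n_members = 0
        if near.any():
            cand = np.flatnonzero(near)
            g_index = geno.dosages[:, summary.at[i, "_gidx"]]
            g_cand = geno.dosages[:, summary["_gidx"].to_numpy()[cand]]
            r = _corr_with(g_index, g_cand)
            for c, rr in zip(cand, r):
                if rr * rr >= r2:
                    assigned[c] = True
                    member_rows.append((idx_rsid, summary.at[int(c), "rsid"], rr * rr))
                    n_members += 1
        clump_rows.append((idx_rsid, summary.at[i, "p"], n_members))

    clumps = pd.DataFrame(clump_rows, columns=["index_rsid", "index_p", "n_members"])
    members = pd.DataFrame(member_rows, columns=["index_rsid", "rsid", "r2"])
    return ClumpSet(clumps=clumps, members=members)


def _corr_with(g: np.ndarray, G: np.ndarray) -> np.ndarray:
    g = g - g.mean()
    X = G - G.mean(axis=0)
    denom = np.sqrt((g @ g) * (X * X).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (g @ X) / denom, 0.0)
    return r
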
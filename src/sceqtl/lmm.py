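"""Kinship-aware linear mixed model for cis-eQTL mapping.

Model per gene: y = W a + u + e with u ~ N(0, sg2 K) and e ~ N(0, se2 I).
K is eigendecomposed once per context; the restricted likelihood is profiled
over h2 = sg2/(sg2+se2) on the rotated (diagonal-covariance) system.  Per-SNP
tests use generalized least squares with the variance components fixed at the
gene's null fit (the EMMAX-style single-fit approximation), which makes the
per-variant test a weighted regression and the permutation pass a batched
matrix product.

Gene-level multiplicity follows the permutation / Storey-q convention:
empirical p per gene from the permutation minimum, q-values across genes,
and the max nominal p among eGenes as the global eVariant threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype import GenotypeMatrix, KinshipMatrix

logger = logging.getLogger("sceqtl")

__all__ = [
    "VarianceFit",
    "EqtlCallSet",
    "rank_inverse_normal",
    "condition_covariates",
    "fit_null_lmm",
    "map_cis",
    "permutation_pass",
    "qvalues",
    "call_egenes",
]


def rank_inverse_normal(y: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Blom rank-based inverse-normal transform."""
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(y)
    return stats.norm.ppf((ranks - offset) / (len(y) + 1 - 2 * offset))


def condition_covariates(meta: pd.DataFrame) -> pd.DataFrame:
    """Stimulation and vaccination indicators from the 4-level condition."""
    cond = meta["condition"].astype(str)
    return pd.DataFrame(
        {
            "stimulation": cond.str.endswith("LPS").astype(float),
            "vaccination": cond.str.startswith("T3m").astype(float),
        },
        index=meta.index,
    )


# ---------------------------------------------------------------------------
# null-model variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceFit:
    """Profiled REML fit of the single-kinship mixed model."""

    h2: float
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    weights: np.ndarray = field(repr=False)   # 1 / (h2 s_i + 1 - h2)

    def __post_init__(self) -> None:
        if not np.isfinite(self.reml_loglik):
            raise ValueError("restricted log-likelihood not finite")
        if self.sigma_e2 <= 0:
            raise ValueError("residual variance must be positive")


def _reml_neg2ll(h2: float, yt: np.ndarray, Wt: np.ndarray, s: np.ndarray) -> float:
    d = h2 * s + (1.0 - h2)
    if d.min() <= 0:
        return np.inf
    w = 1.0 / d
    sw = np.sqrt(w)
    Xw = Wt * sw[:, None]
    yw = yt * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n, p = Wt.shape
    rss = float(resid @ resid)
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    _, logdet_x = np.linalg.slogdet(Xw.T @ Xw)
    return (n - p) * np.log(sigma2) + float(np.log(d).sum()) + logdet_x


def fit_null_lmm(
    y: np.ndarray,
    covariates: np.ndarray,
    kinship: KinshipMatrix,
    n_grid: int = 64,
    h2_max: float = 0.99,
) -> VarianceFit:
    """Profile REML over h2 on the rotated diagonal system.

    ``covariates`` is the fixed-effect design W including the intercept.
    A 64-point grid locates the optimum, refined by bounded minimization;
    the boundary h2 = 0 is permitted.
    """
    y = np.asarray(y, dtype=float)
    W = np.asarray(covariates, dtype=float)
    n, p = W.shape
    if n <= p + 2:
        raise ValueError(f"too few samples ({n}) for {p} covariates")
    if np.linalg.matrix_rank(W) < p:
        raise ValueError("singular fixed-effect design")
    s, U = kinship.eig()
    yt = U.T @ y
    Wt = U.T @ W
    return _fit_rotated(yt, Wt, s, n_grid, h2_max)


def _fit_rotated(yt, Wt, s, n_grid=64, h2_max=0.99) -> VarianceFit:
    grid = np.linspace(0.0, h2_max, n_grid)
    vals = np.array([_reml_neg2ll(h, yt, Wt, s) for h in grid])
    # tie-break toward the smallest h2 (flat objective when K is uninformative)
    tol = 1e-8 * max(1.0, abs(float(vals.min())))
    i = int(np.flatnonzero(vals <= vals.min() + tol)[0])
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            _reml_neg2ll, bounds=(lo, hi), args=(yt, Wt, s), method="bounded",
            options={"xatol": 1e-8},
        )
        h2 = float(res.x) if res.fun < vals[i] - tol else float(grid[i])
    else:
        h2 = float(grid[i])
    d = h2 * s + (1 - h2)
    w = 1.0 / d
    sw = np.sqrt(w)
    Xw = Wt * sw[:, None]
    yw = yt * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n, p = Wt.shape
    sigma2 = float(resid @ resid) / (n - p)
    return VarianceFit(
        h2=h2,
        sigma_g2=h2 * sigma2,
        sigma_e2=(1 - h2) * sigma2,
        reml_loglik=-0.5 * _reml_neg2ll(h2, yt, Wt, s),
        weights=w,
    )


# ---------------------------------------------------------------------------
# cis mapping workspace
# ---------------------------------------------------------------------------

class _CisWorkspace:
    """Shared rotated quantities for one (cell type) mapping context."""

    def __init__(
        self,
        expr: pd.DataFrame,
        meta: pd.DataFrame,
        gene_annot: pd.DataFrame,
        geno: GenotypeMatrix,
        K_samples: KinshipMatrix | None,
        covariates: pd.DataFrame | None,
        window: int = 1_000_000,
        maf: float = 0.05,
        transform: str = "int",
    ):
        self.samples = expr.index
        n = len(self.samples)
        if K_samples is None:
            K_samples = KinshipMatrix(ids=np.asarray(self.samples, dtype=object),
                                      values=np.eye(n))
        else:
            pos = {i: k for k, i in enumerate(K_samples.ids)}
            if set(self.samples) - set(pos):
                raise KeyError("expression samples missing from sample kinship")
            idx = np.array([pos[i] for i in self.samples])
            K_samples = KinshipMatrix(
                ids=np.asarray(self.samples, dtype=object),
                values=K_samples.values[np.ix_(idx, idx)],
            )
        self.K_values = K_samples.values
        self.s, self.U = K_samples.eig()

        cols = [np.ones(n)]
        if covariates is not None:
            cov = covariates.loc[self.samples]
            cols.append(cov.to_numpy(dtype=float))
        self.W = np.column_stack(cols)
        self.p = np.linalg.matrix_rank(self.W)
        if self.p < self.W.shape[1]:
            raise ValueError("singular fixed-effect design")
        self.Wt = self.U.T @ self.W
        self.df = n - self.p - 1

        donor_pos = {d: i for i, d in enumerate(geno.donors)}
        try:
            self.donor_idx = np.array([donor_pos[d] for d in meta.loc[self.samples, "donor"]])
        except KeyError as e:
            raise KeyError(f"sample donor absent from genotypes: {e}")
        # sample -> donor indicator rotated later per gene
        self.E = np.zeros((n, geno.n_donors))
        self.E[np.arange(n), self.donor_idx] = 1.0

        self.geno = geno
        self.window = window
        self.maf = maf
        self.expr = expr
        self.transform = transform
        self.gene_annot = gene_annot

        vpos = geno.variants["pos"].to_numpy()
        vchrom = geno.variants["chrom"].to_numpy()
        vmaf = geno.variants["maf"].to_numpy()
        self.cis: dict[str, np.ndarray] = {}
        for gene in expr.columns:
            if gene not in gene_annot.index:
                continue
            chrom, tss = gene_annot.loc[gene, ["chrom", "tss"]]
            elig = (vchrom == str(chrom)) & (np.abs(vpos - int(tss)) <= window) & (vmaf > maf)
            idx = np.flatnonzero(elig)
            if len(idx):
                self.cis[gene] = idx

    def phenotype(self, gene: str) -> np.ndarray:
        y = self.expr[gene].to_numpy(dtype=float)
        if self.transform == "int":
            y = rank_inverse_normal(y)
        elif self.transform != "none":
            raise ValueError(f"unknown transform {self.transform!r}")
        return y

    def gene_fit(self, gene: str) -> tuple[np.ndarray, VarianceFit]:
        yt = self.U.T @ self.phenotype(gene)
        return yt, _fit_rotated(yt, self.Wt, self.s)


def _gls_scan(yt, Wt, Gt, w, df):
    """Vectorized per-column GLS t-tests with fixed weights.

    Gt: rotated genotype columns (n x m).  Returns beta, se, p arrays.
    """
    sw = np.sqrt(w)
    yw = yt * sw
    Xw = Wt * sw[:, None]
    Q, _ = np.linalg.qr(Xw)
    yr = yw - Q @ (Q.T @ yw)
    Gw = Gt * sw[:, None]
    Gr = Gw - Q @ (Q.T @ Gw)
    gg = (Gr * Gr).sum(axis=0)
    ok = gg > 1e-12
    num = Gr.T @ yr
    beta = np.where(ok, num / np.where(ok, gg, 1.0), np.nan)
    rss = float(yr @ yr) - np.where(ok, beta * num, 0.0)
    rss = np.clip(rss, 1e-300, None)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / np.where(ok, gg, np.nan))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def map_cis(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    gene_annot: pd.DataFrame,
    geno: GenotypeMatrix,
    K_samples: KinshipMatrix | None,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    maf: float = 0.05,
    transform: str = "int",
    context: str = "",
) -> pd.DataFrame:
    """Additive cis associations for every gene x eligible variant.

    Variants within ``window`` bp of the TSS (inclusive) with MAF strictly
    above ``maf`` are tested by GLS with the gene's null variance fit; the
    per-gene phenotype is rank inverse-normal transformed by default.
    Genes with no eligible variant are listed in ``result.attrs['untested']``.
    """
    ws = _CisWorkspace(expr, meta, gene_annot, geno, K_samples, covariates,
                       window, maf, transform)
    rows = []
    untested = []
    for gene in expr.columns:
        idx = ws.cis.get(gene)
        if idx is None or len(idx) == 0:
            untested.append(gene)
            continue
        yt, fit = ws.gene_fit(gene)
        Gt = ws.U.T @ (ws.E @ geno.dosages[:, idx])
        beta, se, p = _gls_scan(yt, ws.Wt, Gt, fit.weights, ws.df)
        sub = geno.variants.iloc[idx]
        rows.append(pd.DataFrame({
            "gene": gene,
            "variant": sub["rsid"].to_numpy(),
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "df": ws.df,
            "term": "additive",
            "context": context,
            "h2": fit.h2,
        }))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["gene", "variant", "chrom", "pos", "beta", "se", "p", "df",
                 "term", "context", "h2"])
    out = out.dropna(subset=["beta"]).reset_index(drop=True)
    out.attrs["untested"] = untested
    return out


def _relatedness_groups(ws: "_CisWorkspace", geno: GenotypeMatrix,
                        threshold: float) -> list[list[int]]:
    """Connected components of the donor relatedness graph (kinship above
    threshold); donors without samples count as singletons."""
    # donor-level kinship entries via one representative sample per donor
    rep = {}
    for si, di in enumerate(ws.donor_idx):
        rep.setdefault(int(di), si)
    Kvals = ws.K_values
    adj = {d: set() for d in range(geno.n_donors)}
    donors_present = sorted(rep)
    for a in donors_present:
        for b in donors_present:
            if a < b and abs(Kvals[rep[a], rep[b]]) > threshold:
                adj[a].add(b)
                adj[b].add(a)
    seen, groups = set(), []
    for d in range(geno.n_donors):
        if d in seen:
            continue
        stack, comp = [d], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x] - seen)
        groups.append(sorted(comp))
    return groups


def _grouped_donor_permutation(groups: list[list[int]], n_donors: int, rng) -> np.ndarray:
    """Permute donors so same-size relatedness groups swap slots as units."""
    perm = np.empty(n_donors, dtype=int)
    by_size: dict[int, list[list[int]]] = {}
    for g in groups:
        by_size.setdefault(len(g), []).append(g)
    for size, gs in by_size.items():
        order = rng.permutation(len(gs))
        for src_i, dst_i in enumerate(order):
            src, dst = gs[src_i], gs[int(dst_i)]
            members = list(rng.permutation(src)) if size > 1 else src
            for m, slot in zip(members, dst):
                perm[slot] = m
    return perm


def permutation_pass(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    gene_annot: pd.DataFrame,
    geno: GenotypeMatrix,
    K_samples: KinshipMatrix | None,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    maf: float = 0.05,
    transform: str = "int",
    B: int = 1000,
    seed: int = 0,
    scheme: str = "donor",
    relatedness_threshold: float = 0.45,
) -> pd.DataFrame:
    """Gene-level empirical p-values from permutations of the cis scan.

    The empirical p is (1 + #{min cis p_perm <= min cis p_obs}) / (1 + B);
    the same B permutations serve every gene.  Two schemes:

    - ``donor`` (default): permute the donor-to-genotype assignment (a
      donor's repeated samples move together).  Donors are permuted within
      exchangeability blocks derived from the kinship: strongly related
      donor groups (pairwise kinship above ``relatedness_threshold``) swap
      only with groups of the same size, so the alignment between genotype
      similarity and kinship-downweighted directions is preserved and the
      test stays calibrated with related donors in the cohort.
    - ``rotation``: permute the entries of the whitened phenotype residual
      (genotypes untouched, LD preserved).  Relies on the fitted variance
      components whitening exactly; kept as a cross-check.
    """
    if B < 100:
        logger.warning("permutation_pass: B=%d < 100, unstable tail", B)
    if scheme not in {"rotation", "donor"}:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    ws = _CisWorkspace(expr, meta, gene_annot, geno, K_samples, covariates,
                       window, maf, transform)
    rng = np.random.default_rng(seed)
    n = len(ws.samples)
    n_donors = geno.n_donors
    if scheme == "donor":
        groups = _relatedness_groups(ws, geno, relatedness_threshold)
        perms = np.stack([_grouped_donor_permutation(groups, n_donors, rng)
                          for _ in range(B)])
    else:
        perms = np.stack([rng.permutation(n) for _ in range(B)])

    rows = []
    for gene in expr.columns:
        idx = ws.cis.get(gene)
        if idx is None or len(idx) == 0:
            continue
        yt, fit = ws.gene_fit(gene)
        w = fit.weights
        sw = np.sqrt(w)
        yw = yt * sw
        Xw = ws.Wt * sw[:, None]
        Q, _ = np.linalg.qr(Xw)
        yr = yw - Q @ (Q.T @ yw)
        yy = float(yr @ yr)
        G_cis = geno.dosages[:, idx]                   # (d, m)
        m = G_cis.shape[1]

        if scheme == "rotation":
            Gw = ((ws.U.T @ ws.E) * sw[:, None]) @ G_cis     # (n, m)
            Gr = Gw - Q @ (Q.T @ Gw)
            gg = (Gr * Gr).sum(axis=0)
            ok = gg > 1e-12

            def max_t2_y(Y):
                # Y: (n, B') permuted residual columns; re-residualize on Q
                Y = Y - Q @ (Q.T @ Y)
                yyb = (Y * Y).sum(axis=0)
                num = Gr.T @ Y                               # (m, B')
                denom = gg[:, None] * yyb[None, :] - num**2
                t2 = np.where(ok[:, None], num**2 * ws.df / np.clip(denom, 1e-300, None), 0.0)
                return t2.max(axis=0)

            t2_obs = float(max_t2_y(yr[:, None])[0])
            counts = 0
            chunk = max(1, int(4e6 // n))
            for b0 in range(0, B, chunk):
                P = perms[b0:b0 + chunk]
                counts += int((max_t2_y(yr[P].T) >= t2_obs - 1e-12).sum())
        else:
            MEw = (ws.U.T @ ws.E) * sw[:, None]

            def max_t2_g(Gd_batch):
                # Gd_batch: (B', d, m) donor-level dosages
                Gw = np.matmul(MEw, Gd_batch)                # (B', n, m)
                Gr = Gw - np.matmul(Q, np.matmul(Q.T, Gw))
                gg = np.einsum("bnm,bnm->bm", Gr, Gr)
                num = np.einsum("n,bnm->bm", yr, Gr)
                ok = gg > 1e-12
                beta = np.where(ok, num / np.where(ok, gg, 1.0), 0.0)
                rss = np.clip(yy - beta * num, 1e-300, None)
                t2 = np.where(ok, beta * num * ws.df / rss, 0.0)
                return t2.max(axis=1)

            t2_obs = float(max_t2_g(G_cis[None])[0])
            counts = 0
            chunk = max(1, int(2e7 // (n * m)))
            for b0 in range(0, B, chunk):
                P = perms[b0:b0 + chunk]
                Gd = G_cis[P.reshape(-1)].reshape(len(P), n_donors, m)
                counts += int((max_t2_g(Gd) >= t2_obs - 1e-12).sum())

        p_obs = 2 * stats.t.sf(np.sqrt(t2_obs), ws.df)
        rows.append((gene, p_obs, (1 + counts) / (1 + B), B, seed))

    return pd.DataFrame(rows, columns=["gene", "p_obs", "p_emp", "n_perm", "seed"])


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def qvalues(p: np.ndarray, lambdas: np.ndarray | None = None,
            pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the cubic-smoother pi0 estimate.

    pi0(lambda) over the grid 0.05..0.95 is smoothed by a cubic polynomial
    and evaluated at the largest lambda; a degenerate smoother falls back to
    pi0 = 1 (plain Benjamini-Hochberg).  ``pi0`` may be forced explicitly
    (pi0 = 1 gives exactly BH).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0,1]")
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
        try:
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas.max()))
        except Exception:
            pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = 1.0
    pi0 = min(pi0, 1.0)

    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pi0 * m * p[i] / rank)
        q[i] = val
        prev = val
    return q


# ---------------------------------------------------------------------------
# eGene / eVariant calling
# ---------------------------------------------------------------------------

@dataclass
class EqtlCallSet:
    """Significant eGenes with the global nominal eVariant threshold."""

    context: str
    egenes: pd.DataFrame         # gene, top_variant, p_obs, p_emp, q
    nominal_threshold: float
    evariants: pd.DataFrame      # gene, variant, beta, se, p
    q_threshold: float = 0.05


def call_egenes(
    perm_records: pd.DataFrame,
    nominal_assoc: pd.DataFrame,
    q_threshold: float = 0.05,
    context: str = "",
) -> EqtlCallSet:
    """Call eGenes at q < threshold on empirical p; the max top nominal p
    among eGenes becomes the global cutoff that defines eVariants."""
    perm = perm_records.copy()
    perm["q"] = qvalues(perm["p_emp"].to_numpy())
    sig = perm[perm["q"] < q_threshold].copy()

    top = (
        nominal_assoc.sort_values(["gene", "p", "pos"], kind="mergesort")
        .groupby("gene", sort=False)
        .first()
    )
    sig["top_variant"] = top["variant"].reindex(sig["gene"]).to_numpy()
    egenes = sig[["gene", "top_variant", "p_obs", "p_emp", "q"]].reset_index(drop=True)

    if len(egenes):
        # threshold from the nominal table so the comparison is exact
        cutoff = float(top["p"].reindex(egenes["gene"]).max())
        ev = nominal_assoc[
            nominal_assoc["gene"].isin(egenes["gene"]) & (nominal_assoc["p"] <= cutoff)
        ][["gene", "variant", "beta", "se", "p"]].reset_index(drop=True)
    else:
        cutoff = np.nan
        ev = nominal_assoc.iloc[0:0][["gene", "variant", "beta", "se", "p"]]
    return EqtlCallSet(
        context=context,
        egenes=egenes,
        nominal_threshold=cutoff,
        evariants=ev,
        q_threshold=q_threshold,
    )
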
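"""Cell QC, normalization, pseudobulk aggregation, latent expression factors,
differential expression, module scores and pathway correlations."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("sceqtl")

__all__ = [
    "Pseudobulk",
    "qc_and_normalize",
    "pseudobulk_aggregate",
    "latent_factors",
    "differential_expression",
    "module_score",
    "pathway_correlation",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)


# ---------------------------------------------------------------------------
# cell QC + log-normalization
# ---------------------------------------------------------------------------

def qc_and_normalize(
    cells: ad.AnnData,
    max_mito: float = 0.25,
    min_genes: int = 100,
    max_genes: int = 5000,
    scale: float = 1e4,
) -> ad.AnnData:
    """Remove low-quality cells and add a log-normalized layer.

    Cells with mitochondrial fraction > ``max_mito`` or detected-gene count
    < ``min_genes`` or > ``max_genes`` are removed (thresholds are the usual
    droplet scRNA-seq defaults).  The normalized value is
    ln(1 + count * scale / cell_total).
    """
    X = _dense(cells.X)
    detected = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    mito_mask = cells.var["mito"].to_numpy() if "mito" in cells.var else np.zeros(cells.n_vars, bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, mito_mask].sum(axis=1) / total, 0.0)

    fail_mito = mito_frac > max_mito
    fail_low = detected < min_genes
    fail_high = detected > max_genes
    keep = ~(fail_mito | fail_low | fail_high)
    report = {
        "n_input": cells.n_obs,
        "removed_mito": int(fail_mito.sum()),
        "removed_few_genes": int(fail_low.sum()),
        "removed_many_genes": int(fail_high.sum()),
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError(f"all cells removed by QC: {report}")

    out = cells[keep].copy()
    Xk = X[keep]
    tot = Xk.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    out.layers["lognorm"] = np.log1p(Xk * scale / tot)
    out.obs["n_genes_detected"] = detected[keep]
    out.obs["mito_fraction"] = mito_frac[keep]
    out.uns["qc_report"] = report
    logger.info("qc_and_normalize: %s", report)
    return out


# ---------------------------------------------------------------------------
# pseudobulk aggregation + donor-fraction gene filter
# ---------------------------------------------------------------------------

@dataclass
class Pseudobulk:
    """Mean normalized expression per (donor, condition, cell type) sample.

    ``retained`` holds, per cell type, the genes with nonzero expression in
    at least the required fraction of donors; cis mapping in a cell type is
    restricted to that list.  Samples with zero cells are absent, not
    zero-filled.
    """

    expr: pd.DataFrame            # samples x genes, mean lognorm
    meta: pd.DataFrame            # sample_id -> donor, condition, cell_type, n_cells
    retained: dict = field(default_factory=dict)

    def context(self, cell_type: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(expression, metadata) for one cell type, filtered genes."""
        m = self.meta[self.meta["cell_type"] == cell_type]
        genes = self.retained.get(cell_type, list(self.expr.columns))
        return self.expr.loc[m.index, genes], m


def pseudobulk_aggregate(cells: ad.AnnData, min_donor_frac: float = 0.30) -> Pseudobulk:
    if "lognorm" not in cells.layers:
        raise ValueError("run qc_and_normalize first (no lognorm layer)")
    L = np.asarray(cells.layers["lognorm"], dtype=float)
    obs = cells.obs
    key = obs["donor"].astype(str) + "|" + obs["condition"].astype(str) + "|" + obs["cell_type"].astype(str)
    groups = pd.Index(key, name="sample")
    expr = pd.DataFrame(L, index=groups, columns=cells.var_names).groupby(level=0).mean()
    sizes = groups.value_counts()
    meta = pd.DataFrame(
        [s.split("|") for s in expr.index],
        index=expr.index,
        columns=["donor", "condition", "cell_type"],
    )
    meta["n_cells"] = sizes.reindex(expr.index).to_numpy()

    retained: dict[str, list[str]] = {}
    for ct, m in meta.groupby("cell_type", observed=True):
        sub = expr.loc[m.index]
        # a donor counts as expressing if any of its samples is nonzero
        nz = (sub > 0).groupby(m["donor"]).any()
        frac = nz.mean(axis=0)
        retained[ct] = list(expr.columns[(frac >= min_donor_frac).to_numpy()])
    return Pseudobulk(expr=expr, meta=meta, retained=retained)


# ---------------------------------------------------------------------------
# latent expression factors (covariate-residualized PCA)
# ---------------------------------------------------------------------------

def latent_factors(
    expr: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """Append k leading principal factors of covariate-residualized expression.

    Stands in for PEER-style latent confounders: expression is residualized
    on the known covariates (plus intercept), and the top left singular
    vectors of the residual matrix are returned standardized (zero mean,
    unit variance, mutually orthogonal).
    """
    n = len(expr)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples {n}")
    Y = expr.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    if covariates is not None and covariates.shape[1] > 0:
        C = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
        Y = Y - C @ beta
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    F = U[:, :k]
    F = (F - F.mean(axis=0)) / F.std(axis=0)
    out = covariates.copy() if covariates is not None else pd.DataFrame(index=expr.index)
    for i in range(k):
        out[f"factor{i + 1}"] = F[:, i]
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    cells: ad.AnnData,
    group_a,
    group_b,
    test: str = "wilcoxon",
    fdr: float = 0.05,
    lfc: float = 0.15,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene DE between two cell groups on the normalized layer.

    log2FC = log2((mean expm1 lognorm in A + 1) / (mean expm1 lognorm in B + 1));
    p by two-sided rank-sum (default) or a likelihood-ratio test on detection
    rates; BH adjustment.  The significant set requires adjusted p < ``fdr``
    AND |log2FC| > ``lfc``.
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.dtype == bool:
        a = np.flatnonzero(a)
    if b.dtype == bool:
        b = np.flatnonzero(b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 cells")
    L = np.asarray(cells.layers["lognorm"], dtype=float)
    A, B = L[a], L[b]
    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + 1) / (mean_b + 1))

    if test == "wilcoxon":
        p = np.ones(cells.n_vars)
        for g in range(cells.n_vars):
            x, y = A[:, g], B[:, g]
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                continue
            p[g] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    elif test == "lr":
        # LR test on detection: logistic null (pooled rate) vs per-group rates
        det_a = (A > 0).sum(axis=0)
        det_b = (B > 0).sum(axis=0)
        na, nb = len(a), len(b)
        p = np.ones(cells.n_vars)
        for g in range(cells.n_vars):
            table = np.array([[det_a[g], na - det_a[g]], [det_b[g], nb - det_b[g]]])
            if table.sum(axis=0).min() == 0:
                continue
            ll = 0.0
            tot = table.sum()
            col = table.sum(axis=0)
            for i in range(2):
                row = table[i].sum()
                for j in range(2):
                    if table[i, j] > 0:
                        exp = row * col[j] / tot
                        ll += table[i, j] * np.log(table[i, j] / exp)
            p[g] = stats.chi2.sf(2 * ll, df=1)
    else:
        raise ValueError(f"unknown test {test!r}")

    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"gene": cells.var_names, "log2fc": log2fc, "p": p, "p_adj": padj}
    )
    sig = table.loc[(table["p_adj"] < fdr) & (table["log2fc"].abs() > lfc), "gene"].tolist()
    return table, sig


# ---------------------------------------------------------------------------
# module scores (expression-bin matched control genes)
# ---------------------------------------------------------------------------

def module_score(
    cells: ad.AnnData,
    gene_set: list[str],
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell score of a gene set against expression-matched controls.

    Genes are binned by mean normalized expression across cells; each set
    gene draws ``nctrl`` control genes (with replacement) from its bin; the
    score is mean(set) - mean(controls) per cell.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(cells.var_names)
    if missing:
        raise KeyError(f"gene set members not measured: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    L = np.asarray(cells.layers["lognorm"], dtype=float)
    gmean = pd.Series(L.mean(axis=0), index=cells.var_names)
    nbin_eff = min(nbin, gmean.nunique())
    bins = pd.qcut(gmean.rank(method="first"), nbin_eff, labels=False)

    gidx = {g: i for i, g in enumerate(cells.var_names)}
    set_idx = np.array([gidx[g] for g in gene_set])
    ctrl_cols = []
    for g in gene_set:
        pool = bins.index[bins == bins[g]]
        ctrl_cols.append(rng.choice([gidx[c] for c in pool], size=nctrl, replace=True))
    ctrl_idx = np.unique(np.concatenate(ctrl_cols))
    score = L[:, set_idx].mean(axis=1) - L[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=cells.obs_names, name="module_score")


def pathway_correlation(
    cells: ad.AnnData,
    gene_set: list[str],
    per_donor_signal: pd.Series,
    n_null_sets: int = 1000,
    seed: int = 0,
    nbin: int = 24,
    nctrl: int = 100,
) -> dict:
    """Pearson correlation between a per-donor signal and per-donor mean
    module score, with an empirical null from size-matched random gene sets."""
    if per_donor_signal.std() == 0:
        raise ValueError("zero-variance signal")
    donors = cells.obs["donor"]
    common = per_donor_signal.index.intersection(donors.unique())
    if len(common) < 5:
        raise ValueError("need >= 5 donors with both signal and cells")
    rng = np.random.default_rng(seed)

    def _donor_mean(score: pd.Series) -> pd.Series:
        return score.groupby(donors.to_numpy()).mean().reindex(common)

    obs_score = _donor_mean(module_score(cells, gene_set, nbin, nctrl, seed=seed))
    sig = per_donor_signal.reindex(common)
    r_obs, p_obs = stats.pearsonr(sig, obs_score)

    all_genes = list(cells.var_names)
    null_r = np.empty(n_null_sets)
    for i in range(n_null_sets):
        rand_set = list(rng.choice(all_genes, size=len(gene_set), replace=False))
        sc = _donor_mean(module_score(cells, rand_set, nbin, nctrl, seed=int(rng.integers(2**31))))
        null_r[i] = stats.pearsonr(sig, sc)[0]
    quantile = float((np.abs(null_r) < abs(r_obs)).mean())
    return {
        "r": float(r_obs),
        "p": float(p_obs),
        "null_r": null_r,
        "null_quantile": quantile,
    }
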
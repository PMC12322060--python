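"""Readers and writers for the pipeline's on-disk formats, run configuration
and the staged pipeline driver.

Inputs: VCF 4.2 genotypes (DS or GT), single-cell counts as TSV or
MatrixMarket with a cell-metadata table, a gene-annotation TSV (1-based TSS),
GWAS summary TSV and allele-specific count TSV.  Outputs are diff-able TSV
tables plus a JSON provenance sidecar; identical config and seeds give
byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype import GenotypeMatrix, compute_maf

logger = logging.getLogger("sceqtl")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

__all__ = [
    "RunConfig",
    "ResultBundle",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_cells",
    "write_cells_tsv",
    "run_pipeline",
]

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration; all randomness flows from explicit seeds."""

    paths: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    coloc: dict = field(default_factory=dict)
    smr: dict = field(default_factory=dict)
    simulate: dict | None = None

    _ANALYSIS_DEFAULTS = {
        "cell_types": ["monocyte"],
        "cis_window": 1_000_000,
        "maf": 0.05,
        "n_permutations": 1000,
        "q_threshold": 0.05,
        "n_latent_factors": 5,
        "transform": "int",
        "seed": 0,
        "contrasts": ["BCG", "LPS", "LPS_postBCG"],
        "varpart_genes": 10,
        "qc_max_mito": 0.25,
        "qc_min_genes": 100,
        "qc_max_genes": 5000,
    }
    _COLOC_DEFAULTS = {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5,
                       "sd_quant": 0.15, "sd_cc": 0.2,
                       "gwas_p_max": 5e-5, "pp4_candidate": 0.5}
    _SMR_DEFAULTS = {"instrument_p": 5e-8, "r2_min": 0.05, "r2_max": 0.9}

    def __post_init__(self) -> None:
        self.analysis = {**self._ANALYSIS_DEFAULTS, **self.analysis}
        self.coloc = {**self._COLOC_DEFAULTS, **self.coloc}
        self.smr = {**self._SMR_DEFAULTS, **self.smr}
        a = self.analysis
        if a["cis_window"] <= 0:
            raise ValueError("cis_window must be > 0")
        if not (0 < a["maf"] <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        for k in ("p1", "p2", "p12"):
            if not (0 < self.coloc[k] < 1):
                raise ValueError(f"coloc prior {k} must be in (0,1)")
        if not isinstance(a["seed"], (int, np.integer)):
            raise ValueError("seed must be an explicit integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            paths=raw.get("paths", {}),
            analysis=raw.get("analysis", {}),
            coloc=raw.get("coloc", {}),
            smr=raw.get("smr", {}),
            simulate=raw.get("simulate"),
        )

    def digest(self) -> str:
        blob = json.dumps(
            {"paths": {k: str(v) for k, v in self.paths.items()},
             "analysis": self.analysis, "coloc": self.coloc, "smr": self.smr,
             "simulate": self.simulate},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_genotypes_vcf(
    path,
    donor_subset: list[str] | None = None,
    max_missingness: float = 0.10,
) -> GenotypeMatrix:
    """Read biallelic dosages from a VCF (DS field preferred over GT).

    Multi-allelic records are skipped with a logged count; missing genotypes
    are mean-imputed per variant and the imputation fraction recorded as
    ``missingness``; variants missing in more than ``max_missingness`` of
    donors are dropped.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as e:
        raise OSError(f"unreadable VCF {path}: {e}")
    samples = list(vcf.samples)
    if donor_subset is not None:
        missing = [d for d in donor_subset if d not in samples]
        if missing:
            raise KeyError(f"donors absent from VCF: {missing}")
        keep_idx = np.array([samples.index(d) for d in donor_subset])
        donors = list(donor_subset)
    else:
        keep_idx = np.arange(len(samples))
        donors = samples

    rows, cols = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, float).reshape(-1)[keep_idx]
            d = np.where((d < 0) | ~np.isfinite(d), np.nan, d)
        else:
            gts = np.asarray(v.genotype.array())[:, :2][keep_idx]
            d = np.where((gts >= 0).all(axis=1), gts.clip(0).sum(axis=1), np.nan).astype(float)
        miss = np.isnan(d)
        frac = miss.mean()
        if frac > max_missingness:
            continue
        if miss.any():
            d[miss] = np.nanmean(d)
        rows.append(d)
        cols.append((v.ID or ".", v.CHROM, v.POS, v.REF, v.ALT[0], frac))
    if n_multi:
        logger.info("read_genotypes_vcf: skipped %d multi-allelic records", n_multi)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    dosages = np.column_stack(rows)
    variants = pd.DataFrame(cols, columns=["rsid", "chrom", "pos", "ref", "alt", "missingness"])
    variants["maf"] = compute_maf(dosages)
    variants = variants[["rsid", "chrom", "pos", "ref", "alt", "maf", "missingness"]]
    return GenotypeMatrix(donors=np.asarray(donors, dtype=object),
                          variants=variants, dosages=dosages)


def write_genotypes_vcf(geno: GenotypeMatrix, path) -> None:
    """Write hard-called genotypes as a minimal VCF 4.2 with GT records."""
    hard = np.rint(np.clip(geno.dosages, 0, 2)).astype(int)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(geno.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, geno.donors)) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in geno.variants.iterrows():
            gts = "\t".join(gt_str[g] for g in hard[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['rsid']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def read_cells(matrix_path, metadata_path, annotation_path) -> ad.AnnData:
    """Assemble an AnnData from counts + cell metadata + gene annotation.

    Counts: TSV with cells in rows (first column = cell id) or MatrixMarket
    (cells x genes) with ``<stem>_cells.txt`` / ``<stem>_genes.txt`` sidecars.
    Metadata must cover every cell and use the four-level condition design;
    genes lacking a TSS annotation are retained but flagged unmappable.
    """
    from .simulate import CONDITIONS

    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        from scipy.io import mmread

        X = np.asarray(mmread(matrix_path).todense())
        stem = matrix_path.with_suffix("")
        cells_ids = pd.read_csv(f"{stem}_cells.txt", header=None)[0].astype(str).tolist()
        gene_ids = pd.read_csv(f"{stem}_genes.txt", header=None)[0].astype(str).tolist()
        counts = pd.DataFrame(X, index=cells_ids, columns=gene_ids)
    else:
        with open(matrix_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise ValueError("duplicate gene ids in count matrix")
        counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if counts.columns.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = set(counts.index) - set(meta.index)
    if missing:
        raise KeyError(f"cells absent from metadata: {sorted(missing)[:5]}")
    meta = meta.loc[counts.index]
    bad = set(meta["condition"].astype(str)) - set(CONDITIONS)
    if bad:
        raise ValueError(f"condition labels outside the design: {sorted(bad)}")

    annot = pd.read_csv(annotation_path, sep="\t", index_col=0)
    var = pd.DataFrame(index=counts.columns)
    var["chrom"] = annot["chrom"].reindex(counts.columns).astype(object)
    var["tss"] = annot["tss"].reindex(counts.columns)
    var["mappable"] = var["tss"].notna()
    var["tss"] = var["tss"].fillna(-1).astype(int)
    if "mito" in annot.columns:
        var["mito"] = annot["mito"].reindex(counts.columns).fillna(False).astype(bool)
    else:
        var["mito"] = False
    if (~var["mappable"]).any():
        logger.info("read_cells: %d genes lack TSS annotation (excluded from cis mapping)",
                    int((~var["mappable"]).sum()))
    return ad.AnnData(X=counts.to_numpy(dtype=np.int32),
                      obs=meta[["donor", "condition", "cell_type"]].astype(str),
                      var=var)


def write_cells_tsv(cells: ad.AnnData, matrix_path, metadata_path, annotation_path) -> None:
    X = np.asarray(cells.X)
    pd.DataFrame(X, index=cells.obs_names, columns=cells.var_names).to_csv(
        matrix_path, sep="\t")
    cells.obs[["donor", "condition", "cell_type"]].to_csv(metadata_path, sep="\t")
    annot = cells.var[["chrom", "tss"]].copy()
    annot["mito"] = cells.var.get("mito", False)
    annot.to_csv(annotation_path, sep="\t")


# ---------------------------------------------------------------------------
# result bundle
# ---------------------------------------------------------------------------

@dataclass
class ResultBundle:
    """Named result tables plus provenance; lossless TSV round-trip."""

    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                      float_format=FLOAT_FORMAT)
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True, default=str)

    @classmethod
    def read(cls, outdir) -> "ResultBundle":
        outdir = Path(outdir)
        tables = {
            p.stem: pd.read_csv(p, sep="\t")
            for p in sorted(outdir.glob("*.tsv"))
        }
        with open(outdir / "provenance.json") as fh:
            prov = json.load(fh)
        return cls(tables=tables, provenance=prov)


# ---------------------------------------------------------------------------
# staged pipeline driver
# ---------------------------------------------------------------------------

ALL_STAGES = ["qc", "pseudobulk", "kinship", "map-cis", "map-response",
              "map-ti", "coloc", "smr", "share", "allelic", "varpart"]


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> ResultBundle:
    """Execute the pipeline stages in dependency order.

    Writes each stage's tables into ``paths.outdir`` as it completes, so a
    failing stage leaves earlier results on disk; the failure is re-raised
    with the stage name.  Stages whose inputs are not configured (e.g. coloc
    without a GWAS path) are skipped with a log message.
    """
    from . import coloc as coloc_mod
    from . import smr as smr_mod
    from .genotype import compute_grm, expand_kinship, prune_ld, qc_variants
    from .lmm import call_egenes, condition_covariates, map_cis, permutation_pass
    from .pseudobulk import (differential_expression, latent_factors,
                             pseudobulk_aggregate, qc_and_normalize)
    from .response import CONTRASTS, map_response, map_ti
    from .sharing import allelic_imbalance, eb_shrink, pairwise_sharing
    from .simulate import (CellTruthSpec, default_design, simulate_cells,
                           simulate_genotypes)
    from .varpart import FACTORS, fit_variance_components, variance_summary

    stages = stages or ALL_STAGES
    a = config.analysis
    seed = int(a["seed"])
    outdir = Path(config.paths.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(provenance={
        "config_digest": config.digest(), "seed": seed, "version": __version__,
    })

    def _emit(name, df):
        bundle.tables[name] = df
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    # --- optional synthetic inputs -------------------------------------
    if config.simulate is not None:
        sim = dict(config.simulate)
        geno_path = Path(config.paths["genotypes"])
        if not geno_path.exists():
            geno, _ = simulate_genotypes(
                n_donors=sim.get("n_donors", 38),
                n_variants=sim.get("n_variants", 400),
                ld_rho=sim.get("ld_rho", 0.6),
                n_duplicate_pairs=sim.get("n_duplicate_pairs", 2),
                seed=seed,
            )
            write_genotypes_vcf(geno, geno_path)
            design = default_design(
                geno.donors,
                cells_per_sample=sim.get("cells_per_sample", 25),
                cell_types=tuple(a["cell_types"]),
            )
            spec = CellTruthSpec(n_genes=sim.get("n_genes", 60))
            cells, _ = simulate_cells(geno, design, spec, seed=seed + 1)
            write_cells_tsv(cells, config.paths["counts"],
                            config.paths["cell_metadata"], config.paths["gene_annotation"])

    # --- load + QC ------------------------------------------------------
    current = "load"
    try:
        geno = read_genotypes_vcf(config.paths["genotypes"])
        cells = read_cells(config.paths["counts"], config.paths["cell_metadata"],
                           config.paths["gene_annotation"])

        qc_kwargs = dict(max_mito=a["qc_max_mito"], min_genes=a["qc_min_genes"],
                         max_genes=a["qc_max_genes"])
        if "qc" in stages:
            current = "qc"
            geno = qc_variants(geno)
            cells = qc_and_normalize(cells, **qc_kwargs)
            _emit("qc_variants", geno.variants)
        else:
            cells = qc_and_normalize(cells, **qc_kwargs)

        current = "pseudobulk"
        pb = pseudobulk_aggregate(cells)
        if "pseudobulk" in stages:
            _emit("pseudobulk_meta", pb.meta.reset_index())
            _emit("pseudobulk_expr", pb.expr.reset_index())

        current = "kinship"
        pruned = prune_ld(geno)
        K_donor = compute_grm(geno, pruned if len(pruned) >= 2 else None)
        if "kinship" in stages:
            kdf = pd.DataFrame(K_donor.values, columns=K_donor.ids)
            kdf.insert(0, "donor", K_donor.ids)
            _emit("kinship", kdf)

        gene_annot = cells.var.loc[cells.var["mappable"]][["chrom", "tss"]]
        gene_annot["chrom"] = gene_annot["chrom"].astype(str)

        calls = {}
        assoc_by_ct = {}
        if "map-cis" in stages:
            current = "map-cis"
            rows_e, rows_a = [], []
            for ct in a["cell_types"]:
                expr, meta = pb.context(ct)
                expr = expr[[g for g in expr.columns if g in gene_annot.index]]
                if expr.empty or len(meta) < 10:
                    logger.info("map-cis: skipping %s (too few samples)", ct)
                    continue
                cov = condition_covariates(meta)
                k = min(a["n_latent_factors"], len(meta) - cov.shape[1] - 3)
                if k > 0:
                    cov = latent_factors(expr, cov, k=k)
                Ks = expand_kinship(K_donor, meta["donor"])
                assoc = map_cis(expr, meta, gene_annot, geno, Ks, cov,
                                a["cis_window"], a["maf"], a["transform"], context=ct)
                perm = permutation_pass(expr, meta, gene_annot, geno, Ks, cov,
                                        a["cis_window"], a["maf"], a["transform"],
                                        B=a["n_permutations"], seed=seed + 17)
                cs = call_egenes(perm, assoc, a["q_threshold"], context=ct)
                calls[ct] = cs
                assoc_by_ct[ct] = assoc
                rows_a.append(assoc)
                eg = cs.egenes.copy()
                eg["context"] = ct
                eg["nominal_threshold"] = cs.nominal_threshold
                rows_e.append(eg)
            if rows_a:
                _emit("assoc_cis", pd.concat(rows_a, ignore_index=True))
                _emit("egenes", pd.concat(rows_e, ignore_index=True))

        if "map-response" in stages:
            current = "map-response"
            rows = []
            for ct in a["cell_types"]:
                for cname in a["contrasts"]:
                    try:
                        r = map_response(pb, gene_annot, geno, K_donor,
                                         CONTRASTS[cname], ct,
                                         window=a["cis_window"], maf=a["maf"],
                                         transform=a["transform"])
                    except ValueError as e:
                        logger.info("map-response %s/%s skipped: %s", ct, cname, e)
                        continue
                    if len(r):
                        rows.append(r)
            if rows:
                _emit("response_eqtl", pd.concat(rows, ignore_index=True))

        if "map-ti" in stages and "monocyte" in set(cells.obs["cell_type"]):
            current = "map-ti"
            mono = cells[cells.obs["cell_type"] == "monocyte"]
            grp_a = (mono.obs["condition"] == "T3m-LPS").to_numpy()
            grp_b = (mono.obs["condition"] == "T0-LPS").to_numpy()
            if grp_a.sum() >= 3 and grp_b.sum() >= 3:
                de, ti_genes = differential_expression(mono, grp_a, grp_b)
                _emit("ti_response_genes", de)
                cov = None
                if config.paths.get("donor_covariates"):
                    cov = pd.read_csv(config.paths["donor_covariates"], sep="\t", index_col=0)
                if ti_genes:
                    try:
                        ti_assoc, ti_sig = map_ti(pb, ti_genes, gene_annot, geno,
                                                  K_donor, cov,
                                                  a["cis_window"], a["maf"])
                        _emit("ti_eqtl", ti_assoc)
                        _emit("ti_eqtl_significant", ti_sig)
                    except ValueError as e:
                        logger.info("map-ti skipped: %s", e)

        gwas = None
        if config.paths.get("gwas"):
            gwas = pd.read_csv(config.paths["gwas"], sep="\t")

        egene_assoc = {}
        for ct, cs in calls.items():
            for g in cs.egenes["gene"]:
                egene_assoc[g] = assoc_by_ct[ct][assoc_by_ct[ct]["gene"] == g]

        if "coloc" in stages and gwas is not None and egene_assoc:
            current = "coloc"
            cres = coloc_mod.coloc_scan(
                egene_assoc, geno.variants, gwas,
                gwas_p_max=config.coloc["gwas_p_max"],
                pp4_candidate=config.coloc["pp4_candidate"],
                p1=config.coloc["p1"], p2=config.coloc["p2"], p12=config.coloc["p12"],
                sd_quant=config.coloc["sd_quant"], sd_cc=config.coloc["sd_cc"],
            )
            if len(cres):
                _emit("coloc", cres)

        if "smr" in stages and gwas is not None and egene_assoc:
            current = "smr"
            sres = smr_mod.smr_scan(
                egene_assoc, gwas, geno,
                instrument_p=config.smr["instrument_p"],
                r2_bounds=(config.smr["r2_min"], config.smr["r2_max"]),
            )
            if len(sres):
                _emit("smr", sres)

        if "share" in stages and len(assoc_by_ct) >= 2:
            current = "share"
            # effects of each cell type's union of top eVariants across contexts
            pairs = set()
            for ct, cs in calls.items():
                for _, r in cs.egenes.iterrows():
                    pairs.add((r["gene"], r["top_variant"]))
            if len(pairs) >= 2:
                eff, se = {}, {}
                for ct, assoc in assoc_by_ct.items():
                    idx = assoc.set_index(["gene", "variant"])
                    eff[ct] = [idx["beta"].get(p, np.nan) for p in sorted(pairs)]
                    se[ct] = [idx["se"].get(p, np.nan) for p in sorted(pairs)]
                names = [f"{g}:{v}" for g, v in sorted(pairs)]
                E = pd.DataFrame(eff, index=names).dropna()
                S = pd.DataFrame(se, index=names).loc[E.index]
                if len(E) >= 2:
                    model = eb_shrink(E, S, seed=seed + 23)
                    sh = pairwise_sharing(model.posterior_mean, model.lfsr)
                    _emit("sharing", sh.reset_index(names="context"))

        if "allelic" in stages and config.paths.get("allelic_counts"):
            current = "allelic"
            ac = pd.read_csv(config.paths["allelic_counts"], sep="\t")
            _emit("allelic_imbalance", allelic_imbalance(ac))

        if "varpart" in stages:
            current = "varpart"
            rng = np.random.default_rng(seed + 29)
            genes = list(cells.var_names)
            pick = list(rng.choice(genes, size=min(a["varpart_genes"], len(genes)),
                                   replace=False))
            rows = [fit_variance_components(cells, g, seed=seed + 31).as_row()
                    for g in pick]
            vt = pd.DataFrame(rows)
            _emit("variance_fractions", vt)
            _emit("variance_summary", variance_summary(vt))
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{current}' failed: {e}") from e

    bundle.write(outdir)
    return bundle
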
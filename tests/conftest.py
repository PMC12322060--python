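import numpy as np
import pandas as pd
import pytest

from sceqtl import (
    CellTruthSpec,
    compute_grm,
    default_design,
    expand_kinship,
    prune_ld,
    pseudobulk_aggregate,
    qc_and_normalize,
    simulate_cells,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def cis_geno():
    """Cis-region genotypes: 40 donors (2 duplicated pairs), 300 variants."""
    geno, truth = simulate_genotypes(
        n_donors=40, n_variants=300, ld_rho=0.6, n_duplicate_pairs=2, seed=11
    )
    return geno, truth


@pytest.fixture(scope="session")
def bg_kinship(cis_geno):
    """Donor kinship from a separate background variant set (second chrom)."""
    bg, _ = simulate_genotypes(
        n_donors=40, n_variants=500, ld_rho=0.6, n_duplicate_pairs=2,
        seed=1011, chrom="2",
    )
    return compute_grm(bg, prune_ld(bg))


@pytest.fixture(scope="session")
def null_cohort(cis_geno):
    """Null single-cell cohort (no genetic effects): QCed cells + pseudobulk."""
    geno, _ = cis_geno
    design = default_design(geno.donors, cells_per_sample=15, cell_types=("monocyte",))
    cells, truth = simulate_cells(geno, design, CellTruthSpec(n_genes=60), seed=12)
    cells = qc_and_normalize(cells, min_genes=5)
    return cells, pseudobulk_aggregate(cells), truth


@pytest.fixture(scope="session")
def gene_annot(null_cohort):
    cells, _, _ = null_cohort
    ga = cells.var[["chrom", "tss"]].copy()
    ga["chrom"] = ga["chrom"].astype(str)
    return ga


@pytest.fixture(scope="session")
def sample_kinship(bg_kinship, null_cohort):
    _, pb, _ = null_cohort
    _, meta = pb.context("monocyte")
    return expand_kinship(bg_kinship, meta["donor"])
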
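import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from blastomics import expression
from blastomics.synthetic import CohortConfig, generate_cohort


def small_config(seed: int = 7, **kwargs) -> CohortConfig:
    """A fast desk-scale cohort: light methylome, 1,200-gene transcriptome."""
    defaults = dict(
        n_embryos_per_group=4,
        cells_per_embryo=20,
        n_genes=1200,
        marker_genes_per_lineage=20,
        program_genes_per_lineage=150,
        meth_region_bp=6_000,
        aneuploid_cell_fraction=0.1,
        seed=seed,
    )
    defaults.update(kwargs)
    return CohortConfig(**defaults)


def prepare_expression(cohort, min_genes: int = 400):
    """Cell QC -> ln(TPM/10+1) -> gene filter, with truth lineage attached."""
    ad = expression.qc_filter_cells(cohort.expression, min_genes=min_genes)
    ad = expression.normalize_ln_tpm(ad)
    ad = expression.filter_genes(ad)
    ad.obs["lineage"] = cohort.truth.cells["lineage"].reindex(ad.obs_names)
    return ad


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def prepared(cohort):
    return prepare_expression(cohort)


def make_adata(counts, normalized: bool = False, groups=None, **var_cols) -> AnnData:
    """Tiny AnnData builder for hand-constructed examples."""
    counts = np.asarray(counts, dtype=float)
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(
        {
            "embryo_id": [f"E{i // 2}" for i in range(n_cells)],
            "group": groups if groups is not None else ["ST"] * n_cells,
        },
        index=[f"c{i}" for i in range(n_cells)],
    )
    var = pd.DataFrame(index=[f"g{j}" for j in range(n_genes)])
    var["chrom"] = var_cols.get("chrom", ["chr1"] * n_genes)
    var["start"] = var_cols.get("start", np.arange(n_genes) * 1000)
    var["end"] = var["start"] + 500
    ad = AnnData(X=counts, obs=obs, var=var)
    ad.uns["normalization"] = "lnTPM" if normalized else "raw"
    return ad
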
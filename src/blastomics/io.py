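"""On-disk cohort layout.

A cohort directory holds plain-text layers keyed by shared cell ids:

* ``counts.mtx`` + ``genes.tsv`` + ``cells.tsv`` — UMI matrix (MatrixMarket)
  with gene and cell metadata;
* ``meth_sites.tsv`` + ``meth_counts.tsv`` / ``meth_totals.tsv`` +
  ``meth_cells.tsv`` + ``lambda.tsv`` — dense per-cell CpG count matrices;
* ``windows.tsv`` + ``bin_counts.tsv`` — 1-Mb-window read counts;
* ``elements/<name>.bed`` — genomic element classes (BED4);
* ``truth_*.tsv`` / ``truth.json`` — planted ground truth;
* ``config.yaml`` — the generating configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from anndata import AnnData

from blastomics.cnv_methylation import BinCountMatrix
from blastomics.errors import DataError
from blastomics.methylome import MethylomeCohort
from blastomics.synthetic import Cohort, CohortConfig, SyntheticTruth


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ad = cohort.expression
    x = ad.X
    x = sp.csr_matrix(x) if not sp.issparse(x) else x
    sio.mmwrite(out / "counts.mtx", x, field="integer")
    ad.var.reset_index(names="gene").to_csv(out / "genes.tsv", sep="\t", index=False)
    ad.obs.reset_index(names="cell_id").to_csv(
        out / "cells.tsv", sep="\t", index=False
    )

    meth = cohort.methylome
    meth.sites.to_csv(out / "meth_sites.tsv", sep="\t", index=False)
    np.savetxt(out / "meth_counts.tsv", meth.meth, fmt="%d", delimiter="\t")
    np.savetxt(out / "meth_totals.tsv", meth.total, fmt="%d", delimiter="\t")
    meth.cells.reset_index(names="cell_id").to_csv(
        out / "meth_cells.tsv", sep="\t", index=False
    )
    meth.lambda_stats.reset_index().to_csv(out / "lambda.tsv", sep="\t", index=False)

    cohort.bins.windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    np.savetxt(out / "bin_counts.tsv", cohort.bins.counts, fmt="%d", delimiter="\t")

    cohort.genes.to_csv(out / "gene_annotation.tsv", sep="\t", index=False)
    elem_dir = out / "elements"
    elem_dir.mkdir(exist_ok=True)
    for name, df in cohort.elements.items():
        df[["chrom", "start", "end", "name"]].to_csv(
            elem_dir / f"{name}.bed", sep="\t", index=False, header=False
        )

    truth = cohort.truth
    truth.cells.reset_index(names="cell_id").to_csv(
        out / "truth_cells.tsv", sep="\t", index=False
    )
    truth.planted_cnvs.to_csv(out / "truth_cnvs.tsv", sep="\t", index=False)
    truth.planted_dmr_tiles.to_csv(out / "truth_dmr_tiles.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "embryo_sex": truth.embryo_sex.to_dict(),
                "marker_genes": truth.marker_genes,
                "program_genes": truth.program_genes,
                "deg_genes": truth.deg_genes,
                "te_methylation_offset": truth.te_methylation_offset,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    cohort.config.to_yaml(out / "config.yaml")
    return out


def read_cohort(indir: str | Path) -> Cohort:
    d = Path(indir)
    if not (d / "counts.mtx").exists():
        raise DataError(f"{d} is not a cohort directory (no counts.mtx)")
    config = CohortConfig.from_yaml(d / "config.yaml")
    counts = np.asarray(sio.mmread(d / "counts.mtx").todense()).astype(np.int64)
    genes = pd.read_csv(d / "genes.tsv", sep="\t")
    cells = pd.read_csv(d / "cells.tsv", sep="\t").set_index("cell_id")
    ad = AnnData(X=counts, obs=cells, var=genes.set_index("gene"))
    ad.uns["normalization"] = "raw"

    sites = pd.read_csv(d / "meth_sites.tsv", sep="\t")
    meth_counts = np.loadtxt(d / "meth_counts.tsv", dtype=np.int16, delimiter="\t")
    meth_totals = np.loadtxt(d / "meth_totals.tsv", dtype=np.int16, delimiter="\t")
    meth_cells = pd.read_csv(d / "meth_cells.tsv", sep="\t").set_index("cell_id")
    lam = pd.read_csv(d / "lambda.tsv", sep="\t").set_index("cell_id")
    meth = MethylomeCohort(
        sites=sites,
        meth=np.atleast_2d(meth_counts),
        total=np.atleast_2d(meth_totals),
        cells=meth_cells,
        lambda_stats=lam,
    )

    windows = pd.read_csv(d / "windows.tsv", sep="\t")
    bin_counts = np.atleast_2d(
        np.loadtxt(d / "bin_counts.tsv", dtype=np.int64, delimiter="\t")
    )
    bins = BinCountMatrix(counts=bin_counts, windows=windows, cells=meth_cells.copy())

    gene_annot = pd.read_csv(d / "gene_annotation.tsv", sep="\t")
    elements = {}
    for bed in sorted((d / "elements").glob("*.bed")):
        elements[bed.stem] = pd.read_csv(
            bed, sep="\t", names=["chrom", "start", "end", "name"]
        )

    truth_cells = pd.read_csv(d / "truth_cells.tsv", sep="\t").set_index("cell_id")
    cnvs = pd.read_csv(d / "truth_cnvs.tsv", sep="\t")
    dmr = pd.read_csv(d / "truth_dmr_tiles.tsv", sep="\t")
    with open(d / "truth.json") as fh:
        tj = json.load(fh)
    truth = SyntheticTruth(
        cells=truth_cells,
        embryo_sex=pd.Series(tj["embryo_sex"], name="sex"),
        planted_cnvs=cnvs,
        planted_dmr_tiles=dmr,
        marker_genes=tj["marker_genes"],
        program_genes=tj["program_genes"],
        deg_genes=tj["deg_genes"],
        te_methylation_offset=tj["te_methylation_offset"],
    )
    return Cohort(
        expression=ad,
        methylome=meth,
        bins=bins,
        genes=gene_annot,
        elements=elements,
        truth=truth,
        config=config,
    )


def export_bedgraph(meth: MethylomeCohort, cell_id: str, path: str | Path) -> None:
    """Write one cell's covered CpG sites as a bedGraph-like TSV."""
    sub = meth.to_frame()
    sub = sub[sub["cell_id"] == cell_id].drop(columns="cell_id")
    sub.to_csv(path, sep="\t", index=False)
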
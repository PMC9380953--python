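"""Copy-number inference from smoothed single-cell expression.

Following the moving-average approach of expression-based CNV callers, a
per-gene CNV score is the mean relative expression of the 50 genes
upstream and 50 genes downstream (same chromosome, truncated at the
ends, self included), normalized per gene to the mean score across all
cells — so a diploid region scores ~1 and a whole-chromosome gain at
1.5x dosage scores ~1.5.

Smoothing operates on the linear relative-expression scale (the
back-transform ``exp(value) - 1`` of the ln(TPM/10+1) matrix): ratios of
log-scale values compress dosage toward 1 and would not separate a 1.5x
gain from noise at any fixed threshold, whereas linear ratios track copy
number directly.

Denoising of the resulting calls keeps a chromosome-level event only when
its span exceeds 60% of the chromosome length and at least 3 cells in the
cohort carry a same-direction call on that chromosome; an embryo-level
event additionally needs at least 3 supporting cells within the embryo.
Cells without any retained call are euploid; the CNV frequency of an
embryo is its fraction of aneuploid cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from blastomics.errors import DataError

log = logging.getLogger(__name__)


@dataclass
class CnvScoreMatrix:
    """Smoothed, cell-mean-normalized CNV scores (cells x ordered genes)."""

    scores: pd.DataFrame  # index cell_id, columns gene names in genome order
    genes: pd.DataFrame  # chrom, start, end per gene, in the same order


@dataclass
class PloidySummary:
    """Euploid/aneuploid classification and embryo-level CNV summary."""

    cell_calls: pd.DataFrame  # cell_id, chrom, direction, span_fraction, ...
    aneuploid: pd.Series  # cell_id -> bool
    cnv_frequency: pd.Series  # embryo_id -> aneuploid-cell fraction
    embryo_cnvs: pd.DataFrame = field(default_factory=pd.DataFrame)


def cnv_scores(
    adata: AnnData,
    window: int = 50,
    min_genes_per_chrom: int = 5,
) -> CnvScoreMatrix:
    """Moving-average CNV score per cell and gene.

    Requires gene coordinates in ``var`` and a ln(TPM/10+1) matrix. Genes
    are ordered by (chrom, start); chromosomes with fewer than
    ``min_genes_per_chrom`` genes are excluded with a warning.
    """
    if adata.uns.get("normalization") != "lnTPM":
        raise DataError("cnv_scores requires a ln(TPM/10+1)-normalized matrix")
    var = adata.var
    if not {"chrom", "start"}.issubset(var.columns):
        raise DataError("cnv_scores requires chrom/start gene coordinates")
    order = np.lexsort((var["start"].to_numpy(), var["chrom"].to_numpy()))
    adata = adata[:, order]
    var = adata.var
    x = adata.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    rel = np.expm1(x)  # linear relative expression (TPM/10)

    chroms = var["chrom"].to_numpy()
    keep_cols = np.ones(len(var), dtype=bool)
    smoothed = np.empty_like(rel)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        n = int(mask.sum())
        if n < min_genes_per_chrom:
            warnings.warn(
                f"chromosome {chrom} has {n} genes (<{min_genes_per_chrom}); excluded",
                stacklevel=2,
            )
            keep_cols[mask] = False
            continue
        block = rel[:, mask]
        csum = np.cumsum(block, axis=1)
        csum = np.hstack([np.zeros((block.shape[0], 1)), csum])
        j = np.arange(n)
        lo = np.maximum(0, j - window)
        hi = np.minimum(n, j + window + 1)
        smoothed[:, mask] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    rel_sm = smoothed[:, keep_cols]
    gene_mean = rel_sm.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(gene_mean > 0, rel_sm / np.where(gene_mean > 0, gene_mean, 1), 1.0)
    genes = var.loc[keep_cols, ["chrom", "start", "end"]].copy()
    return CnvScoreMatrix(
        scores=pd.DataFrame(
            scores, index=adata.obs_names, columns=adata.var_names[keep_cols]
        ),
        genes=genes,
    )


def _runs(mask: np.ndarray):
    """Yield (start_idx, end_idx_inclusive) of maximal True runs."""
    if not mask.any():
        return
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    yield from zip(starts, ends)


def call_cnvs(
    s: CnvScoreMatrix,
    chrom_lengths: dict[str, int],
    embryo_of: pd.Series,
    gain_thr: float = 1.15,
    loss_thr: float = 0.85,
    min_span: float = 0.6,
    min_cells: int = 3,
    min_run_genes: int = 20,
    exclude_chroms: tuple[str, ...] = ("chrX", "chrY"),
    span_units: str = "bp",
) -> PloidySummary:
    """Chromosome-level gain/loss calls with cohort- and embryo-level denoising.

    Per cell and chromosome, the longest contiguous gene run beyond the
    gain (or loss) threshold is a candidate call; it is kept when the run
    has at least ``min_run_genes`` genes and spans more than ``min_span``
    of the chromosome (in bp by default, or as a gene-count fraction with
    ``span_units="genes"``). Cohort denoising then drops chromosome calls
    carried by fewer than ``min_cells`` same-direction cells; embryo-level
    CNVs additionally need ``min_cells`` supporting cells in that embryo.

    Sex chromosomes are excluded by default: their expression dosage tracks
    embryo sex, not aneuploidy.
    """
    if not loss_thr < 1 < gain_thr:
        raise DataError("thresholds must satisfy loss_thr < 1 < gain_thr")
    chroms = s.genes["chrom"].to_numpy()
    starts = s.genes["start"].to_numpy()
    ends = s.genes["end"].to_numpy()
    scores = s.scores.to_numpy()
    records = []
    for chrom in pd.unique(chroms):
        if chrom in exclude_chroms:
            continue
        mask = chroms == chrom
        length = chrom_lengths[chrom]
        g_start, g_end = starts[mask], ends[mask]
        n_genes = int(mask.sum())
        block = scores[:, mask]
        for i, cell in enumerate(s.scores.index):
            for direction, hit in (
                ("gain", block[i] > gain_thr),
                ("loss", block[i] < loss_thr),
            ):
                best = None
                for r0, r1 in _runs(hit):
                    if r1 - r0 + 1 < min_run_genes:
                        continue
                    if span_units == "genes":
                        frac = (r1 - r0 + 1) / n_genes
                    else:
                        frac = (g_end[r1] - g_start[r0]) / length
                    if best is None or frac > best[0]:
                        best = (frac, r0, r1)
                if best is not None and best[0] > min_span:
                    frac, r0, r1 = best
                    records.append(
                        {
                            "cell_id": cell,
                            "chrom": chrom,
                            "direction": direction,
                            "span_fraction": float(frac),
                            "n_genes_in_run": int(r1 - r0 + 1),
                            "mean_score": float(block[i, r0 : r1 + 1].mean()),
                            "start_bp": int(g_start[r0]),
                            "end_bp": int(g_end[r1]),
                        }
                    )
    calls = pd.DataFrame(
        records,
        columns=[
            "cell_id",
            "chrom",
            "direction",
            "span_fraction",
            "n_genes_in_run",
            "mean_score",
            "start_bp",
            "end_bp",
        ],
    )
    # cohort-level denoising: >= min_cells same-direction cells per chromosome
    if len(calls):
        support = calls.groupby(["chrom", "direction"])["cell_id"].transform("nunique")
        calls = calls[support >= min_cells].reset_index(drop=True)

    aneuploid = pd.Series(False, index=s.scores.index, name="aneuploid")
    if len(calls):
        aneuploid[calls["cell_id"].unique()] = True
    embryos = embryo_of.reindex(s.scores.index)
    cnv_frequency = aneuploid.groupby(embryos).mean()
    cnv_frequency.name = "cnv_frequency"

    if len(calls):
        with_embryo = calls.assign(embryo_id=embryos[calls["cell_id"]].to_numpy())
        emb = (
            with_embryo.groupby(["embryo_id", "chrom", "direction"])
            .agg(n_cells=("cell_id", "nunique"))
            .reset_index()
        )
        embryo_cnvs = emb[emb["n_cells"] >= min_cells].reset_index(drop=True)
    else:
        embryo_cnvs = pd.DataFrame(
            columns=["embryo_id", "chrom", "direction", "n_cells"]
        )
    return PloidySummary(
        cell_calls=calls,
        aneuploid=aneuploid,
        cnv_frequency=cnv_frequency,
        embryo_cnvs=embryo_cnvs,
    )


def chromosome_states(
    ploidy: PloidySummary, chromosomes: list[str]
) -> pd.DataFrame:
    """Cell x chromosome gain/loss/normal table from retained calls."""
    states = pd.DataFrame(
        "normal", index=ploidy.aneuploid.index, columns=chromosomes
    )
    for _, row in ploidy.cell_calls.iterrows():
        if row["chrom"] in states.columns:
            states.loc[row["cell_id"], row["chrom"]] = row["direction"]
    return states


def integrate_dosage(
    adata: AnnData,
    ploidy: PloidySummary,
    exclude_chroms: tuple[str, ...] = ("chrX", "chrY"),
) -> pd.DataFrame:
    """Per-chromosome relative expression stratified by copy-number state.

    For each cell, the mean normalized expression of each chromosome is
    divided by the mean over that cell's normal (copy-2) chromosomes, so
    normal chromosomes average 1 and gains/losses show their dosage shift.
    Cells with no normal chromosome are excluded with a warning.
    """
    if adata.uns.get("normalization") != "lnTPM":
        raise DataError("integrate_dosage requires a normalized matrix")
    chroms = [
        c for c in pd.unique(adata.var["chrom"]) if c not in exclude_chroms
    ]
    x = adata.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    chrom_means = pd.DataFrame(index=adata.obs_names, columns=chroms, dtype=float)
    for chrom in chroms:
        mask = (adata.var["chrom"] == chrom).to_numpy()
        chrom_means[chrom] = x[:, mask].mean(axis=1)
    states = chromosome_states(ploidy, chroms).reindex(adata.obs_names)
    rows = []
    n_excluded = 0
    for cell in adata.obs_names:
        normal = [c for c in chroms if states.loc[cell, c] == "normal"]
        if not normal:
            n_excluded += 1
            continue
        baseline = chrom_means.loc[cell, normal].mean()
        for chrom in chroms:
            rows.append(
                {
                    "cell_id": cell,
                    "chrom": chrom,
                    "state": states.loc[cell, chrom],
                    "relative_expression": float(
                        chrom_means.loc[cell, chrom] / baseline
                    ),
                }
            )
    if n_excluded:
        warnings.warn(
            f"{n_excluded} cell(s) with no normal chromosome excluded",
            stacklevel=2,
        )
    return pd.DataFrame(rows)
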
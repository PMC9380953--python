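"""Expression-matrix QC, normalization, and embedding plumbing.

The in-memory container is an :class:`anndata.AnnData` with raw UMI counts
in ``X`` (and, after normalization, in ``layers["counts"]``), per-cell
metadata in ``obs`` (``embryo_id``, ``group``, optionally ``lineage`` /
``sex``) and gene coordinates in ``var`` (``chrom``, ``start``, ``end``,
``strand``). ``uns["normalization"]`` tracks the state (``raw`` or
``lnTPM``).

The fixed preprocessing order is cell QC -> ln(TPM/10+1) normalization ->
gene filtering.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from anndata import AnnData

from blastomics.errors import DataError

log = logging.getLogger(__name__)


def _dense(adata: AnnData) -> np.ndarray:
    x = adata.X
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


def _require_state(adata: AnnData, state: str, op: str) -> None:
    actual = adata.uns.get("normalization", "raw")
    if actual != state:
        raise DataError(
            f"{op} requires a {state} matrix (normalization state is {actual!r})"
        )


def qc_filter_cells(adata: AnnData, min_genes: int = 4000) -> AnnData:
    """Remove cells detecting fewer than ``min_genes`` genes.

    A gene is detected in a cell when its UMI count is > 0; cells with at
    least ``min_genes`` detected genes are retained. The removed cell ids
    are recorded in ``uns["qc_removed_cells"]``.
    """
    _require_state(adata, "raw", "qc_filter_cells")
    if adata.n_obs == 0:
        raise DataError("qc_filter_cells: empty expression matrix")
    x = _dense(adata)
    detected = (x > 0).sum(axis=1)
    keep = detected >= min_genes
    removed = list(adata.obs_names[~keep])
    if not keep.any():
        warnings.warn("qc_filter_cells removed every cell", stacklevel=2)
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = detected[keep]
    out.uns["qc_removed_cells"] = removed
    log.info("cell QC: retained %d/%d cells", int(keep.sum()), adata.n_obs)
    return out


def normalize_ln_tpm(adata: AnnData) -> AnnData:
    """Normalize UMI counts to ln(TPM/10 + 1).

    TPM here is counts-per-million of the cell's total UMIs (UMIs already
    count transcripts, so no length term). Raw counts are preserved in
    ``layers["counts"]``.
    """
    _require_state(adata, "raw", "normalize_ln_tpm")
    x = _dense(adata).astype(float)
    totals = x.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = list(adata.obs_names[zero])
        raise DataError(f"cells with zero total counts cannot be normalized: {bad}")
    tpm = x / totals[:, None] * 1e6
    out = adata.copy()
    out.layers["counts"] = x
    out.X = np.log1p(tpm / 10.0)
    out.uns["normalization"] = "lnTPM"
    return out


def filter_genes(adata: AnnData, level: float = 1.0, min_cells: int = 3) -> AnnData:
    """Keep genes expressed above ``level`` in more than ``min_cells`` cells.

    Both comparisons are strict: a gene is kept when its normalized value
    exceeds ``level`` in strictly more than ``min_cells`` cells.
    """
    _require_state(adata, "lnTPM", "filter_genes")
    x = _dense(adata)
    n_above = (x > level).sum(axis=0)
    keep = n_above > min_cells
    out = adata[:, keep].copy()
    log.info("gene filter: retained %d/%d genes", int(keep.sum()), adata.n_vars)
    return out


def embed_cells(
    adata: AnnData,
    method: str = "pca",
    seed: int = 0,
    n_comps: int = 30,
) -> np.ndarray:
    """Embed cells by PCA, t-SNE, or UMAP (deterministic given ``seed``).

    t-SNE and UMAP are run on the PCA representation, mirroring the usual
    linear-then-nonlinear reduction. Returns one coordinate row per cell.
    """
    import scanpy as sc

    _require_state(adata, "lnTPM", "embed_cells")
    n_comps = min(n_comps, adata.n_obs - 1, adata.n_vars - 1)
    if n_comps < 1:
        raise DataError("embed_cells: fewer cells than components")
    work = adata.copy()
    sc.pp.pca(work, n_comps=n_comps, random_state=seed)
    if method == "pca":
        return work.obsm["X_pca"][:, : min(2, n_comps)].copy()
    if method == "tsne":
        sc.tl.tsne(work, random_state=seed, use_rep="X_pca")
        return work.obsm["X_tsne"].copy()
    if method == "umap":
        sc.pp.neighbors(work, random_state=seed, use_rep="X_pca")
        sc.tl.umap(work, random_state=seed)
        return work.obsm["X_umap"].copy()
    raise DataError(f"unknown embedding method {method!r}")


def tpm_conservation_check(adata: AnnData, atol: float = 1e-6) -> bool:
    """Verify per-cell TPM conservation: sum_g 10*(exp(value)-1) == 1e6."""
    _require_state(adata, "lnTPM", "tpm_conservation_check")
    x = _dense(adata)
    totals = (np.expm1(x) * 10.0).sum(axis=1)
    return bool(np.allclose(totals, 1e6, atol=atol * 1e6))
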
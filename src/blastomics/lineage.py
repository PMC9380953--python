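"""Blastocyst lineage assignment and scoring.

Cells are clustered (graph partitioning tuned to three clusters, with a
k-means fallback), each cluster is labeled with the lineage whose
canonical marker set has the highest mean expression over the cluster,
lineage-specific signatures are found by one-vs-rest Wilcoxon tests, and
per-cell lineage scores (mean signature expression, min-max rescaled to
[1, 100]) give ternary coordinates for simplex plots.

Canonical high-confidence markers: SOX2/NANOG/POU5F1 for the epiblast
(EPI), GATA4/SOX17/FOXA2 for the primitive endoderm (PE), and
GATA2/GATA3/CDX2 for the trophectoderm (TE).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from blastomics.errors import DataError
from blastomics.stats import bonferroni, wilcoxon_pvalues

log = logging.getLogger(__name__)

LINEAGES = ("EPI", "PE", "TE")

CANONICAL_MARKERS: dict[str, list[str]] = {
    "EPI": ["SOX2", "NANOG", "POU5F1"],
    "PE": ["GATA4", "SOX17", "FOXA2"],
    "TE": ["GATA2", "GATA3", "CDX2"],
}


def validate_marker_set(markers: dict[str, list[str]]) -> None:
    seen: set[str] = set()
    for lineage, genes in markers.items():
        if not genes:
            raise DataError(f"marker set for {lineage} is empty")
        if seen & set(genes):
            raise DataError("marker sets are not mutually disjoint")
        seen |= set(genes)


def cluster_cells(adata: AnnData, n_clusters: int = 3, seed: int = 0) -> pd.Series:
    """Partition cells into ``n_clusters`` clusters.

    Leiden clustering on the PCA neighbor graph, searching the resolution
    for exactly ``n_clusters`` communities; falls back to k-means on the
    PCA representation when no resolution yields that count.
    """
    import scanpy as sc

    work = adata.copy()
    n_comps = min(30, work.n_obs - 1, work.n_vars - 1)
    sc.pp.pca(work, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(work, random_state=seed, use_rep="X_pca")
    lo, hi = 0.01, 3.0
    for _ in range(12):
        res = (lo + hi) / 2
        sc.tl.leiden(
            work,
            resolution=res,
            random_state=seed,
            key_added="leiden",
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
        k = work.obs["leiden"].nunique()
        if k == n_clusters:
            return pd.Series(
                work.obs["leiden"].astype(str).to_numpy(), index=adata.obs_names
            )
        if k < n_clusters:
            lo = res
        else:
            hi = res
    from sklearn.cluster import KMeans

    log.info("leiden did not yield %d clusters; falling back to k-means", n_clusters)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(work.obsm["X_pca"])
    return pd.Series(labels.astype(str), index=adata.obs_names)


def assign_lineages(
    adata: AnnData,
    clusters: pd.Series,
    markers: dict[str, list[str]] | None = None,
) -> pd.Series:
    """Label each cluster with the lineage of its top-scoring marker set.

    The cluster's score for a lineage is the mean normalized expression of
    that lineage's marker genes over the cluster's cells; every cell
    inherits its cluster's label. An exact tie raises an error requesting
    manual resolution.
    """
    markers = markers or CANONICAL_MARKERS
    validate_marker_set(markers)
    clusters = clusters.reindex(adata.obs_names)
    if clusters.isna().any():
        raise DataError("every cell must be clustered before lineage assignment")
    x = adata.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    marker_idx = {}
    for lineage, genes in markers.items():
        present = [g for g in genes if g in adata.var_names]
        if not present:
            raise DataError(f"no marker genes of {lineage} present in the matrix")
        marker_idx[lineage] = adata.var_names.get_indexer(present)
    labels = {}
    for cluster in pd.unique(clusters):
        rows = (clusters == cluster).to_numpy()
        scores = {
            lineage: float(x[np.ix_(rows, idx)].mean())
            for lineage, idx in marker_idx.items()
        }
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            raise DataError(
                f"cluster {cluster}: tie between {ranked[0][0]} and {ranked[1][0]} "
                "marker scores; resolve manually"
            )
        labels[cluster] = ranked[0][0]
    return clusters.map(labels)


def find_signatures(
    adata: AnnData,
    labels: pd.Series,
    min_pct: float = 0.25,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> dict[str, pd.DataFrame]:
    """Lineage-specific signatures by one-vs-rest Wilcoxon rank-sum tests.

    Genes detected in at least ``min_pct`` of cells on either side of the
    contrast are tested; genes with positive enrichment (log2 fold change
    > 0 on back-transformed means) and Bonferroni-adjusted p < ``alpha``
    form the signature, ranked by fold change. Lineages with fewer than
    ``min_cells`` cells are excluded with a warning.
    """
    labels = labels.reindex(adata.obs_names)
    present = [l for l in pd.unique(labels.dropna())]
    if len(present) < 2:
        raise DataError("find_signatures requires at least 2 lineages")
    x = adata.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    out: dict[str, pd.DataFrame] = {}
    for lineage in present:
        in_mask = (labels == lineage).to_numpy()
        if in_mask.sum() < min_cells:
            warnings.warn(
                f"lineage {lineage} has <{min_cells} cells; excluded", stacklevel=2
            )
            continue
        xg, xr = x[in_mask], x[~in_mask]
        pct_in = (xg > 0).mean(axis=0)
        pct_rest = (xr > 0).mean(axis=0)
        tested = (pct_in >= min_pct) | (pct_rest >= min_pct)
        p = wilcoxon_pvalues(xg[:, tested], xr[:, tested])
        p_adj = bonferroni(p, int(tested.sum()))
        lfc = log2_fold_change(xg[:, tested], xr[:, tested])
        df = pd.DataFrame(
            {
                "gene": adata.var_names[tested],
                "log2_fold_change": lfc,
                "pct_in": pct_in[tested],
                "pct_rest": pct_rest[tested],
                "p_raw": p,
                "p_adj": p_adj,
            }
        )
        sig = df[(df["p_adj"] < alpha) & (df["log2_fold_change"] > 0)]
        out[lineage] = sig.sort_values(
            "log2_fold_change", ascending=False
        ).reset_index(drop=True)
    return out


def log2_fold_change(
    x_a: np.ndarray, x_b: np.ndarray, method: str = "seurat"
) -> np.ndarray:
    """Column-wise log2 fold change between two groups of ln(TPM/10+1) values.

    ``seurat``: log2((mean(exp(x)-1) + 1) / (mean(exp(y)-1) + 1)), i.e.
    back-transformed means with a pseudocount of 1. ``mean_diff``: the
    difference of ln-scale means divided by ln(2).
    """
    if method == "seurat":
        a = np.expm1(x_a).mean(axis=0) + 1.0
        b = np.expm1(x_b).mean(axis=0) + 1.0
        return np.log2(a) - np.log2(b)
    if method == "mean_diff":
        return (x_a.mean(axis=0) - x_b.mean(axis=0)) / np.log(2)
    raise DataError(f"unknown fold-change method {method!r}")


@dataclass
class LineageScores:
    """Per-cell lineage scores on raw, [1, 100], and ternary scales."""

    raw: pd.DataFrame  # cells x lineages, mean signature expression
    scaled: pd.DataFrame  # cells x lineages, min-max rescaled to [1, 100]
    ternary: pd.DataFrame  # cells x lineages, rows sum to 1
    assigned: pd.Series  # cell -> lineage with the largest ternary component


def lineage_scores(
    adata: AnnData, signatures: dict[str, list[str] | pd.DataFrame]
) -> LineageScores:
    """Lineage scores: mean signature expression, rescaled to [1, 100].

    The raw score of a cell for a lineage is the mean normalized
    expression of the lineage's signature genes; scores are min-max
    rescaled per lineage across all cells onto [1, 100]
    (x -> 1 + 99 (x - min) / (max - min)); the ternary coordinate divides
    each scaled score by the sum of the three.
    """
    x = adata.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    raw = {}
    for lineage, sig in signatures.items():
        genes = sig["gene"].tolist() if isinstance(sig, pd.DataFrame) else list(sig)
        present = [g for g in genes if g in adata.var_names]
        if not present:
            raise DataError(f"signature for {lineage} has no genes in the matrix")
        idx = adata.var_names.get_indexer(present)
        raw[lineage] = x[:, idx].mean(axis=1)
    raw_df = pd.DataFrame(raw, index=adata.obs_names)
    lo, hi = raw_df.min(axis=0), raw_df.max(axis=0)
    if (hi - lo == 0).any():
        const = list(raw_df.columns[(hi - lo) == 0])
        raise DataError(f"constant raw score across cells for {const}; cannot rescale")
    scaled = 1.0 + 99.0 * (raw_df - lo) / (hi - lo)
    ternary = scaled.div(scaled.sum(axis=1), axis=0)
    return LineageScores(
        raw=raw_df,
        scaled=scaled,
        ternary=ternary,
        assigned=ternary.idxmax(axis=1),
    )
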
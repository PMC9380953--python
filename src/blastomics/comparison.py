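"""ST-vs-ICSI group comparisons.

Per-lineage differential expression with Wilcoxon rank-sum tests and
Bonferroni correction (a DEG needs |log2 fold change| > 1 and adjusted
p < 0.01), regression similarity of group mean expression (R^2 of the
per-gene mean(ST) vs mean(ICSI) fit), down-sampling of that similarity,
gene-level expression variance summaries, embryo sexing by the
Mean_X/Mean_Y ratio, and the sex-ratio simulation quantifying how the
sex composition of the ST group drives sex-linked DEG calls.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats as sps

from blastomics.errors import DataError
from blastomics.lineage import log2_fold_change
from blastomics.stats import bonferroni, wilcoxon_pvalues

log = logging.getLogger(__name__)

GROUPS = ("ST", "ICSI")


def _dense(adata: AnnData) -> np.ndarray:
    x = adata.X
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


def _lineage_mask(adata: AnnData, lineage: str | None) -> np.ndarray:
    if lineage is None:
        return np.ones(adata.n_obs, dtype=bool)
    if "lineage" not in adata.obs:
        raise DataError("obs['lineage'] is required for per-lineage analyses")
    return (adata.obs["lineage"] == lineage).to_numpy()


def deg_test(
    adata: AnnData,
    lineage: str | None,
    min_pct: float = 0.25,
    alpha: float = 0.01,
    lfc_threshold: float = 1.0,
    fc_method: str = "seurat",
) -> pd.DataFrame:
    """ST-vs-ICSI differential expression within a lineage.

    Genes detected in at least ``min_pct`` of cells in either group are
    tested by a two-sided Wilcoxon rank-sum test; p-values are Bonferroni
    adjusted over the tested genes. ``direction`` is ``up`` (higher in ST)
    when log2FC > ``lfc_threshold`` and p_adj < ``alpha``, ``down`` when
    log2FC < -``lfc_threshold`` and p_adj < ``alpha``, else ``ns``.
    """
    if adata.uns.get("normalization") != "lnTPM":
        raise DataError("deg_test requires a normalized matrix")
    mask = _lineage_mask(adata, lineage)
    sub = adata[mask]
    groups = sub.obs["group"]
    st = (groups == "ST").to_numpy()
    icsi = (groups == "ICSI").to_numpy()
    if st.sum() < 3 or icsi.sum() < 3:
        raise DataError(
            f"lineage {lineage!r} needs >=3 cells per group "
            f"(ST={int(st.sum())}, ICSI={int(icsi.sum())})"
        )
    x = _dense(sub)
    x_st, x_icsi = x[st], x[icsi]
    pct_st = (x_st > 0).mean(axis=0)
    pct_icsi = (x_icsi > 0).mean(axis=0)
    tested = (pct_st >= min_pct) | (pct_icsi >= min_pct)
    if min_pct <= 0:
        tested = np.ones(sub.n_vars, dtype=bool)
    n_tested = int(tested.sum())
    p = wilcoxon_pvalues(x_st[:, tested], x_icsi[:, tested])
    p_adj = bonferroni(p, n_tested)
    lfc = log2_fold_change(x_st[:, tested], x_icsi[:, tested], method=fc_method)
    direction = np.where(
        (p_adj < alpha) & (lfc > lfc_threshold),
        "up",
        np.where((p_adj < alpha) & (lfc < -lfc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": sub.var_names[tested],
            "lineage": lineage,
            "mean_ST": x_st[:, tested].mean(axis=0),
            "mean_ICSI": x_icsi[:, tested].mean(axis=0),
            "log2_fold_change": lfc,
            "pct_ST": pct_st[tested],
            "pct_ICSI": pct_icsi[tested],
            "p_raw": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    )


def _group_means(adata: AnnData, lineage: str | None):
    mask = _lineage_mask(adata, lineage)
    sub = adata[mask]
    x = _dense(sub)
    st = (sub.obs["group"] == "ST").to_numpy()
    icsi = (sub.obs["group"] == "ICSI").to_numpy()
    if not st.any() or not icsi.any():
        raise DataError(f"lineage {lineage!r} absent from a group")
    common = ((x[st] > 0).any(axis=0)) & ((x[icsi] > 0).any(axis=0))
    return x[st][:, common].mean(axis=0), x[icsi][:, common].mean(axis=0)


def regression_similarity(adata: AnnData, lineage: str | None) -> float:
    """R^2 of the per-gene mean(ST) ~ mean(ICSI) least-squares fit.

    Computed over commonly expressed genes: genes detected in at least one
    cell of each group within the lineage.
    """
    mean_st, mean_icsi = _group_means(adata, lineage)
    if mean_st.size < 2:
        raise DataError("regression requires >= 2 commonly expressed genes")
    if np.std(mean_icsi) == 0 or np.std(mean_st) == 0:
        raise DataError("degenerate (constant) group means")
    fit = sps.linregress(mean_icsi, mean_st)
    return float(fit.rvalue**2)


def downsample_similarity(
    adata: AnnData,
    lineage: str | None,
    sizes: list[int],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Regression similarity after down-sampling each group to given sizes.

    For each size, ``reps`` subsamples without replacement are drawn per
    group and the R^2 recomputed; returns (size, mean R^2, sd).
    """
    mask = _lineage_mask(adata, lineage)
    sub = adata[mask]
    st_cells = sub.obs_names[(sub.obs["group"] == "ST").to_numpy()]
    icsi_cells = sub.obs_names[(sub.obs["group"] == "ICSI").to_numpy()]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > len(st_cells) or size > len(icsi_cells):
            raise DataError(
                f"requested size {size} exceeds available cells "
                f"(ST={len(st_cells)}, ICSI={len(icsi_cells)})"
            )
        r2s = []
        for _ in range(reps):
            pick = list(rng.choice(st_cells, size, replace=False)) + list(
                rng.choice(icsi_cells, size, replace=False)
            )
            r2s.append(regression_similarity(sub[pick], lineage=None if "lineage" not in sub.obs else lineage))
        rows.append(
            {
                "size": size,
                "mean_r2": float(np.mean(r2s)),
                "sd_r2": float(np.std(r2s, ddof=1)) if reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def expression_variance(adata: AnnData) -> pd.DataFrame:
    """Per-gene SD of normalized expression within each lineage x group.

    Returns a long table (lineage, group, gene, sd) plus distribution
    summaries are easily derived by the caller; sample SD (ddof=1).
    """
    if "lineage" not in adata.obs:
        raise DataError("obs['lineage'] is required")
    x = _dense(adata)
    rows = []
    for lineage in pd.unique(adata.obs["lineage"].dropna()):
        for group in GROUPS:
            m = (
                (adata.obs["lineage"] == lineage) & (adata.obs["group"] == group)
            ).to_numpy()
            if m.sum() < 2:
                continue
            sd = x[m].std(axis=0, ddof=1)
            rows.append(
                pd.DataFrame(
                    {
                        "lineage": lineage,
                        "group": group,
                        "gene": adata.var_names,
                        "sd": sd,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def infer_sex(
    adata: AnnData,
    x_genes: list[str] | None = None,
    y_genes: list[str] | None = None,
    ratio_threshold: float = 2.0,
) -> pd.DataFrame:
    """Sex each embryo by the ratio of mean X- to mean Y-linked expression.

    Mean_X (Mean_Y) is the mean normalized expression of the X-linked
    (Y-linked) genes over the embryo's cells; an embryo is female iff
    Mean_X / Mean_Y > 2 (a zero Mean_Y yields an infinite ratio, i.e.
    female, and is logged).
    """
    derived_y = y_genes is None
    if x_genes is None:
        x_genes = list(adata.var_names[adata.var.get("is_X_linked", pd.Series(False, index=adata.var_names)).astype(bool)])
    if y_genes is None:
        y_genes = list(adata.var_names[adata.var.get("is_Y_linked", pd.Series(False, index=adata.var_names)).astype(bool)])
    if not x_genes or (not y_genes and not derived_y):
        raise DataError("X- and Y-linked gene lists must be non-empty")
    x = _dense(adata)
    xi = adata.var_names.get_indexer([g for g in x_genes if g in adata.var_names])
    yi = adata.var_names.get_indexer([g for g in y_genes if g in adata.var_names])
    if xi.size == 0:
        raise DataError("no X-linked genes present in the matrix")
    rows = []
    for embryo, cells in adata.obs.groupby("embryo_id", observed=True).groups.items():
        rowmask = adata.obs_names.get_indexer(cells)
        mean_x = float(x[np.ix_(rowmask, xi)].mean())
        # a Y-linked gene silent everywhere (e.g. all-female cohort) may not
        # survive gene filtering; absence of Y signal means Mean_Y = 0
        mean_y = float(x[np.ix_(rowmask, yi)].mean()) if yi.size else 0.0
        if mean_y == 0:
            ratio = np.inf
            log.info("embryo %s: Mean_Y = 0, ratio treated as +inf", embryo)
        else:
            ratio = mean_x / mean_y
        rows.append(
            {
                "embryo_id": embryo,
                "mean_X": mean_x,
                "mean_Y": mean_y,
                "ratio": ratio,
                "sex": "female" if ratio > ratio_threshold else "male",
            }
        )
    return pd.DataFrame(rows).set_index("embryo_id")


def sex_ratio_simulation(
    adata: AnnData,
    female_counts_to_test: list[int],
    reps: int = 3,
    seed: int = 0,
    lineage: str = "TE",
    embryo_sex: pd.Series | None = None,
    min_pct: float = 0.25,
) -> pd.DataFrame:
    """Sex-linked DEG fraction as a function of ST-group sex composition.

    All male ST embryos are kept and ``n_female`` female ST embryos are
    added for each tested composition (varying the female count is what
    changes the sex ratio; the male embryos are the scarcer side). The DEG
    test is rerun within ``lineage`` against the full ICSI group and the
    fraction of DEGs that are X- or Y-linked is recorded, averaged over
    ``reps`` draws of the female subset.
    """
    if embryo_sex is None:
        embryo_sex = infer_sex(adata)["sex"]
    obs = adata.obs
    st_embryos = obs.loc[obs["group"] == "ST", "embryo_id"].unique()
    females = [e for e in st_embryos if embryo_sex.get(e) == "female"]
    males = [e for e in st_embryos if embryo_sex.get(e) == "male"]
    sex_linked = (
        adata.var.get("is_X_linked", pd.Series(False, index=adata.var_names)).astype(bool)
        | adata.var.get("is_Y_linked", pd.Series(False, index=adata.var_names)).astype(bool)
    )
    rng = np.random.default_rng(seed)
    rows = []
    for n_female in female_counts_to_test:
        if n_female > len(females):
            raise DataError(
                f"composition with {n_female} female ST embryos unavailable "
                f"({len(females)} female ST embryos present)"
            )
        fracs, n_degs = [], []
        for _ in range(reps):
            chosen = list(rng.choice(females, n_female, replace=False)) + males
            keep = (obs["group"] == "ICSI") | obs["embryo_id"].isin(chosen)
            sub = adata[keep.to_numpy()]
            degs = deg_test(sub, lineage=lineage, min_pct=min_pct)
            hits = degs[degs["direction"] != "ns"]
            n_degs.append(len(hits))
            if len(hits) == 0:
                fracs.append(0.0)
            else:
                fracs.append(
                    float(sex_linked.reindex(hits["gene"]).fillna(False).mean())
                )
        rows.append(
            {
                "n_female_ST": n_female,
                "sex_linked_deg_fraction": float(np.mean(fracs)),
                "sd": float(np.std(fracs, ddof=1)) if reps > 1 else 0.0,
                "mean_n_degs": float(np.mean(n_degs)),
            }
        )
    return pd.DataFrame(rows)
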
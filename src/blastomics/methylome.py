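"""Single-cell DNA methylome analysis.

Per-CpG methylation calls (methylated read count C, unmethylated count T
per site per cell) are the entry point; upstream bisulfite alignment is
assumed done. This module provides:

* per-cell QC against the lambda spike-in conversion ratio and the number
  of covered CpG sites;
* per-cell and per-embryo global methylation levels (unweighted site and
  cell means, respectively);
* 300-bp genome-tile methylation from read counts pooled across the cells
  of a group/lineage (read-weighted, not cell-averaged);
* DMR calling by the double-threshold rule (< ``low`` in one group and
  > ``high`` in the other) and DMR frequency within genomic element
  classes;
* gene-body / CGI metaprofiles with ±15-kb flanks;
* PCA-based demethylation pseudotime against staged reference samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from blastomics.errors import DataError

log = logging.getLogger(__name__)

TILE_SIZE = 300


@dataclass
class MethylomeCohort:
    """Per-cell CpG methylation counts for a cohort, in dense site-major form.

    ``meth[i, j]`` / ``total[i, j]`` are the methylated and total read counts
    of cell i at site j. ``sites`` has columns ``chrom``, ``pos`` (0-based)
    and is sorted by (chrom, pos). ``cells`` is indexed by cell_id with
    columns ``embryo_id``, ``group`` and optionally ``lineage``.
    ``lambda_stats`` carries the spike-in conversion data per cell.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    cells: pd.DataFrame
    lambda_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.meth.shape != self.total.shape:
            raise DataError("meth and total count matrices differ in shape")
        if self.meth.shape != (len(self.cells), len(self.sites)):
            raise DataError("count matrices do not match cells x sites")
        if (self.meth > self.total).any():
            raise DataError("methylated counts exceed total read counts")

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def covered_site_counts(self) -> pd.Series:
        """Number of CpG sites with >= 1 read, per cell."""
        return pd.Series((self.total > 0).sum(axis=1), index=self.cell_ids)

    def subset(self, cell_ids) -> "MethylomeCohort":
        idx = self.cells.index.get_indexer(cell_ids)
        if (idx < 0).any():
            raise DataError("unknown cell id in subset request")
        lam = self.lambda_stats
        if len(lam):
            lam = lam.loc[lam.index.intersection(cell_ids)]
        return MethylomeCohort(
            sites=self.sites,
            meth=self.meth[idx],
            total=self.total[idx],
            cells=self.cells.iloc[idx],
            lambda_stats=lam,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format (cell_id, chrom, start, end, meth, unmeth) table."""
        ci, sj = np.nonzero(self.total)
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids[ci],
                "chrom": self.sites["chrom"].to_numpy()[sj],
                "start": self.sites["pos"].to_numpy()[sj],
                "end": self.sites["pos"].to_numpy()[sj] + 1,
                "methylated_count": self.meth[ci, sj],
                "unmethylated_count": self.total[ci, sj] - self.meth[ci, sj],
            }
        )


def cell_qc(
    cohort: MethylomeCohort,
    min_conversion: float = 0.99,
    min_sites: int = 2_000_000,
) -> pd.DataFrame:
    """Per-cell methylome QC.

    A cell passes iff its lambda bisulfite conversion ratio is strictly
    greater than ``min_conversion`` and it covers at least ``min_sites``
    CpG sites with >= 1 read. Returns a report with columns ``conversion``,
    ``covered_sites``, ``passed``, ``reason``.
    """
    covered = cohort.covered_site_counts()
    rows = []
    for cell_id in cohort.cell_ids:
        reason = ""
        if cell_id not in cohort.lambda_stats.index:
            conversion = np.nan
            passed = False
            reason = "missing lambda spike-in data"
        else:
            conversion = float(cohort.lambda_stats.loc[cell_id, "conversion"])
            passed = conversion > min_conversion
            if not passed:
                reason = f"conversion {conversion:.4f} <= {min_conversion}"
        if passed and covered[cell_id] < min_sites:
            passed = False
            reason = f"covered sites {covered[cell_id]} < {min_sites}"
        rows.append(
            {
                "cell_id": cell_id,
                "conversion": conversion,
                "covered_sites": int(covered[cell_id]),
                "passed": bool(passed),
                "reason": reason,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def cell_and_embryo_levels(
    cohort: MethylomeCohort,
) -> tuple[pd.Series, pd.Series]:
    """Global methylation level per cell and per embryo.

    The cell level is the unweighted mean over its covered sites of
    C/(C+T); the embryo level is the unweighted mean of its cells' levels.
    Cells with zero covered sites are excluded with a warning.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        site_levels = np.where(
            cohort.total > 0, cohort.meth / np.maximum(cohort.total, 1), np.nan
        )
    n_covered = (cohort.total > 0).sum(axis=1)
    empty = n_covered == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} cell(s) with zero covered sites excluded "
            "from methylation levels",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        levels = np.nanmean(site_levels, axis=1)
    cell_levels = pd.Series(levels, index=cohort.cell_ids, name="level")[~empty]
    embryos = cohort.cells.loc[cell_levels.index, "embryo_id"]
    embryo_levels = cell_levels.groupby(embryos).mean()
    embryo_levels.name = "level"
    return cell_levels, embryo_levels


def _tile_starts(positions: np.ndarray, tile_size: int = TILE_SIZE) -> np.ndarray:
    return (positions // tile_size) * tile_size


def tile_levels(
    cohort: MethylomeCohort,
    groups: pd.Series | None = None,
    tile_size: int = TILE_SIZE,
) -> dict[str, pd.DataFrame]:
    """Pooled tile methylation per group.

    Read counts of all member cells are pooled per genome tile (0-based,
    half-open, aligned to multiples of ``tile_size``); the tile level is
    pooled C / pooled (C+T), i.e. read-weighted rather than averaged over
    cells. Tiles with zero pooled reads are absent from the output.

    ``groups`` maps cell_id -> group label; by default all cells form one
    group ``"all"``. Returns ``{group: DataFrame(chrom, start, end, c, t,
    level)}``.
    """
    if groups is None:
        groups = pd.Series("all", index=cohort.cell_ids)
    starts = _tile_starts(cohort.sites["pos"].to_numpy(), tile_size)
    key = pd.DataFrame({"chrom": cohort.sites["chrom"].to_numpy(), "start": starts})
    out: dict[str, pd.DataFrame] = {}
    for label in pd.unique(groups.dropna()):
        members = groups.index[groups == label]
        idx = cohort.cells.index.get_indexer(members)
        idx = idx[idx >= 0]
        c = cohort.meth[idx].sum(axis=0)
        tot = cohort.total[idx].sum(axis=0)
        df = key.assign(c=c, t=tot - c, total=tot)
        agg = df.groupby(["chrom", "start"], as_index=False, sort=True).sum()
        agg = agg[agg["total"] > 0]
        agg["end"] = agg["start"] + tile_size
        agg["level"] = agg["c"] / agg["total"]
        out[str(label)] = agg[["chrom", "start", "end", "c", "t", "level"]].reset_index(
            drop=True
        )
    return out


def cell_tile_levels(
    cohort: MethylomeCohort,
    tile_size: int = TILE_SIZE,
) -> pd.DataFrame:
    """Per-cell tile methylation matrix (cells x tiles; NaN = uncovered)."""
    starts = _tile_starts(cohort.sites["pos"].to_numpy(), tile_size)
    tile_key = pd.MultiIndex.from_arrays(
        [cohort.sites["chrom"], starts], names=["chrom", "start"]
    )
    codes, uniques = pd.factorize(tile_key, sort=True)
    n_tiles = len(uniques)
    c = np.zeros((len(cohort.cells), n_tiles))
    tot = np.zeros_like(c)
    np.add.at(c.T, codes, cohort.meth.T)
    np.add.at(tot.T, codes, cohort.total.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = np.where(tot > 0, c / np.maximum(tot, 1), np.nan)
    return pd.DataFrame(lev, index=cohort.cell_ids, columns=uniques)


def call_dmrs(
    tiles_a: pd.DataFrame,
    tiles_b: pd.DataFrame,
    low: float = 0.10,
    high: float = 0.40,
    min_depth: int = 5,
    labels: tuple[str, str] = ("ST", "ICSI"),
) -> pd.DataFrame:
    """Call DMRs between two pooled tile sets by the double-threshold rule.

    A tile covered in both groups (pooled depth >= ``min_depth`` in each)
    is ``hyper_in_ST`` iff level_ICSI < ``low`` and level_ST > ``high``,
    and ``hypo_in_ST`` iff level_ST < ``low`` and level_ICSI > ``high``
    (strict inequalities). ``labels`` names group A and group B for the
    output columns; the class names follow the first label.
    """
    a, b = labels
    merged = tiles_a.merge(
        tiles_b, on=["chrom", "start", "end"], suffixes=(f"_{a}", f"_{b}")
    )
    depth_a = merged[f"c_{a}"] + merged[f"t_{a}"]
    depth_b = merged[f"c_{b}"] + merged[f"t_{b}"]
    merged = merged[(depth_a >= min_depth) & (depth_b >= min_depth)]
    la = merged[f"level_{a}"]
    lb = merged[f"level_{b}"]
    hyper = (lb < low) & (la > high)
    hypo = (la < low) & (lb > high)
    out = merged.loc[
        hyper | hypo, ["chrom", "start", "end", f"level_{a}", f"level_{b}"]
    ].copy()
    out["class"] = np.where(
        hyper[hyper | hypo], f"hyper_in_{a}", f"hypo_in_{a}"
    )
    return out.reset_index(drop=True)


def _element_trees(elements: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in elements.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            if e > s:
                tree.addi(int(s), int(e))
        trees[str(chrom)] = tree
    return trees


def annotate_dmrs(
    dmrs: pd.DataFrame,
    elements: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """DMR frequency within each genomic-element class.

    For each element class and DMR class, the frequency is the number of
    DMRs overlapping at least one element of the class divided by the
    total number of elements of the class. Empty element classes yield a
    missing frequency.
    """
    rows = []
    classes = sorted(dmrs["class"].unique()) if len(dmrs) else []
    for elem_name, elem_df in elements.items():
        n_elements = len(elem_df)
        trees = _element_trees(elem_df) if n_elements else {}
        for dmr_class in classes:
            sub = dmrs[dmrs["class"] == dmr_class]
            n_overlap = 0
            for chrom, s, e in zip(sub["chrom"], sub["start"], sub["end"]):
                tree = trees.get(str(chrom))
                if tree is not None and tree.overlap(int(s), int(e)):
                    n_overlap += 1
            rows.append(
                {
                    "element_class": elem_name,
                    "dmr_class": dmr_class,
                    "n_dmrs_overlapping": n_overlap,
                    "n_elements": n_elements,
                    "frequency": n_overlap / n_elements if n_elements else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "element_class",
            "dmr_class",
            "n_dmrs_overlapping",
            "n_elements",
            "frequency",
        ],
    )


def metaprofile(
    cohort: MethylomeCohort,
    features: pd.DataFrame,
    flank_bp: int = 15_000,
    body_bins: int = 100,
    flank_bins: int = 50,
    groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Methylation metaprofile over features and their flanking regions.

    Each feature body is scaled onto ``body_bins`` bins, with ``flank_bins``
    fixed-width bins covering ``flank_bp`` on each side. Minus-strand
    features are reversed so every profile runs 5'->3'. Site levels are
    averaged per (cell, bin) across all features.

    Returns ``(per_cell, per_group)``: cell x bin and group x bin matrices
    (bins indexed 0 .. 2*flank_bins+body_bins-1, upstream flank first).
    """
    n_bins = 2 * flank_bins + body_bins
    pos = cohort.sites["pos"].to_numpy()
    chroms = cohort.sites["chrom"].to_numpy()
    sums = np.zeros((len(cohort.cells), n_bins))
    counts = np.zeros_like(sums)
    with np.errstate(invalid="ignore", divide="ignore"):
        site_levels = np.where(
            cohort.total > 0, cohort.meth / np.maximum(cohort.total, 1), np.nan
        )
    n_skipped = 0
    for _, feat in features.iterrows():
        start, end = int(feat["start"]), int(feat["end"])
        length = end - start
        if length < body_bins:  # sub-base-pair body bins
            n_skipped += 1
            continue
        strand = feat.get("strand", "+")
        mask = (
            (chroms == feat["chrom"])
            & (pos >= start - flank_bp)
            & (pos < end + flank_bp)
        )
        if not mask.any():
            continue
        p = pos[mask]
        rel = np.empty(p.size)
        up = p < start
        down = p >= end
        body = ~up & ~down
        rel[up] = (p[up] - (start - flank_bp)) / flank_bp * flank_bins
        rel[body] = flank_bins + (p[body] - start) / length * body_bins
        rel[down] = flank_bins + body_bins + (p[down] - end) / flank_bp * flank_bins
        bins = np.clip(rel.astype(int), 0, n_bins - 1)
        if strand == "-":
            bins = n_bins - 1 - bins
        lv = site_levels[:, mask]
        ok = ~np.isnan(lv)
        np.add.at(sums.T, bins, np.where(ok, lv, 0.0).T)
        np.add.at(counts.T, bins, ok.T.astype(float))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} feature(s) shorter than one body bin skipped",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_cell = pd.DataFrame(
            np.where(counts > 0, sums / np.maximum(counts, 1), np.nan),
            index=cohort.cell_ids,
        )
    if groups is None:
        groups = pd.Series("all", index=cohort.cell_ids)
    per_group = per_cell.groupby(groups.reindex(per_cell.index)).mean()
    return per_cell, per_group


@dataclass
class PseudotimeResult:
    """PC1-based demethylation pseudotime for study and reference samples."""

    samples: pd.DataFrame  # index sample id; columns pseudotime, stage, is_reference
    loadings: pd.Series  # tile -> PC1 loading
    explained_variance_ratio: float


def pseudotime(
    study_tiles: pd.DataFrame,
    reference_tiles: pd.DataFrame,
    reference_stages: pd.Series,
    stage_order: list[str],
    min_sample_coverage: float = 0.8,
) -> PseudotimeResult:
    """Demethylation pseudotime from a joint sample x tile PCA.

    ``study_tiles`` and ``reference_tiles`` are sample x tile methylation
    matrices (NaN = uncovered); ``reference_stages`` maps reference sample
    ids to stage labels, ordered earliest-first in ``stage_order``.

    Tiles covered in at least ``min_sample_coverage`` of all samples are
    kept and remaining missing entries are mean-imputed. PC1 of the joint
    matrix is the pseudotime; its sign is fixed so the earliest reference
    stage has the largest pseudotime (pseudotime decreases along the
    demethylation trajectory).
    """
    from sklearn.decomposition import PCA

    stages_present = [s for s in stage_order if (reference_stages == s).any()]
    if len(stages_present) < 2:
        raise DataError("pseudotime requires at least 2 reference stages")
    joint = pd.concat([study_tiles, reference_tiles], axis=0)
    if len(joint) < 2:
        raise DataError("pseudotime requires at least 2 samples")
    keep = joint.notna().mean(axis=0) >= min_sample_coverage
    joint = joint.loc[:, keep]
    if joint.shape[1] == 0:
        raise DataError("no tiles pass the sample-coverage threshold")
    filled = joint.fillna(joint.mean(axis=0))
    filled = filled.loc[:, filled.std(axis=0) > 0]
    pca = PCA(n_components=min(2, len(filled) - 1), random_state=0)
    pcs = pca.fit_transform(filled.to_numpy())
    pc1 = pd.Series(pcs[:, 0], index=joint.index)
    loadings = pd.Series(pca.components_[0], index=filled.columns)

    earliest = reference_stages.index[reference_stages == stages_present[0]]
    latest = reference_stages.index[reference_stages == stages_present[-1]]
    if pc1[earliest].mean() < pc1[latest].mean():
        pc1 = -pc1
        loadings = -loadings
    samples = pd.DataFrame({"pseudotime": pc1})
    samples["stage"] = reference_stages.reindex(samples.index)
    samples["is_reference"] = samples.index.isin(reference_stages.index)
    return PseudotimeResult(
        samples=samples,
        loadings=loadings,
        explained_variance_ratio=float(pca.explained_variance_ratio_[0]),
    )
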
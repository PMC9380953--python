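"""Copy-number inference from single-cell bisulfite read depth.

Reads are counted in consecutive 1-Mb genome windows per cell. Cells and
windows whose median count falls below a floor (default 500) are removed;
each cell is then depth-normalized by its total read count, each window is
normalized by its median across control cells, and the result is rescaled
so a normal (diploid) window sits at copy number 2. Smoothing replaces
each window with the rounded average of the surrounding 100 windows
(50 per side, self included, truncated at chromosome ends), yielding
integer copy-number profiles used to cross-validate the expression-based
calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from blastomics.errors import DataError

log = logging.getLogger(__name__)

WINDOW_SIZE = 1_000_000


@dataclass
class BinCountMatrix:
    """Cells x 1-Mb-window read counts.

    ``windows`` has columns ``chrom``, ``start``, ``end`` and tiles each
    chromosome consecutively. ``cells`` is indexed by cell_id with at least
    an ``embryo_id`` column.
    """

    counts: np.ndarray
    windows: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cells), len(self.windows)):
            raise DataError("count matrix does not match cells x windows")
        if (self.counts < 0).any():
            raise DataError("negative window read counts")

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def cell_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def bin_read_positions(
    reads: pd.DataFrame,
    genome: list[tuple[str, int]],
    cells: pd.DataFrame,
    window_size: int = WINDOW_SIZE,
) -> BinCountMatrix:
    """Bin per-read positions (cell_id, chrom, pos) into window counts."""
    windows = make_windows(genome, window_size)
    wkey = {
        (c, s): i
        for i, (c, s) in enumerate(zip(windows["chrom"], windows["start"]))
    }
    counts = np.zeros((len(cells), len(windows)), dtype=np.int64)
    cell_pos = {cid: i for i, cid in enumerate(cells.index)}
    starts = (reads["pos"] // window_size) * window_size
    for cid, chrom, s in zip(reads["cell_id"], reads["chrom"], starts):
        j = wkey.get((chrom, int(s)))
        i = cell_pos.get(cid)
        if i is not None and j is not None:
            counts[i, j] += 1
    return BinCountMatrix(counts=counts, windows=windows, cells=cells)


def make_windows(
    genome: list[tuple[str, int]], window_size: int = WINDOW_SIZE
) -> pd.DataFrame:
    rows = []
    for chrom, length in genome:
        for start in range(0, int(length), window_size):
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + window_size, int(length)),
                }
            )
    return pd.DataFrame(rows)


def filter_bins_and_cells(
    b: BinCountMatrix, min_median: float = 500
) -> tuple[BinCountMatrix, dict]:
    """Remove poor-quality cells, then low-abundance windows.

    A cell is removed when its median per-window count is below
    ``min_median``; among the remaining cells, a window is removed when its
    median per-cell count is below ``min_median``.
    """
    cell_medians = np.median(b.counts, axis=1)
    keep_cells = cell_medians >= min_median
    removed_cells = list(b.cell_ids[~keep_cells])
    counts = b.counts[keep_cells]
    if counts.shape[0] == 0:
        raise DataError("all cells removed by the median read filter")
    window_medians = np.median(counts, axis=0)
    keep_windows = window_medians >= min_median
    removed_windows = b.windows.loc[~keep_windows]
    counts = counts[:, keep_windows]
    if counts.shape[1] == 0:
        raise DataError("all windows removed by the median read filter")
    report = {
        "removed_cells": removed_cells,
        "removed_windows": removed_windows[["chrom", "start", "end"]].to_dict(
            "records"
        ),
    }
    filtered = BinCountMatrix(
        counts=counts,
        windows=b.windows.loc[keep_windows].reset_index(drop=True),
        cells=b.cells.loc[keep_cells],
    )
    return filtered, report


def normalize_bins(
    b: BinCountMatrix,
    control: str | None = None,
    euploid_copy: float = 2.0,
) -> pd.DataFrame:
    """Depth- and control-normalize window counts onto a copy-number scale.

    Each cell is divided by its total read count; each window is divided by
    the median of these depth-normalized values over the control cells
    (all cells when ``control`` is None selects the automatic control, the
    embryo with minimal cross-window variance; pass ``"all"`` to use every
    cell). The result is multiplied by ``euploid_copy`` so that a window at
    the control median sits at copy 2. Windows with a zero control median
    are returned as NaN.
    """
    totals = b.cell_totals().astype(float)
    if (totals == 0).any():
        raise DataError("cell with zero total reads cannot be normalized")
    frac = b.counts / totals[:, None]
    if control is None:
        control = select_control_embryo(b)
        log.info("automatically selected control embryo %s", control)
    if control == "all":
        ctrl_rows = np.ones(len(b.cells), dtype=bool)
    else:
        ctrl_rows = (b.cells["embryo_id"] == control).to_numpy()
        if not ctrl_rows.any():
            raise DataError(f"control embryo {control!r} has no cells")
    med = np.median(frac[ctrl_rows], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(med > 0, frac / np.where(med > 0, med, 1), np.nan)
    values = values * euploid_copy
    cols = pd.MultiIndex.from_arrays(
        [b.windows["chrom"], b.windows["start"]], names=["chrom", "start"]
    )
    return pd.DataFrame(values, index=b.cell_ids, columns=cols)


def select_control_embryo(b: BinCountMatrix) -> str:
    """Pick the embryo whose cells have minimal cross-window variance.

    Used when no control is named: an embryo with no CNVs in any cell has
    the flattest depth-normalized profiles.
    """
    totals = b.cell_totals().astype(float)
    frac = b.counts / np.maximum(totals, 1)[:, None]
    med = np.median(frac, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(med > 0, frac / np.where(med > 0, med, 1), np.nan)
    cell_var = np.nanvar(rel, axis=1)
    by_embryo = pd.Series(cell_var, index=b.cell_ids).groupby(
        b.cells["embryo_id"]
    ).mean()
    return str(by_embryo.idxmin())


def smooth_and_round(
    values: pd.DataFrame,
    half_window: int = 50,
) -> pd.DataFrame:
    """Integer copy-number profile from normalized window signals.

    Each window is replaced by the nearest integer of the average of the
    surrounding ``2 * half_window`` windows (self included, restricted to
    the same chromosome, truncated at chromosome ends). Ties at .5 round
    half away from zero. Chromosomes with fewer than 2 windows pass
    through unsmoothed (with a warning) before rounding.
    """
    chroms = np.asarray(values.columns.get_level_values("chrom"))
    arr = values.to_numpy()
    out = np.empty(values.shape)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        block = arr[:, mask]
        n = block.shape[1]
        if n < 2:
            warnings.warn(
                f"chromosome {chrom} has fewer than 2 windows; unsmoothed",
                stacklevel=2,
            )
            out[:, mask] = block
            continue
        smoothed = np.empty_like(block)
        for j in range(n):
            lo = max(0, j - half_window)
            hi = min(n, j + half_window + 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                smoothed[:, j] = np.nanmean(block[:, lo:hi], axis=1)
        out[:, mask] = smoothed
    # round half away from zero (values are non-negative here)
    rounded = np.where(np.isnan(out), np.nan, np.floor(out + 0.5))
    return pd.DataFrame(rounded, index=values.index, columns=values.columns)


def chromosome_states(
    profile: pd.DataFrame,
    euploid_copy: float = 2.0,
) -> pd.DataFrame:
    """Majority-vote per-chromosome copy-number state per cell.

    Returns a cell x chromosome frame of ``gain`` / ``loss`` / ``normal``
    from the modal integer copy over the chromosome's windows.
    """
    chroms = profile.columns.get_level_values("chrom")
    out = {}
    for chrom in pd.unique(chroms):
        block = profile.loc[:, chroms == chrom]
        modal = block.mode(axis=1)
        modal = modal.iloc[:, 0]
        state = np.where(
            modal > euploid_copy, "gain", np.where(modal < euploid_copy, "loss", "normal")
        )
        out[chrom] = pd.Series(state, index=profile.index)
    return pd.DataFrame(out)


def concordance(
    rna_states: pd.DataFrame,
    meth_profile: pd.DataFrame,
    exclude_chroms: tuple[str, ...] = ("chrX", "chrY"),
) -> tuple[pd.DataFrame, float]:
    """Cross-layer chromosome-level CNV agreement on shared cells.

    ``rna_states`` is a cell x chromosome frame of gain/loss/normal from
    the expression caller; ``meth_profile`` is the integer copy-number
    frame from the bisulfite caller. Sex chromosomes are excluded by
    default (expected dosage differs by sex, not by aneuploidy). Returns
    the per-(cell, chromosome) table and the overall agreement fraction.
    """
    meth_states = chromosome_states(meth_profile)
    shared_cells = rna_states.index.intersection(meth_states.index)
    if len(shared_cells) == 0:
        raise DataError("no shared cells between the two CNV layers")
    shared_chroms = [
        c
        for c in rna_states.columns
        if c in meth_states.columns and c not in exclude_chroms
    ]
    rows = []
    for cell in shared_cells:
        for chrom in shared_chroms:
            r = rna_states.loc[cell, chrom]
            m = meth_states.loc[cell, chrom]
            rows.append(
                {
                    "cell_id": cell,
                    "chrom": chrom,
                    "rna_state": r,
                    "meth_state": m,
                    "agree": r == m,
                }
            )
    table = pd.DataFrame(rows)
    return table, float(table["agree"].mean())
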
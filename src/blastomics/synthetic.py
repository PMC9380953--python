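"""Seeded synthetic blastocyst cohorts with shared ground truth.

The generator emulates the statistical structure of a single-cell
triple-omics study of spindle-transfer (ST) versus ICSI-control
blastocysts on a desk-scale toy genome (five 30-Mb autosomes plus X and
Y), producing four coherent layers keyed by the same cell/embryo ids:

* a UMI count matrix from a negative-binomial model with lineage-specific
  marker up-regulation, X/Y dosage reflecting embryo sex, planted
  whole-chromosome copy-number events, optional planted ST-vs-ICSI
  differential expression, and a fraction of shallow low-quality cells;
* per-cell CpG methylation counts over 300-bp tiles covering the start of
  each chromosome, with CGI hypomethylation, planted double-threshold DMR
  tiles (TE lineage), a global TE-ST methylation offset, and lambda
  spike-in conversion controls;
* per-cell 1-Mb-bin read counts scaling with planted copy number;
* gene/element annotation (genes, promoters, CGIs, repeats).

Every random draw flows from the single root seed through
``numpy.random.SeedSequence.spawn``, so equal seeds give byte-identical
cohorts. The emitted :class:`SyntheticTruth` carries all planted labels
so downstream analyses can be scored without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData

from blastomics.cnv_methylation import BinCountMatrix, make_windows
from blastomics.errors import ConfigurationError
from blastomics.methylome import TILE_SIZE, MethylomeCohort

LINEAGES = ("EPI", "PE", "TE")

DEFAULT_GENOME: list[tuple[str, int]] = [
    ("chr1", 30_000_000),
    ("chr2", 30_000_000),
    ("chr3", 30_000_000),
    ("chr4", 30_000_000),
    ("chr5", 30_000_000),
    ("chrX", 8_000_000),
    ("chrY", 5_000_000),
]


@dataclass
class CohortConfig:
    """Parameters of a synthetic blastocyst cohort.

    Defaults mirror the scale of a two-arm blastocyst study: tens of
    embryos with ~30 cells each, a TE-dominated lineage mix, ~190k UMIs
    per cell, a minority of aneuploid cells carrying whole-chromosome
    events, and a small global TE methylation offset planted in the ST
    group (default +0.024, i.e. 2.4 percentage points).
    """

    n_embryos_per_group: int = 8
    cells_per_embryo: int = 30
    n_genes: int = 2000
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_GENOME)
    )
    lineage_proportions: tuple[float, float, float] = (0.15, 0.10, 0.75)
    marker_genes_per_lineage: int = 40
    marker_fold: float = 5.0
    # diffuse lineage programs: many genes at a modest fold, so lineage —
    # not sex or noise — dominates the transcriptome distance, as in real
    # blastocysts where lineages differ in thousands of genes
    program_genes_per_lineage: int = 300
    program_fold: float = 2.0
    aneuploid_cell_fraction: float = 0.2
    te_methylation_offset: float = 0.024
    mean_umis_per_cell: float = 190_000.0
    cpg_sites_per_tile: int = 5
    dispersion: float = 0.1
    seed: int = 0
    # sex composition and planted group effects; the control arm can be
    # given its own female fraction to emulate the compositional imbalance
    # between treatment arms that confounds sex-linked DEG calls
    female_fraction: float = 0.5
    female_fraction_icsi: float | None = None
    n_deg_genes: int = 0
    deg_fold: float = 4.0
    # quality structure
    low_quality_cell_fraction: float = 0.0
    low_conversion_cell_fraction: float = 0.0
    # methylome layer
    meth_region_bp: int = 60_000
    dmr_tile_fraction: float = 0.05
    meth_depth_per_site: float = 2.0
    lambda_conversion: float = 0.995
    lambda_sites: int = 500
    lambda_depth: int = 10
    # genome bin-count layer
    reads_per_window: float = 1000.0
    # fraction of a mosaic embryo's cells sharing its planted CNV
    aneuploid_block_fraction: float = 0.3

    def validate(self) -> None:
        positive = [
            "n_embryos_per_group",
            "cells_per_embryo",
            "n_genes",
            "marker_genes_per_lineage",
            "program_genes_per_lineage",
            "program_fold",
            "mean_umis_per_cell",
            "cpg_sites_per_tile",
            "dispersion",
            "meth_region_bp",
            "meth_depth_per_site",
            "lambda_sites",
            "lambda_depth",
            "reads_per_window",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        fractions = [
            "aneuploid_cell_fraction",
            "te_methylation_offset",
            "female_fraction",
            "low_quality_cell_fraction",
            "low_conversion_cell_fraction",
            "dmr_tile_fraction",
            "lambda_conversion",
            "aneuploid_block_fraction",
        ]
        for name in fractions:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.female_fraction_icsi is not None and not (
            0 <= self.female_fraction_icsi <= 1
        ):
            raise ConfigurationError("female_fraction_icsi must lie in [0, 1]")
        if abs(sum(self.lineage_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("lineage_proportions must sum to 1")
        if any(p < 0 for p in self.lineage_proportions):
            raise ConfigurationError("lineage_proportions must be non-negative")
        if not self.genome:
            raise ConfigurationError("genome must list at least one chromosome")
        for chrom, length in self.genome:
            if length <= 0:
                raise ConfigurationError(f"genome length for {chrom} must be positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        d["lineage_proportions"] = list(self.lineage_proportions)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["genome"] = [tuple(g) for g in d.get("genome", DEFAULT_GENOME)]
        d["lineage_proportions"] = tuple(d.get("lineage_proportions", (0.15, 0.10, 0.75)))
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted alongside every synthetic cohort."""

    cells: pd.DataFrame  # index cell_id: embryo_id, group, lineage, is_aneuploid, is_low_quality
    embryo_sex: pd.Series  # embryo_id -> male/female
    planted_cnvs: pd.DataFrame  # cell_id, chrom, start_bp, end_bp, copy_number
    planted_dmr_tiles: pd.DataFrame  # chrom, start, end, level_ST, level_ICSI, class
    marker_genes: dict[str, list[str]]
    program_genes: dict[str, list[str]]
    deg_genes: list[str]
    te_methylation_offset: float


@dataclass
class Cohort:
    """All synthetic layers plus annotation and truth."""

    expression: AnnData
    methylome: MethylomeCohort
    bins: BinCountMatrix
    genes: pd.DataFrame
    elements: dict[str, pd.DataFrame]
    truth: SyntheticTruth
    config: CohortConfig


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# expressed-gene density relative to autosomes; sex chromosomes are
# gene-poor (chrY especially), which also keeps sex dosage from dominating
# transcriptome distances
_DENSITY = {"chrX": 0.5, "chrY": 0.15}


def _gene_annotation(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Evenly spaced genes, counts proportional to weighted chromosome length."""
    weights = {c: length * _DENSITY.get(c, 1.0) for c, length in config.genome}
    total = sum(weights.values())
    rows = []
    remaining = config.n_genes
    for k, (chrom, length) in enumerate(config.genome):
        if k == len(config.genome) - 1:
            n = remaining
        else:
            n = max(1, round(config.n_genes * weights[chrom] / total))
            n = min(n, remaining - (len(config.genome) - 1 - k))
        remaining -= n
        spacing = length / (n + 1)
        gene_len = int(min(20_000, max(1_000, spacing / 2)))
        for i in range(n):
            start = int(spacing * (i + 1))
            strand = "+" if (i % 2 == 0) else "-"
            end = min(start + gene_len, length - 1)
            rows.append(
                {
                    "gene": f"{chrom}_g{i:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": start if strand == "+" else end,
                }
            )
    genes = pd.DataFrame(rows)
    genes["is_X_linked"] = genes["chrom"] == "chrX"
    genes["is_Y_linked"] = genes["chrom"] == "chrY"
    return genes


_CANONICAL = {
    "EPI": ["SOX2", "NANOG", "POU5F1"],
    "PE": ["GATA4", "SOX17", "FOXA2"],
    "TE": ["GATA2", "GATA3", "CDX2"],
}


def _pick_markers(
    genes: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Choose scattered autosomal genes as lineage markers and programs.

    High-confidence markers (strong ``marker_fold`` up-regulation) carry
    the canonical symbols for the first three of each lineage
    (SOX2/NANOG/POU5F1, GATA4/SOX17/FOXA2, GATA2/GATA3/CDX2) so default
    marker-driven assignment works out of the box; the diffuse lineage
    program genes keep their positional names.
    """
    autosomal = genes.index[~genes["is_X_linked"] & ~genes["is_Y_linked"]].to_numpy()
    per_lineage = config.marker_genes_per_lineage + config.program_genes_per_lineage
    n_needed = 3 * per_lineage
    if n_needed > autosomal.size:
        raise ConfigurationError(
            "marker_genes_per_lineage + program_genes_per_lineage too large "
            "for the autosomal gene count"
        )
    chosen = rng.choice(autosomal, n_needed, replace=False)
    markers: dict[str, list[str]] = {}
    programs: dict[str, list[str]] = {}
    for li, lineage in enumerate(LINEAGES):
        idx = chosen[li * per_lineage : (li + 1) * per_lineage]
        names = []
        for j, gi in enumerate(idx[: config.marker_genes_per_lineage]):
            name = (
                _CANONICAL[lineage][j]
                if j < len(_CANONICAL[lineage])
                else f"{lineage}_SIG{j:02d}"
            )
            genes.loc[gi, "gene"] = name
            names.append(name)
        markers[lineage] = names
        programs[lineage] = genes.loc[
            idx[config.marker_genes_per_lineage :], "gene"
        ].tolist()
    return markers, programs


def _plan_cells(config: CohortConfig, rng: np.random.Generator):
    """Cell metadata: embryo, group, lineage, sex, quality flags."""
    rows = []
    embryo_sex = {}
    for group in ("ST", "ICSI"):
        p_female = config.female_fraction
        if group == "ICSI" and config.female_fraction_icsi is not None:
            p_female = config.female_fraction_icsi
        for e in range(config.n_embryos_per_group):
            embryo = f"{group}_E{e:02d}"
            embryo_sex[embryo] = "female" if rng.random() < p_female else "male"
            lineages = rng.choice(
                LINEAGES, size=config.cells_per_embryo, p=list(config.lineage_proportions)
            )
            for c in range(config.cells_per_embryo):
                rows.append(
                    {
                        "cell_id": f"{embryo}_c{c:03d}",
                        "embryo_id": embryo,
                        "group": group,
                        "lineage": lineages[c],
                    }
                )
    cells = pd.DataFrame(rows).set_index("cell_id")
    n = len(cells)
    cells["is_low_quality"] = rng.random(n) < config.low_quality_cell_fraction
    cells["is_low_conversion"] = (
        rng.random(n) < config.low_conversion_cell_fraction
    )
    return cells, pd.Series(embryo_sex, name="sex")


def _plan_cnvs(
    cells: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Plant whole-chromosome events in mosaic blocks within embryos.

    Aneuploidy is mosaic: an affected embryo carries one event (random
    autosome, copy 1 or 3) in a contiguous block of its cells. Blocks hold
    at least 3 cells (when the overall quota allows), matching how
    mitotic-origin aneuploidy clusters within an embryo.
    """
    quota = round(config.aneuploid_cell_fraction * len(cells))
    records = []
    if quota == 0:
        return pd.DataFrame(
            columns=["cell_id", "chrom", "start_bp", "end_bp", "copy_number"]
        )
    autosomes = [
        (c, l) for c, l in config.genome if c not in ("chrX", "chrY")
    ]
    embryos = list(cells["embryo_id"].unique())
    rng.shuffle(embryos)
    remaining = quota
    for embryo in embryos:
        if remaining <= 0:
            break
        member_cells = cells.index[cells["embryo_id"] == embryo]
        block = max(3, int(rng.binomial(len(member_cells), config.aneuploid_block_fraction)))
        block = min(block, remaining, len(member_cells))
        if 0 < remaining - block < 3:
            block = min(remaining, len(member_cells))
        chrom, length = autosomes[rng.integers(len(autosomes))]
        copy = int(rng.choice([1, 3]))
        chosen = rng.choice(member_cells, block, replace=False)
        for cell in chosen:
            records.append(
                {
                    "cell_id": cell,
                    "chrom": chrom,
                    "start_bp": 0,
                    "end_bp": int(length),
                    "copy_number": copy,
                }
            )
        remaining -= block
    return pd.DataFrame(records)


def _expression_layer(
    cells: pd.DataFrame,
    embryo_sex: pd.Series,
    genes: pd.DataFrame,
    markers: dict[str, list[str]],
    programs: dict[str, list[str]],
    deg_genes: list[str],
    cnvs: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> AnnData:
    n_cells, n_genes = len(cells), len(genes)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    mult = np.ones((n_cells, n_genes))

    gene_pos = {g: i for i, g in enumerate(genes["gene"])}
    cell_pos = {c: i for i, c in enumerate(cells.index)}
    for lineage, names in markers.items():
        cols = [gene_pos[g] for g in names]
        rows = (cells["lineage"] == lineage).to_numpy()
        mult[np.ix_(rows, cols)] *= config.marker_fold
    for lineage, names in programs.items():
        cols = [gene_pos[g] for g in names]
        rows = (cells["lineage"] == lineage).to_numpy()
        mult[np.ix_(rows, cols)] *= config.program_fold
    # sex dosage: females 2x on X and silent on Y; males 1x on both
    female_rows = cells["embryo_id"].map(embryo_sex).eq("female").to_numpy()
    x_cols = genes["is_X_linked"].to_numpy()
    y_cols = genes["is_Y_linked"].to_numpy()
    mult[np.ix_(female_rows, x_cols)] *= 2.0
    mult[np.ix_(female_rows, y_cols)] = 0.0
    # planted ST-vs-ICSI differential expression in TE
    if deg_genes:
        cols = [gene_pos[g] for g in deg_genes]
        rows = ((cells["group"] == "ST") & (cells["lineage"] == "TE")).to_numpy()
        mult[np.ix_(rows, cols)] *= config.deg_fold
    # planted copy-number dosage
    chrom_of = genes["chrom"].to_numpy()
    for _, ev in cnvs.iterrows():
        i = cell_pos[ev["cell_id"]]
        in_event = (
            (chrom_of == ev["chrom"])
            & (genes["start"].to_numpy() >= ev["start_bp"])
            & (genes["end"].to_numpy() <= ev["end_bp"])
        )
        mult[i, in_event] *= ev["copy_number"] / 2.0

    mean = base[None, :] * mult
    mean /= mean.sum(axis=1, keepdims=True)
    depth = np.full(n_cells, config.mean_umis_per_cell)
    depth[cells["is_low_quality"].to_numpy()] *= 0.002
    mean = mean * depth[:, None]

    # NB with var = mu + dispersion * mu^2
    size = 1.0 / config.dispersion
    p = size / (size + np.maximum(mean, 1e-12))
    counts = np.where(mean > 0, rng.negative_binomial(size, p), 0).astype(np.int64)

    adata = AnnData(
        X=counts,
        obs=cells[["embryo_id", "group"]].copy(),
        var=genes.set_index("gene")[
            ["chrom", "start", "end", "strand", "tss", "is_X_linked", "is_Y_linked"]
        ].copy(),
    )
    adata.uns["normalization"] = "raw"
    return adata


def _meth_sites(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, length in config.genome:
        region = min(config.meth_region_bp, length)
        for start in range(0, region - TILE_SIZE + 1, TILE_SIZE):
            offsets = np.sort(
                rng.choice(TILE_SIZE, size=config.cpg_sites_per_tile, replace=False)
            )
            for off in offsets:
                rows.append({"chrom": chrom, "pos": start + int(off)})
    sites = pd.DataFrame(rows)
    return sites.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _element_beds(
    config: CohortConfig,
    genes: pd.DataFrame,
    sites: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    promoters = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(0, genes["tss"] - 1500),
            "end": genes["tss"] + 1500,
            "name": genes["gene"] + "_prom",
        }
    )
    cgi_rows, repeat_rows = [], []
    for chrom, length in config.genome:
        region = min(config.meth_region_bp, length)
        n_tiles = region // TILE_SIZE
        # CGIs inside the methylome-covered region, one per ~20 tiles
        for i, tile in enumerate(range(5, n_tiles - 2, 20)):
            start = tile * TILE_SIZE
            cgi_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + 2 * TILE_SIZE,
                    "name": f"{chrom}_CGI{i:02d}",
                }
            )
        for i in range(50):
            start = int(rng.integers(0, length - 2000))
            repeat_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + int(rng.integers(500, 2000)),
                    "name": f"{chrom}_rep{i:02d}",
                }
            )
    cols = ["chrom", "start", "end", "name"]
    return {
        "promoters": promoters.reset_index(drop=True),
        "CGI": pd.DataFrame(cgi_rows, columns=cols),
        "repeats": pd.DataFrame(repeat_rows, columns=cols),
    }


def _plan_tiles(
    sites: pd.DataFrame,
    elements: dict[str, pd.DataFrame],
    config: CohortConfig,
    rng: np.random.Generator,
):
    """Baseline tile levels, CGI hypomethylation, and planted DMR tiles."""
    tiles = (
        sites.assign(start=(sites["pos"] // TILE_SIZE) * TILE_SIZE)[["chrom", "start"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    n = len(tiles)
    base = rng.beta(1.5, 3.5, size=n)  # global mean ~0.3, blastocyst-like
    cgi = elements["CGI"]
    in_cgi = np.zeros(n, dtype=bool)
    for chrom, grp in cgi.groupby("chrom"):
        m = tiles["chrom"] == chrom
        for s, e in zip(grp["start"], grp["end"]):
            in_cgi |= (m & (tiles["start"] >= s) & (tiles["start"] < e)).to_numpy()
    base[in_cgi] = rng.beta(1.0, 19.0, size=int(in_cgi.sum()))  # ~0.05

    n_dmr = round(config.dmr_tile_fraction * n)
    candidates = np.where(~in_cgi)[0]
    dmr_idx = rng.choice(candidates, min(n_dmr, candidates.size), replace=False)
    level_st = base.copy()
    level_icsi = base.copy()
    dmr_records = []
    for k, ti in enumerate(np.sort(dmr_idx)):
        if k % 2 == 0:  # hyper in ST
            level_st[ti], level_icsi[ti] = 0.50, 0.05
            cls = "hyper_in_ST"
        else:
            level_st[ti], level_icsi[ti] = 0.05, 0.50
            cls = "hypo_in_ST"
        dmr_records.append(
            {
                "chrom": tiles.loc[ti, "chrom"],
                "start": int(tiles.loc[ti, "start"]),
                "end": int(tiles.loc[ti, "start"]) + TILE_SIZE,
                "level_ST": float(level_st[ti]),
                "level_ICSI": float(level_icsi[ti]),
                "class": cls,
            }
        )
    is_dmr = np.zeros(n, dtype=bool)
    is_dmr[dmr_idx] = True
    tiles = tiles.assign(
        base=base, level_ST=level_st, level_ICSI=level_icsi, is_dmr=is_dmr
    )
    return tiles, pd.DataFrame(
        dmr_records,
        columns=["chrom", "start", "end", "level_ST", "level_ICSI", "class"],
    )


def generate_lambda_spikein(
    conversion_rate: float, n_sites: int, depth: int, seed: int
) -> pd.DataFrame:
    """Lambda spike-in C/T counts for one cell.

    The phage genome is unmethylated, so every methylated ('C') lambda
    read is a conversion failure: the expected fraction of converted ('T')
    reads equals ``conversion_rate``.
    """
    if not 0 <= conversion_rate <= 1:
        raise ConfigurationError("conversion_rate must lie in [0, 1]")
    if n_sites <= 0 or depth <= 0:
        raise ConfigurationError("n_sites and depth must be positive")
    rng = np.random.default_rng(seed)
    meth = rng.binomial(depth, 1.0 - conversion_rate, size=n_sites)
    return pd.DataFrame(
        {
            "site": np.arange(n_sites),
            "methylated_count": meth,
            "unmethylated_count": depth - meth,
        }
    )


def _methylome_layer(
    cells: pd.DataFrame,
    sites: pd.DataFrame,
    tiles: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    lambda_seeds: np.random.SeedSequence,
) -> MethylomeCohort:
    tile_key = pd.MultiIndex.from_frame(tiles[["chrom", "start"]])
    site_tile = pd.MultiIndex.from_arrays(
        [sites["chrom"], (sites["pos"] // TILE_SIZE) * TILE_SIZE]
    )
    tile_of_site = tile_key.get_indexer(site_tile)

    # per (group, lineage) site-level expectation
    def site_levels(group: str, lineage: str) -> np.ndarray:
        if lineage == "TE":
            lv = tiles["level_ST" if group == "ST" else "level_ICSI"].to_numpy().copy()
            if group == "ST":
                lv = np.where(
                    tiles["is_dmr"],
                    lv,
                    np.clip(lv + config.te_methylation_offset, 0.0, 1.0),
                )
        else:
            lv = tiles["base"].to_numpy()
        return lv[tile_of_site]

    level_map = {
        (g, l): site_levels(g, l) for g in ("ST", "ICSI") for l in LINEAGES
    }
    n_cells, n_sites = len(cells), len(sites)
    levels = np.empty((n_cells, n_sites))
    for i, (g, l) in enumerate(zip(cells["group"], cells["lineage"])):
        levels[i] = level_map[(g, l)]
    depth = rng.poisson(config.meth_depth_per_site, size=(n_cells, n_sites)).astype(
        np.int16
    )
    meth = rng.binomial(depth.astype(np.int64), levels).astype(np.int16)

    lam_rows = []
    child_seeds = lambda_seeds.spawn(n_cells)
    for cell_id, low_conv, ss in zip(
        cells.index, cells["is_low_conversion"], child_seeds
    ):
        conv = 0.98 if low_conv else config.lambda_conversion
        lam = generate_lambda_spikein(
            conv,
            config.lambda_sites,
            config.lambda_depth,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        c = int(lam["methylated_count"].sum())
        t = int(lam["unmethylated_count"].sum())
        lam_rows.append(
            {
                "cell_id": cell_id,
                "lambda_meth": c,
                "lambda_unmeth": t,
                "conversion": t / (c + t),
            }
        )
    lambda_stats = pd.DataFrame(lam_rows).set_index("cell_id")
    return MethylomeCohort(
        sites=sites,
        meth=meth,
        total=depth,
        cells=cells[["embryo_id", "group", "lineage"]].copy(),
        lambda_stats=lambda_stats,
    )


def _bin_layer(
    cells: pd.DataFrame,
    cnvs: pd.DataFrame,
    embryo_sex: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator,
) -> BinCountMatrix:
    windows = make_windows(config.genome)
    n_cells, n_windows = len(cells), len(windows)
    copy = np.full((n_cells, n_windows), 2.0)
    cell_pos = {c: i for i, c in enumerate(cells.index)}
    wchrom = windows["chrom"].to_numpy()
    wstart = windows["start"].to_numpy()
    wend = windows["end"].to_numpy()
    female = cells["embryo_id"].map(embryo_sex).eq("female").to_numpy()
    copy[np.ix_(~female, wchrom == "chrX")] = 1.0
    copy[np.ix_(~female, wchrom == "chrY")] = 1.0
    copy[np.ix_(female, wchrom == "chrY")] = 0.0
    for _, ev in cnvs.iterrows():
        i = cell_pos[ev["cell_id"]]
        mask = (
            (wchrom == ev["chrom"])
            & (wstart >= ev["start_bp"])
            & (wend <= ev["end_bp"])
        )
        copy[i, mask] = float(ev["copy_number"])
    depth_factor = rng.lognormal(0.0, 0.2, size=n_cells)
    mean = config.reads_per_window * (copy / 2.0) * depth_factor[:, None]
    counts = rng.poisson(mean).astype(np.int64)
    return BinCountMatrix(
        counts=counts,
        windows=windows,
        cells=cells[["embryo_id", "group", "lineage"]].copy(),
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one synthetic cohort; equal seeds give identical output."""
    config.validate()
    (
        rng_genes,
        rng_cells,
        rng_cnv,
        rng_expr,
        rng_sites,
        rng_elements,
        rng_tiles,
        rng_meth,
        rng_bins,
    ) = _spawn(config.seed, 9)
    lambda_seq = np.random.SeedSequence(config.seed + 2**30)

    genes = _gene_annotation(config, rng_genes)
    markers, programs = _pick_markers(genes, config, rng_genes)
    cells, embryo_sex = _plan_cells(config, rng_cells)
    cnvs = _plan_cnvs(cells, config, rng_cnv)
    planted_lineage_genes = [
        g for gs in list(markers.values()) + list(programs.values()) for g in gs
    ]
    autosomal_pool = genes.loc[
        ~genes["is_X_linked"]
        & ~genes["is_Y_linked"]
        & ~genes["gene"].isin(planted_lineage_genes),
        "gene",
    ].to_numpy()
    deg_genes = (
        list(rng_cnv.choice(autosomal_pool, config.n_deg_genes, replace=False))
        if config.n_deg_genes
        else []
    )
    adata = _expression_layer(
        cells, embryo_sex, genes, markers, programs, deg_genes, cnvs, config, rng_expr
    )
    sites = _meth_sites(config, rng_sites)
    elements = _element_beds(config, genes, sites, rng_elements)
    tiles, dmr_truth = _plan_tiles(sites, elements, config, rng_tiles)
    meth = _methylome_layer(cells, sites, tiles, config, rng_meth, lambda_seq)
    bins = _bin_layer(cells, cnvs, embryo_sex, config, rng_bins)

    is_aneuploid = pd.Series(False, index=cells.index)
    if len(cnvs):
        is_aneuploid[cnvs["cell_id"].unique()] = True
    truth_cells = cells.copy()
    truth_cells["is_aneuploid"] = is_aneuploid
    truth = SyntheticTruth(
        cells=truth_cells,
        embryo_sex=embryo_sex,
        planted_cnvs=cnvs,
        planted_dmr_tiles=dmr_truth,
        marker_genes=markers,
        program_genes=programs,
        deg_genes=deg_genes,
        te_methylation_offset=config.te_methylation_offset,
    )
    return Cohort(
        expression=adata,
        methylome=meth,
        bins=bins,
        genes=genes,
        elements=elements,
        truth=truth,
        config=config,
    )


def generate_reference_stages(
    sites: pd.DataFrame,
    stage_levels: list[tuple[str, float]],
    n_per_stage: int = 5,
    depth_per_site: float = 5.0,
    seed: int = 0,
) -> MethylomeCohort:
    """Staged reference methylomes along a global demethylation gradient.

    ``stage_levels`` lists (stage label, global methylation level) from
    the earliest to the latest stage, e.g. 8-cell -> morula -> blastocyst.
    Per-sample site counts are binomial around a tile-level expectation
    drawn per stage around the stage's global level. The ``cells`` frame
    carries a ``stage`` column.
    """
    rng = np.random.default_rng(seed)
    n_sites = len(sites)
    tile_idx = pd.MultiIndex.from_arrays(
        [sites["chrom"], (sites["pos"] // TILE_SIZE) * TILE_SIZE]
    )
    codes, uniques = pd.factorize(tile_idx, sort=True)
    rows, meths, totals = [], [], []
    for stage, level in stage_levels:
        # per-tile expectation around the stage mean, shared across replicates
        a = max(level * 8, 0.2)
        b = max((1 - level) * 8, 0.2)
        tile_levels_ = rng.beta(a, b, size=len(uniques))
        site_levels = tile_levels_[codes]
        for r in range(n_per_stage):
            depth = rng.poisson(depth_per_site, size=n_sites).astype(np.int16)
            meth = rng.binomial(depth.astype(np.int64), site_levels).astype(np.int16)
            rows.append(
                {
                    "cell_id": f"ref_{stage}_{r:02d}",
                    "embryo_id": f"ref_{stage}_{r:02d}",
                    "group": "reference",
                    "lineage": "reference",
                    "stage": stage,
                }
            )
            meths.append(meth)
            totals.append(depth)
    cells = pd.DataFrame(rows).set_index("cell_id")
    return MethylomeCohort(
        sites=sites,
        meth=np.vstack(meths),
        total=np.vstack(totals),
        cells=cells,
    )
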
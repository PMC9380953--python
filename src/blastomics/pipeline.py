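"""End-to-end pipeline orchestration.

``run`` executes the stages in dependency order — simulate (or load) ->
RNA QC/normalize/filter -> lineage -> group comparison -> methylome ->
CNV (both layers) -> concordance — writing per-stage TSVs, a JSON
summary keyed by stage, a markdown report, and a log that records every
parameter actually used. Reruns with the same config and seed are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from blastomics import (
    cnv_expression,
    cnv_methylation,
    comparison,
    expression,
    lineage as lineage_mod,
    methylome,
    synthetic,
)
from blastomics.errors import ConfigurationError
from blastomics.synthetic import CohortConfig

log = logging.getLogger(__name__)

DEFAULT_REFERENCE_STAGES: list[tuple[str, float]] = [
    ("8cell", 0.60),
    ("morula", 0.45),
    ("blastocyst", 0.30),
]


@dataclass
class RunConfig:
    """All pipeline stage parameters.

    Analysis defaults are the study's stated thresholds: 4,000 detected
    genes for cell QC, ln(TPM/10+1) normalization with the >1-in->3-cells
    gene filter, min.pct 0.25 Wilcoxon DEG testing at |log2FC| > 1 and
    Bonferroni p < 0.01, Mean_X/Mean_Y > 2 for sexing, 300-bp tiles with
    the 10%/40% DMR rule, ±15-kb metaprofile flanks, 50-gene CNV score
    windows with the 60%-span / ≥3-cell filters, 1-Mb bins with the
    median-500 filters, and 100-window smoothing. ``toy()`` rescales only
    the data-scale-dependent QC floors to the synthetic toy genome.
    """

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # stage toggles
    with_comparison: bool = True
    with_methylome: bool = True
    with_cnv_rna: bool = True
    with_cnv_meth: bool = True
    # expression
    min_genes: int = 4000
    gene_filter_level: float = 1.0
    gene_filter_min_cells: int = 3
    # comparison
    min_pct: float = 0.25
    deg_alpha: float = 0.01
    deg_lfc_threshold: float = 1.0
    sex_ratio_threshold: float = 2.0
    # methylome
    meth_min_conversion: float = 0.99
    meth_min_sites: int = 2_000_000
    dmr_low: float = 0.10
    dmr_high: float = 0.40
    dmr_min_depth: int = 5
    flank_bp: int = 15_000
    meth_lineage: str = "TE"
    reference_stages: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_REFERENCE_STAGES)
    )
    reference_samples_per_stage: int = 5
    # expression CNV
    cnv_window: int = 50
    cnv_gain_threshold: float = 1.15
    cnv_loss_threshold: float = 0.85
    cnv_min_span: float = 0.6
    cnv_min_cells: int = 3
    cnv_min_run_genes: int = 20
    # methylation CNV
    bin_min_median: float = 500
    smooth_half_window: int = 50

    def validate(self) -> None:
        if not 0 <= self.dmr_low < self.dmr_high <= 1:
            raise ConfigurationError("dmr_low/dmr_high must satisfy 0 <= low < high <= 1")
        if not self.cnv_loss_threshold < 1 < self.cnv_gain_threshold:
            raise ConfigurationError(
                "cnv_loss_threshold < 1 < cnv_gain_threshold required"
            )
        if not 0 < self.cnv_min_span <= 1:
            raise ConfigurationError("cnv_min_span must lie in (0, 1]")
        if not 0 <= self.min_pct <= 1:
            raise ConfigurationError("min_pct must lie in [0, 1]")
        if self.min_genes < 0:
            raise ConfigurationError("min_genes must be non-negative")
        if self.meth_min_sites < 0:
            raise ConfigurationError("meth_min_sites must be non-negative")
        self.cohort.validate()

    @classmethod
    def toy(cls, seed: int = 0, **cohort_kwargs) -> "RunConfig":
        """Defaults rescaled to the synthetic toy genome.

        The toy genome carries ~2,000 genes and a 60-kb methylome region
        per chromosome, so the absolute QC floors (4,000 detected genes,
        2e6 covered CpGs) are scaled down proportionally; every analysis
        rule and relative threshold is unchanged.
        """
        cohort = CohortConfig(seed=seed, **cohort_kwargs)
        return cls(seed=seed, cohort=cohort, min_genes=1000, meth_min_sites=3000)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cohort"]["genome"] = [list(g) for g in self.cohort.genome]
        d["cohort"]["lineage_proportions"] = list(self.cohort.lineage_proportions)
        d["reference_stages"] = [list(s) for s in self.reference_stages]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cd = d.pop("cohort", {})
        cd["genome"] = [tuple(g) for g in cd.get("genome", synthetic.DEFAULT_GENOME)]
        cd["lineage_proportions"] = tuple(
            cd.get("lineage_proportions", (0.15, 0.10, 0.75))
        )
        d["cohort"] = CohortConfig(**cd)
        d["reference_stages"] = [
            (s, float(v)) for s, v in d.get("reference_stages", DEFAULT_REFERENCE_STAGES)
        ]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _round(obj, ndigits: int = 6):
    """Round floats recursively so summaries serialize stably."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run(config: RunConfig, outdir: str | Path, cohort=None) -> dict:
    """Execute the pipeline; returns (and writes) the summary dict."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("blastomics")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    log.info("parameters: %s", json.dumps(dataclasses.asdict(config), default=str, sort_keys=True))
    try:
        if cohort is None:
            config.cohort.seed = config.seed
            cohort = synthetic.generate_cohort(config.cohort)
        summary["simulate"] = {
            "n_cells": int(cohort.expression.n_obs),
            "n_genes": int(cohort.expression.n_vars),
            "n_embryos": int(cohort.truth.cells["embryo_id"].nunique()),
        }

        # --- expression -------------------------------------------------
        ad = cohort.expression
        n_before = ad.n_obs
        ad = expression.qc_filter_cells(ad, min_genes=config.min_genes)
        ad = expression.normalize_ln_tpm(ad)
        ad = expression.filter_genes(
            ad, level=config.gene_filter_level, min_cells=config.gene_filter_min_cells
        )
        groups_after = ad.obs["group"].value_counts().to_dict()
        summary["expression"] = {
            "n_cells_before_qc": n_before,
            "n_cells_after_qc": int(ad.n_obs),
            "n_genes_after_filter": int(ad.n_vars),
            "cells_per_group": {k: int(v) for k, v in groups_after.items()},
        }

        # --- lineage ----------------------------------------------------
        clusters = lineage_mod.cluster_cells(ad, n_clusters=3, seed=config.seed)
        assigned = lineage_mod.assign_lineages(ad, clusters)
        ad.obs["lineage"] = assigned
        signatures = lineage_mod.find_signatures(ad, assigned, min_pct=config.min_pct)
        scores = lineage_mod.lineage_scores(ad, signatures)
        scores.ternary.to_csv(out / "lineage_ternary.tsv", sep="\t")
        assigned.rename("lineage").to_csv(out / "lineage_assignments.tsv", sep="\t")
        summary["lineage"] = {
            "cells_per_lineage": {
                k: int(v) for k, v in assigned.value_counts().sort_index().items()
            },
            "signature_sizes": {k: int(len(v)) for k, v in signatures.items()},
        }

        # --- group comparison -------------------------------------------
        if config.with_comparison:
            deg_counts, r2 = {}, {}
            deg_tables = []
            for lin in sorted(assigned.unique()):
                sub = ad[ad.obs["lineage"] == lin]
                n_st = int((sub.obs["group"] == "ST").sum())
                n_icsi = int((sub.obs["group"] == "ICSI").sum())
                if min(n_st, n_icsi) < 3:
                    continue
                degs = comparison.deg_test(
                    ad,
                    lineage=lin,
                    min_pct=config.min_pct,
                    alpha=config.deg_alpha,
                    lfc_threshold=config.deg_lfc_threshold,
                )
                deg_tables.append(degs)
                deg_counts[lin] = {
                    "up": int((degs["direction"] == "up").sum()),
                    "down": int((degs["direction"] == "down").sum()),
                }
                r2[lin] = comparison.regression_similarity(ad, lin)
            if deg_tables:
                pd.concat(deg_tables).to_csv(out / "deg.tsv", sep="\t", index=False)
            sex_calls = comparison.infer_sex(
                ad, ratio_threshold=config.sex_ratio_threshold
            )
            sex_calls.to_csv(out / "sex_calls.tsv", sep="\t")
            summary["comparison"] = {
                "deg_counts": deg_counts,
                "r_squared": r2,
                "sex_counts": {
                    k: int(v) for k, v in sex_calls["sex"].value_counts().items()
                },
            }

        # --- methylome --------------------------------------------------
        if config.with_methylome:
            meth = cohort.methylome
            qc = methylome.cell_qc(
                meth,
                min_conversion=config.meth_min_conversion,
                min_sites=config.meth_min_sites,
            )
            qc.to_csv(out / "meth_qc.tsv", sep="\t")
            passed = meth.subset(qc.index[qc["passed"]])
            cell_levels, embryo_levels = methylome.cell_and_embryo_levels(passed)
            key = passed.cells["group"] + "/" + passed.cells["lineage"]
            group_levels = cell_levels.groupby(key).mean()
            scope = passed.subset(
                passed.cells.index[passed.cells["lineage"] == config.meth_lineage]
            )
            tiles = methylome.tile_levels(scope, scope.cells["group"])
            dmrs = methylome.call_dmrs(
                tiles["ST"],
                tiles["ICSI"],
                low=config.dmr_low,
                high=config.dmr_high,
                min_depth=config.dmr_min_depth,
            )
            dmrs.to_csv(out / "dmrs.tsv", sep="\t", index=False)
            annot = methylome.annotate_dmrs(dmrs, cohort.elements)
            annot.to_csv(out / "dmr_frequency.tsv", sep="\t", index=False)

            ref = synthetic.generate_reference_stages(
                meth.sites,
                config.reference_stages,
                n_per_stage=config.reference_samples_per_stage,
                seed=config.seed + 1,
            )
            study_tiles = methylome.cell_tile_levels(scope)
            ref_tiles = methylome.cell_tile_levels(ref)
            pt = methylome.pseudotime(
                study_tiles,
                ref_tiles,
                ref.cells["stage"],
                stage_order=[s for s, _ in config.reference_stages],
            )
            pt.samples.to_csv(out / "pseudotime.tsv", sep="\t")
            st_pt = pt.samples.loc[
                scope.cells.index[scope.cells["group"] == "ST"], "pseudotime"
            ]
            icsi_pt = pt.samples.loc[
                scope.cells.index[scope.cells["group"] == "ICSI"], "pseudotime"
            ]
            delay_p = float(
                mannwhitneyu(st_pt, icsi_pt, alternative="greater").pvalue
            )
            summary["methylome"] = {
                "n_cells_passing_qc": int(qc["passed"].sum()),
                "group_levels": {k: float(v) for k, v in group_levels.items()},
                "dmr_counts": {
                    k: int(v) for k, v in dmrs["class"].value_counts().items()
                },
                "pseudotime_delay_p": delay_p,
            }

        # --- CNV --------------------------------------------------------
        chrom_lengths = dict(config.cohort.genome)
        rna_states = None
        if config.with_cnv_rna:
            score_matrix = cnv_expression.cnv_scores(ad, window=config.cnv_window)
            ploidy = cnv_expression.call_cnvs(
                score_matrix,
                chrom_lengths,
                embryo_of=ad.obs["embryo_id"],
                gain_thr=config.cnv_gain_threshold,
                loss_thr=config.cnv_loss_threshold,
                min_span=config.cnv_min_span,
                min_cells=config.cnv_min_cells,
                min_run_genes=config.cnv_min_run_genes,
            )
            ploidy.cell_calls.to_csv(out / "cnv_rna_calls.tsv", sep="\t", index=False)
            ploidy.cnv_frequency.to_csv(out / "cnv_frequency.tsv", sep="\t")
            autosomes = [
                c for c, _ in config.cohort.genome if c not in ("chrX", "chrY")
            ]
            rna_states = cnv_expression.chromosome_states(ploidy, autosomes)
            by_group = ploidy.aneuploid.groupby(ad.obs["group"]).mean()
            summary["cnv_rna"] = {
                "aneuploid_fraction": {
                    k: float(v) for k, v in by_group.items()
                },
                "n_aneuploid_cells": int(ploidy.aneuploid.sum()),
            }

        if config.with_cnv_meth:
            filtered, report = cnv_methylation.filter_bins_and_cells(
                cohort.bins, min_median=config.bin_min_median
            )
            values = cnv_methylation.normalize_bins(filtered, control=None)
            profile = cnv_methylation.smooth_and_round(
                values, half_window=config.smooth_half_window
            )
            profile.to_csv(out / "cnv_meth_profile.tsv", sep="\t")
            summary["cnv_meth"] = {
                "n_cells": int(len(profile)),
                "n_windows": int(profile.shape[1]),
                "n_cells_removed": len(report["removed_cells"]),
            }
            if rna_states is not None:
                table, frac = cnv_methylation.concordance(rna_states, profile)
                table.to_csv(out / "cnv_concordance.tsv", sep="\t", index=False)
                summary["concordance"] = {"fraction": float(frac)}

        summary = _round(summary)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_report(summary, out / "report.md")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_report(summary: dict, path: Path) -> None:
    lines = ["# Pipeline report", ""]
    lines.append(f"Config hash: `{summary['config_hash']}`, seed {summary['seed']}.")
    for stage in (
        "simulate",
        "expression",
        "lineage",
        "comparison",
        "methylome",
        "cnv_rna",
        "cnv_meth",
        "concordance",
    ):
        if stage not in summary:
            continue
        lines.append("")
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("| key | value |")
        lines.append("| --- | --- |")
        for k, v in summary[stage].items():
            lines.append(f"| {k} | {v} |")
    path.write_text("\n".join(lines) + "\n")
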
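"""Methylome QC, tile pooling, DMR calling, metaprofiles, pseudotime."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from blastomics import methylome
from blastomics.errors import DataError
from blastomics.methylome import MethylomeCohort
from blastomics.synthetic import generate_cohort, generate_reference_stages

from conftest import small_config


def make_meth(records, lambda_conv=None, groups=None):
    """Build a MethylomeCohort from {cell: [(chrom, pos, c, t), ...]}."""
    sites = sorted({(chrom, pos) for recs in records.values() for chrom, pos, _, _ in recs})
    site_df = pd.DataFrame(sites, columns=["chrom", "pos"])
    idx = {s: j for j, s in enumerate(sites)}
    cells = list(records)
    meth = np.zeros((len(cells), len(sites)), dtype=int)
    total = np.zeros_like(meth)
    for i, cell in enumerate(cells):
        for chrom, pos, c, t in records[cell]:
            meth[i, idx[(chrom, pos)]] = c
            total[i, idx[(chrom, pos)]] = c + t
    cell_df = pd.DataFrame(
        {
            "embryo_id": [c.split("_")[0] for c in cells],
            "group": groups if groups else ["ST"] * len(cells),
            "lineage": ["TE"] * len(cells),
        },
        index=cells,
    )
    lam = pd.DataFrame(index=pd.Index([], name="cell_id"))
    if lambda_conv:
        lam = pd.DataFrame(
            {"conversion": [lambda_conv.get(c, np.nan) for c in cells]},
            index=pd.Index(cells, name="cell_id"),
        ).dropna()
    return MethylomeCohort(
        sites=site_df, meth=meth, total=total, cells=cell_df, lambda_stats=lam
    )


class TestCellQC:
    def test_passing_cell(self):
        m = make_meth(
            {"E0_a": [("chr1", p, 1, 1) for p in range(5)]}, {"E0_a": 0.995}
        )
        report = methylome.cell_qc(m, min_sites=5)
        assert report.loc["E0_a", "passed"]

    def test_conversion_exactly_at_threshold_fails(self):
        m = make_meth({"E0_a": [("chr1", 0, 1, 1)]}, {"E0_a": 0.99})
        report = methylome.cell_qc(m, min_sites=1)
        assert not report.loc["E0_a", "passed"]
        assert "conversion" in report.loc["E0_a", "reason"]

    def test_missing_lambda_fails_with_reason(self):
        m = make_meth({"E0_a": [("chr1", 0, 1, 1)]})
        report = methylome.cell_qc(m, min_sites=1)
        assert not report.loc["E0_a", "passed"]
        assert "lambda" in report.loc["E0_a", "reason"]

    def test_covered_sites_match_bruteforce_count(self, cohort):
        report = methylome.cell_qc(cohort.methylome, min_sites=0)
        m = cohort.methylome
        for i, cell in enumerate(m.cell_ids[:10]):
            brute = sum(1 for v in m.total[i] if v > 0)
            assert report.loc[cell, "covered_sites"] == brute


class TestLevels:
    def test_two_sites_average(self):
        m = make_meth({"E0_a": [("chr1", 0, 2, 0), ("chr1", 5, 0, 3)]})
        cell, embryo = methylome.cell_and_embryo_levels(m)
        assert cell["E0_a"] == pytest.approx(0.5)

    def test_embryo_is_mean_of_cells(self):
        m = make_meth(
            {
                "E0_a": [("chr1", 0, 1, 4)],  # 0.2
                "E0_b": [("chr1", 0, 2, 3)],  # 0.4
            }
        )
        _, embryo = methylome.cell_and_embryo_levels(m)
        assert embryo["E0"] == pytest.approx(0.3)

    def test_matches_site_mean_oracle(self, cohort):
        m = cohort.methylome
        cell, _ = methylome.cell_and_embryo_levels(m)
        i = 3
        covered = m.total[i] > 0
        brute = np.mean(m.meth[i, covered] / m.total[i, covered])
        assert cell.iloc[i] == pytest.approx(brute, abs=1e-12)

    def test_zero_coverage_cell_excluded_with_warning(self):
        m = make_meth({"E0_a": [("chr1", 0, 1, 1)], "E0_b": [("chr1", 0, 0, 0)]})
        with pytest.warns(UserWarning, match="zero covered"):
            cell, _ = methylome.cell_and_embryo_levels(m)
        assert "E0_b" not in cell.index


class TestTileLevels:
    def test_pooled_not_averaged(self):
        """(C=2,T=2) + (C=0,T=4) pools to 2/8, not mean(0.5, 0)."""
        m = make_meth(
            {"E0_a": [("chr1", 10, 2, 2)], "E0_b": [("chr1", 20, 0, 4)]}
        )
        tiles = methylome.tile_levels(m)["all"]
        assert len(tiles) == 1
        assert tiles["level"].iloc[0] == pytest.approx(0.25)

    def test_zero_read_tile_missing(self):
        m = make_meth({"E0_a": [("chr1", 10, 1, 1), ("chr1", 400, 0, 0)]})
        tiles = methylome.tile_levels(m)["all"]
        assert tiles["start"].tolist() == [0]

    def test_half_open_tile_boundary(self):
        m = make_meth({"E0_a": [("chr1", 300, 1, 0)]})
        tiles = methylome.tile_levels(m)["all"]
        assert (tiles["start"].iloc[0], tiles["end"].iloc[0]) == (300, 600)

    def test_pooled_level_is_count_weighted_mean(self, cohort):
        m = cohort.methylome.subset(cohort.methylome.cell_ids[:20])
        tiles = methylome.tile_levels(m)["all"]
        per_cell = methylome.cell_tile_levels(m)
        weights = np.zeros(per_cell.shape)
        starts = (m.sites["pos"] // 300) * 300
        key = pd.MultiIndex.from_arrays([m.sites["chrom"], starts])
        codes, uniq = pd.factorize(key, sort=True)
        np.add.at(weights.T, codes, m.total.T)
        tile0 = (tiles["chrom"].iloc[0], tiles["start"].iloc[0])
        j = list(uniq).index(tile0)
        w = weights[:, j]
        lv = per_cell.iloc[:, j]
        expected = np.nansum(w * lv) / w.sum()
        assert tiles["level"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestDmrCalling:
    def _tiles(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "c", "t"])
        df["end"] = df["start"] + 300
        df["total"] = df["c"] + df["t"]
        df["level"] = df["c"] / df["total"]
        return df[["chrom", "start", "end", "c", "t", "level"]]

    def test_double_threshold_rule(self):
        st = self._tiles([("chr1", 0, 45, 55), ("chr1", 300, 30, 70)])
        icsi = self._tiles([("chr1", 0, 5, 95), ("chr1", 300, 5, 95)])
        dmrs = methylome.call_dmrs(st, icsi)
        assert dmrs["class"].tolist() == ["hyper_in_ST"]
        assert dmrs["start"].tolist() == [0]  # 0.30 <= 0.40 is not a DMR

    def test_matches_bruteforce_double_threshold_scan(self):
        rng = np.random.default_rng(0)
        n = 300
        rows_a = [("chr1", i * 300, rng.integers(0, 20), rng.integers(1, 20)) for i in range(n)]
        rows_b = [("chr1", i * 300, rng.integers(0, 20), rng.integers(1, 20)) for i in range(n)]
        a, b = self._tiles(rows_a), self._tiles(rows_b)
        dmrs = methylome.call_dmrs(a, b, min_depth=0)
        expected = set()
        for i in range(n):
            la = rows_a[i][2] / (rows_a[i][2] + rows_a[i][3])
            lb = rows_b[i][2] / (rows_b[i][2] + rows_b[i][3])
            if lb < 0.10 and la > 0.40:
                expected.add((i * 300, "hyper_in_ST"))
            if la < 0.10 and lb > 0.40:
                expected.add((i * 300, "hypo_in_ST"))
        assert set(zip(dmrs["start"], dmrs["class"])) == expected

    def test_label_swap_swaps_classes(self):
        rng = np.random.default_rng(1)
        rows_a = [("chr1", i * 300, rng.integers(0, 10), rng.integers(1, 10)) for i in range(100)]
        rows_b = [("chr1", i * 300, rng.integers(0, 10), rng.integers(1, 10)) for i in range(100)]
        a, b = self._tiles(rows_a), self._tiles(rows_b)
        fwd = methylome.call_dmrs(a, b, min_depth=0)
        rev = methylome.call_dmrs(b, a, min_depth=0)
        assert (fwd["class"] == "hyper_in_ST").sum() == (rev["class"] == "hypo_in_ST").sum()
        assert (fwd["class"] == "hypo_in_ST").sum() == (rev["class"] == "hyper_in_ST").sum()

    def test_low_depth_tiles_not_compared(self):
        st = self._tiles([("chr1", 0, 2, 0)])  # level 1.0 but depth 2
        icsi = self._tiles([("chr1", 0, 0, 2)])
        assert len(methylome.call_dmrs(st, icsi, min_depth=5)) == 0


class TestAnnotateDmrs:
    def _dmrs(self, starts, cls="hyper_in_ST"):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": [s + 300 for s in starts],
                "class": cls,
            }
        )

    def test_frequency_definition(self):
        """5 DMRs inside CGIs out of 100 CGIs -> 0.05."""
        cgis = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(100) * 10_000,
                "end": np.arange(100) * 10_000 + 1000,
            }
        )
        dmrs = self._dmrs([i * 10_000 + 100 for i in range(5)])
        table = methylome.annotate_dmrs(dmrs, {"CGI": cgis})
        assert table["frequency"].iloc[0] == pytest.approx(0.05)

    def test_no_overlap_gives_zero(self):
        cgis = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [500]})
        table = methylome.annotate_dmrs(self._dmrs([0]), {"CGI": cgis})
        assert table["frequency"].iloc[0] == 0

    def test_empty_element_class_reports_missing(self):
        table = methylome.annotate_dmrs(
            self._dmrs([0]), {"CGI": pd.DataFrame(columns=["chrom", "start", "end"])}
        )
        assert table.empty or table["frequency"].isna().all()

    def test_matches_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(2)
        dmr_starts = rng.integers(0, 50_000, 40)
        dmrs = self._dmrs(sorted(dmr_starts))
        elements = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": rng.integers(0, 50_000, 30),
            }
        )
        elements["end"] = elements["start"] + rng.integers(100, 2000, 30)
        table = methylome.annotate_dmrs(dmrs, {"rep": elements})
        brute = sum(
            any(
                ds < ee and es < ds + 300
                for es, ee in zip(elements["start"], elements["end"])
            )
            for ds in dmrs["start"]
        )
        assert table["n_dmrs_overlapping"].iloc[0] == brute
        assert table["frequency"].iloc[0] == pytest.approx(brute / 30)


class TestMetaprofile:
    def _uniform_cohort(self, level, n_sites=600, span=6000):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(span, n_sites, replace=False))
        recs = {
            "E0_a": [("chr1", int(p), int(10 * level), int(10 * (1 - level))) for p in pos]
        }
        return make_meth(recs)

    def test_uniform_methylation_gives_flat_curve(self):
        m = self._uniform_cohort(0.3)
        features = pd.DataFrame(
            {"chrom": ["chr1"], "start": [2000], "end": [4000], "strand": ["+"]}
        )
        per_cell, per_group = methylome.metaprofile(
            m, features, flank_bp=1500, body_bins=10, flank_bins=5
        )
        curve = per_group.iloc[0].dropna()
        assert np.allclose(curve, 0.3, atol=1e-9)

    def test_planted_hypomethylated_center_gives_u_shape(self):
        rng = np.random.default_rng(4)
        recs = []
        for p in range(0, 6000, 10):
            level = 0.05 if 2000 <= p < 4000 else 0.6
            recs.append(("chr1", p, int(20 * level), int(20 * (1 - level))))
        m = make_meth({"E0_a": recs})
        features = pd.DataFrame(
            {"chrom": ["chr1"], "start": [2000], "end": [4000], "strand": ["+"]}
        )
        _, per_group = methylome.metaprofile(
            m, features, flank_bp=1500, body_bins=10, flank_bins=5
        )
        curve = per_group.iloc[0]
        body = curve.iloc[5:15]
        flanks = pd.concat([curve.iloc[:5], curve.iloc[15:]])
        assert body.max() < 0.1
        assert flanks.min() > 0.5

    def test_minus_strand_reverses_profile(self):
        recs = []
        for p in range(0, 3000, 10):
            level = 0.9 if p < 1000 else 0.1  # asymmetric signal
            recs.append(("chr1", p, int(10 * level), int(10 * (1 - level))))
        m = make_meth({"E0_a": recs})
        plus = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2000], "strand": ["+"]})
        minus = plus.assign(strand="-")
        _, g_plus = methylome.metaprofile(m, plus, flank_bp=900, body_bins=10, flank_bins=5)
        _, g_minus = methylome.metaprofile(m, minus, flank_bp=900, body_bins=10, flank_bins=5)
        assert np.allclose(
            g_plus.iloc[0].to_numpy(), g_minus.iloc[0].to_numpy()[::-1], equal_nan=True
        )

    def test_short_feature_skipped_with_warning(self):
        m = self._uniform_cohort(0.3)
        features = pd.DataFrame(
            {"chrom": ["chr1"], "start": [2000], "end": [2005], "strand": ["+"]}
        )
        with pytest.warns(UserWarning, match="skipped"):
            methylome.metaprofile(m, features, body_bins=10, flank_bins=5)


class TestPseudotime:
    @pytest.fixture(scope="class")
    def gradient(self):
        cfg = small_config(seed=17)
        cohort = generate_cohort(cfg)
        stages = [(f"s{i}", lv) for i, lv in enumerate(np.linspace(0.8, 0.2, 6))]
        ref = generate_reference_stages(
            cohort.methylome.sites, stages, n_per_stage=5, seed=4
        )
        return ref, stages

    def test_pc1_tracks_demethylation_gradient(self, gradient):
        ref, stages = gradient
        tiles = methylome.cell_tile_levels(ref)
        half = tiles.iloc[: len(tiles) // 2]
        rest = tiles.iloc[len(tiles) // 2 :]
        res = methylome.pseudotime(
            half,
            rest,
            ref.cells["stage"].loc[rest.index],
            stage_order=[s for s, _ in stages],
        )
        stage_rank = ref.cells["stage"].str[1:].astype(int)
        rho = spearmanr(
            res.samples["pseudotime"], -stage_rank.loc[res.samples.index]
        ).statistic
        assert rho >= 0.95

    def test_duplicated_sample_gets_identical_pseudotime(self, gradient):
        ref, stages = gradient
        tiles = methylome.cell_tile_levels(ref)
        study = tiles.iloc[[0]].rename(index={tiles.index[0]: "dup"})
        res = methylome.pseudotime(
            study, tiles, ref.cells["stage"], stage_order=[s for s, _ in stages]
        )
        assert res.samples.loc["dup", "pseudotime"] == pytest.approx(
            res.samples.loc[tiles.index[0], "pseudotime"], abs=1e-9
        )

    def test_delayed_group_shifts_toward_earlier_stages(self):
        cfg = small_config(
            seed=23,
            te_methylation_offset=0.05,
            cells_per_embryo=30,
            meth_depth_per_site=5.0,
            dmr_tile_fraction=0.0,
        )
        cohort = generate_cohort(cfg)
        m = cohort.methylome
        te = m.subset(m.cells.index[m.cells["lineage"] == "TE"])
        stages = [("8cell", 0.6), ("morula", 0.45), ("blastocyst", 0.3)]
        ref = generate_reference_stages(m.sites, stages, n_per_stage=5, seed=5)
        res = methylome.pseudotime(
            methylome.cell_tile_levels(te),
            methylome.cell_tile_levels(ref),
            ref.cells["stage"],
            stage_order=[s for s, _ in stages],
        )
        st = res.samples.loc[te.cells.index[te.cells["group"] == "ST"], "pseudotime"]
        icsi = res.samples.loc[te.cells.index[te.cells["group"] == "ICSI"], "pseudotime"]
        p = mannwhitneyu(st, icsi, alternative="greater").pvalue
        assert p < 0.05

    def test_fewer_than_two_stages_raises(self, gradient):
        ref, stages = gradient
        tiles = methylome.cell_tile_levels(ref)
        one_stage = ref.cells["stage"] == "s0"
        with pytest.raises(DataError, match="stages"):
            methylome.pseudotime(
                tiles[~one_stage.to_numpy()].iloc[:2],
                tiles[one_stage.to_numpy()],
                ref.cells["stage"][one_stage],
                stage_order=[s for s, _ in stages],
            )
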
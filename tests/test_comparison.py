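"""ST-vs-ICSI contrasts: Wilcoxon machinery, DEG calling, R^2, sexing."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from blastomics import comparison
from blastomics.errors import DataError
from blastomics.stats import bonferroni, wilcoxon_exact, wilcoxon_pvalues

from conftest import make_adata, prepare_expression, small_config
from blastomics.synthetic import generate_cohort


def enumeration_pvalue(x, y):
    """Independent brute-force permutation null of the rank sum."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    sums = [
        ranks[list(idx)].sum()
        for idx in combinations(range(len(pooled)), len(x))
    ]
    sums = np.array(sums)
    p_le = np.mean(sums <= w_obs + 1e-9)
    p_ge = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, 2)
        x = rng.integers(0, 5, n1).astype(float)  # ties likely
        y = rng.integers(0, 5, n2).astype(float)
        assert wilcoxon_exact(x, y) == pytest.approx(
            enumeration_pvalue(x, y), abs=1e-12
        )

    def test_small_groups_route_to_exact(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(6, 3))
        p = wilcoxon_pvalues(x, y)
        expected = [enumeration_pvalue(x[:, j], y[:, j]) for j in range(3)]
        assert np.allclose(p, expected, atol=1e-12)

    def test_asymptotic_detects_shift(self):
        rng = np.random.default_rng(2)
        x = rng.normal(2, 1, (30, 1))
        y = rng.normal(0, 1, (30, 1))
        assert wilcoxon_pvalues(x, y)[0] < 1e-6

    def test_all_tied_column_gives_p_one(self):
        p = wilcoxon_pvalues(np.ones((20, 1)), np.ones((20, 1)))
        assert p[0] == 1.0


def test_bonferroni_monotone_capped_never_below_raw():
    p = np.array([1e-5, 0.01, 0.5, 0.9])
    adj = bonferroni(p, 100)
    assert (adj >= p).all()
    assert (adj <= 1).all()
    assert (np.diff(adj) >= 0).all()


class TestDegTest:
    @pytest.fixture(scope="class")
    def planted(self):
        """100 TE cells per group with 20 genes at 4x in ST."""
        cfg = small_config(
            seed=21,
            n_embryos_per_group=5,
            cells_per_embryo=27,
            lineage_proportions=(0.15, 0.10, 0.75),
            n_deg_genes=20,
            aneuploid_cell_fraction=0.0,
            low_quality_cell_fraction=0.0,
            meth_region_bp=600,
        )
        cohort = generate_cohort(cfg)
        return prepare_expression(cohort), cohort.truth

    def test_null_cohort_yields_no_autosomal_degs(self, prepared):
        """No planted group effect -> no autosomal DEGs.

        Sex-linked genes are excluded: when the random sex draw leaves the
        two arms with different sex ratios, X/Y-linked genes are genuinely
        differential — the compositional confound, not a false positive.
        """
        degs = comparison.deg_test(prepared, "TE")
        autosomal = ~degs["gene"].str.startswith(("chrX", "chrY"))
        assert (degs.loc[autosomal, "direction"] != "ns").sum() == 0

    def test_planted_4x_genes_all_recovered(self, planted):
        ad, truth = planted
        degs = comparison.deg_test(ad, "TE")
        up = set(degs.loc[degs["direction"] == "up", "gene"])
        assert set(truth.deg_genes) <= up
        assert len(up - set(truth.deg_genes)) <= 1

    def test_label_swap_negates_log2fc_exactly(self, planted):
        ad, _ = planted
        degs = comparison.deg_test(ad, "TE")
        flipped = ad.copy()
        flipped.obs["group"] = flipped.obs["group"].map({"ST": "ICSI", "ICSI": "ST"})
        degs_f = comparison.deg_test(flipped, "TE")
        merged = degs.merge(degs_f, on="gene", suffixes=("", "_swap"))
        assert np.allclose(
            merged["log2_fold_change"], -merged["log2_fold_change_swap"], atol=1e-12
        )
        assert (degs["direction"] == "up").sum() == (degs_f["direction"] == "down").sum()

    def test_deg_record_invariants(self, planted):
        ad, _ = planted
        degs = comparison.deg_test(ad, "TE")
        assert degs["pct_ST"].between(0, 1).all()
        assert degs["pct_ICSI"].between(0, 1).all()
        assert np.allclose(
            degs["p_adj"], np.minimum(1.0, degs["p_raw"] * len(degs))
        )
        up = degs["direction"] == "up"
        assert ((degs["log2_fold_change"] > 1) & (degs["p_adj"] < 0.01)).equals(up)

    def test_too_few_cells_raise(self, prepared):
        tiny = prepared[:4]
        with pytest.raises(DataError, match=">=3"):
            comparison.deg_test(tiny, "TE")


class TestRegression:
    def test_identical_groups_give_r2_one(self):
        x = np.tile(np.random.default_rng(0).uniform(0.1, 3, (1, 30)), (6, 1))
        ad = make_adata(x, normalized=True, groups=["ST"] * 3 + ["ICSI"] * 3)
        assert comparison.regression_similarity(ad, None) == pytest.approx(1.0)

    def test_exact_linear_relation_gives_r2_one(self):
        base = np.random.default_rng(1).uniform(0.1, 2, 25)
        x = np.vstack([np.tile(2 * base, (3, 1)), np.tile(base, (3, 1))])
        ad = make_adata(x, normalized=True, groups=["ST"] * 3 + ["ICSI"] * 3)
        assert comparison.regression_similarity(ad, None) == pytest.approx(1.0)

    def test_null_cohort_r2_high(self, prepared):
        assert comparison.regression_similarity(prepared, "TE") > 0.98

    def test_constant_means_raise(self):
        x = np.ones((6, 10))
        ad = make_adata(x, normalized=True, groups=["ST"] * 3 + ["ICSI"] * 3)
        with pytest.raises(DataError):
            comparison.regression_similarity(ad, None)


class TestDownsample:
    def test_full_size_equals_undownsampled(self, prepared):
        n = int((prepared.obs["lineage"].eq("TE") & prepared.obs["group"].eq("ST")).sum())
        m = int((prepared.obs["lineage"].eq("TE") & prepared.obs["group"].eq("ICSI")).sum())
        size = min(n, m)
        # at full size of the smaller group the subsample of that group is fixed
        table = comparison.downsample_similarity(prepared, "TE", [size], reps=2, seed=0)
        assert table["mean_r2"].iloc[0] == pytest.approx(
            comparison.regression_similarity(prepared, "TE"), abs=0.02
        )

    def test_r2_declines_with_size(self, prepared):
        table = comparison.downsample_similarity(
            prepared, "TE", [40, 5], reps=5, seed=0
        )
        big, small = table["mean_r2"].to_numpy()
        sd = table["sd_r2"].max()
        assert small <= big + 2 * sd

    def test_seed_determinism(self, prepared):
        t1 = comparison.downsample_similarity(prepared, "TE", [10], reps=3, seed=5)
        t2 = comparison.downsample_similarity(prepared, "TE", [10], reps=3, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_oversized_request_raises(self, prepared):
        with pytest.raises(DataError, match="exceeds"):
            comparison.downsample_similarity(prepared, "TE", [10_000], reps=1, seed=0)


class TestVariance:
    def test_matches_textbook_sd(self, prepared):
        table = comparison.expression_variance(prepared)
        row = table[(table["lineage"] == "TE") & (table["group"] == "ST")]
        mask = (
            prepared.obs["lineage"].eq("TE") & prepared.obs["group"].eq("ST")
        ).to_numpy()
        expected = np.asarray(prepared.X)[mask].std(axis=0, ddof=1)
        assert np.allclose(row["sd"].to_numpy(), expected, atol=1e-12)

    def test_constant_gene_has_zero_sd(self):
        x = np.ones((8, 3))
        x[:, 1] = np.arange(8)
        ad = make_adata(x, normalized=True, groups=["ST"] * 4 + ["ICSI"] * 4)
        ad.obs["lineage"] = "TE"
        table = comparison.expression_variance(ad)
        assert (table.loc[table["gene"] == "g0", "sd"] == 0).all()


class TestInferSex:
    def _sex_adata(self, x_val, y_val):
        x = np.zeros((2, 4))
        x[:, :2] = x_val
        x[:, 2:] = y_val
        ad = make_adata(x, normalized=True)
        ad.obs["embryo_id"] = ["E0", "E0"]
        ad.var["is_X_linked"] = [True, True, False, False]
        ad.var["is_Y_linked"] = [False, False, True, True]
        return ad

    def test_ratio_above_two_is_female(self):
        calls = comparison.infer_sex(self._sex_adata(10.0, 2.0))
        assert calls.loc["E0", "sex"] == "female"
        assert calls.loc["E0", "ratio"] == pytest.approx(5.0)

    def test_ratio_exactly_two_is_male(self):
        calls = comparison.infer_sex(self._sex_adata(4.0, 2.0))
        assert calls.loc["E0", "sex"] == "male"

    def test_zero_mean_y_treated_as_female(self):
        calls = comparison.infer_sex(self._sex_adata(1.0, 0.0))
        assert calls.loc["E0", "sex"] == "female"
        assert np.isinf(calls.loc["E0", "ratio"])

    def test_cohort_agreement_with_truth(self, prepared, cohort):
        calls = comparison.infer_sex(prepared)
        truth = cohort.truth.embryo_sex.reindex(calls.index)
        assert (calls["sex"] == truth).all()

    def test_empty_gene_lists_raise(self, prepared):
        with pytest.raises(DataError):
            comparison.infer_sex(prepared, x_genes=[], y_genes=["a"])


class TestSexRatioSimulation:
    @pytest.fixture(scope="class")
    def sexed_cohort(self):
        # treatment arms with the study-style compositional imbalance:
        # female-rich ST vs male-rich ICSI
        cfg = small_config(
            seed=33,
            n_embryos_per_group=8,
            cells_per_embryo=12,
            aneuploid_cell_fraction=0.0,
            low_quality_cell_fraction=0.0,
            female_fraction=0.74,
            female_fraction_icsi=0.36,
            meth_region_bp=600,
        )
        cohort = generate_cohort(cfg)
        return prepare_expression(cohort), cohort.truth

    def test_imbalance_raises_sex_linked_fraction(self, sexed_cohort):
        ad, truth = sexed_cohort
        sexes = truth.embryo_sex
        obs = ad.obs
        st = obs.loc[obs["group"] == "ST", "embryo_id"].unique()
        icsi = obs.loc[obs["group"] == "ICSI", "embryo_id"].unique()
        n_f_st = sum(sexes[e] == "female" for e in st)
        n_m_st = len(st) - n_f_st
        icsi_frac = np.mean([sexes[e] == "female" for e in icsi])
        # the feasible composition closest to / farthest from the control ratio
        options = {
            n: abs(n / (n + n_m_st) - icsi_frac) for n in range(n_f_st + 1)
        }
        matched = min(options, key=options.get)
        imbalanced = max(options, key=options.get)
        table = comparison.sex_ratio_simulation(
            ad,
            female_counts_to_test=[matched, imbalanced],
            reps=2,
            seed=1,
            embryo_sex=sexes,
        )
        frac = table.set_index("n_female_ST")["sex_linked_deg_fraction"]
        assert frac[imbalanced] > frac[matched]

    def test_seed_determinism(self, sexed_cohort):
        ad, truth = sexed_cohort
        kw = dict(female_counts_to_test=[2], reps=2, seed=9, embryo_sex=truth.embryo_sex)
        t1 = comparison.sex_ratio_simulation(ad, **kw)
        t2 = comparison.sex_ratio_simulation(ad, **kw)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unavailable_composition_raises(self, sexed_cohort):
        ad, truth = sexed_cohort
        with pytest.raises(DataError, match="unavailable"):
            comparison.sex_ratio_simulation(
                ad, female_counts_to_test=[100], reps=1, seed=0,
                embryo_sex=truth.embryo_sex,
            )
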
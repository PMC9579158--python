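"""Desirability mappings, per-dataset and overall scores, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyscore.scoring import (
    DesirabilityParams,
    concordance_factor,
    d_dataset,
    d_overall,
    desirability_foldchange,
    desirability_midbrain,
    desirability_pvalue,
    group_score,
    rank_genes,
    score_genes,
    to_rnk,
    weighted_geometric_mean,
)

PARAMS = DesirabilityParams()


class TestPvalueDesirability:
    def test_above_upper_cut_gets_floor(self):
        assert desirability_pvalue(0.2, PARAMS, p_low=1e-6) == 0.01

    def test_dataset_minimum_gets_maximum(self):
        p = np.array([1e-6, 0.01, 0.2, 0.9])
        d = desirability_pvalue(p, PARAMS, p_low=float(p.min()))
        assert d[0] == 1.0

    def test_linear_midpoint(self):
        p_low = 0.001
        mid = (p_low + 0.05) / 2
        assert desirability_pvalue(mid, PARAMS, p_low=p_low) == pytest.approx(0.505)

    def test_explicit_numeric_low_cut_above_high_cut_raises(self):
        bad = DesirabilityParams(p_low_cut=0.2)
        with pytest.raises(ValueError, match="p_low_cut"):
            desirability_pvalue(0.1, bad, p_low=None)

    def test_degenerate_dataset_min_above_cut_floors_everything(self):
        d = desirability_pvalue(np.array([0.3, 0.6]), PARAMS, p_low=0.3)
        assert (d == 0.01).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            desirability_pvalue(0.0, PARAMS, p_low=1e-4)


class TestFoldChangeDesirability:
    @pytest.mark.parametrize(
        "log2fc,expected",
        [
            (1.5, 1.0),     # FC ~2.83 > 2
            (0.1, 0.01),    # FC ~1.07 < 1.25
            (-1.5, 1.0),    # symmetric in magnitude
            (0.0, 0.01),
        ],
    )
    def test_cut_points_and_symmetry(self, log2fc, expected):
        assert desirability_foldchange(log2fc, PARAMS) == expected

    def test_linear_midpoint_in_fold_change(self):
        mid_fc = (1.25 + 2.0) / 2
        assert desirability_foldchange(np.log2(mid_fc), PARAMS) == pytest.approx(0.505)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            desirability_foldchange(np.inf, PARAMS)


class TestMidbrainDesirability:
    def test_detected_and_undetected_scores(self):
        assert desirability_midbrain(True, PARAMS) == 1.0
        assert desirability_midbrain(False, PARAMS) == 0.25

    def test_toggling_flag_scales_d_dataset_by_fixed_factor(self):
        with_mb = d_dataset(0.5, 0.5, 1.0, PARAMS)
        without = d_dataset(0.5, 0.5, 0.25, PARAMS)
        assert without / with_mb == pytest.approx(0.25 ** (0.01 / 1.51), rel=1e-12)


class TestDDataset:
    def test_identity_on_all_ones(self):
        assert d_dataset(1.0, 1.0, 1.0, PARAMS) == pytest.approx(1.0)

    def test_single_factor_example(self):
        assert d_dataset(0.5, 1.0, 1.0, PARAMS) == pytest.approx(
            np.exp(np.log(0.5) / 1.51), rel=1e-12
        )

    def test_unexpressed_gene_floors_at_001(self):
        assert d_dataset(1.0, 1.0, 1.0, PARAMS, expressed=False) == 0.01

    def test_nonpositive_desirability_rejected(self):
        with pytest.raises(ValueError):
            d_dataset(0.0, 0.5, 1.0, PARAMS)

    def test_matches_brute_force_weighted_geometric_mean(self):
        """exp(sum w ln d / sum w) on 1000 random desirability triples."""
        rng = np.random.default_rng(4)
        triples = rng.uniform(0.01, 1.0, size=(1000, 3))
        w = np.array([1.0, 0.5, 0.01])
        got = d_dataset(triples[:, 0], triples[:, 1], triples[:, 2], PARAMS)
        ref = np.exp((np.log(triples) * w).sum(axis=1) / w.sum())
        assert np.max(np.abs(got - ref)) < 1e-12


class TestConcordance:
    def test_full_agreement(self):
        c, d = concordance_factor([1.0] * 6, PARAMS)
        assert c == 1.0 and d == 1.0

    def test_maximal_discordance_floors(self):
        c, d = concordance_factor([1, 1, 1, -1, -1, -1], PARAMS)
        assert c == 0.0 and d == 0.01

    def test_five_up_one_down(self):
        c, d = concordance_factor([2, 1, 0.5, 0.3, 0.2, -1], PARAMS)
        assert c == pytest.approx(4 / 6)
        assert d == pytest.approx(0.01 + (4 / 6) * 0.99)

    def test_single_expressed_dataset_is_fully_concordant(self):
        c, d = concordance_factor([-0.7], PARAMS)
        assert c == 1.0 and d == 1.0

    def test_zero_fold_changes_are_excluded(self):
        c, _ = concordance_factor([1.0, 0.0, -1.0], PARAMS)
        assert c == 0.0

    def test_no_expressed_datasets_floors_with_nan_concordance(self):
        c, d = concordance_factor([], PARAMS)
        assert np.isnan(c) and d == 0.01


class TestDOverall:
    def test_idempotent_on_equal_inputs(self):
        assert d_overall([0.3] * 6, 0.3, PARAMS) == pytest.approx(0.3)

    def test_one_tenth_weight_construction(self):
        # all datasets at 1, concordance at 0.01: result = 0.01**0.1
        assert d_overall([1.0] * 6, 0.01, PARAMS) == pytest.approx(
            0.01 ** 0.1, rel=1e-12
        )

    def test_strictly_increasing_in_any_dataset_score(self):
        base = d_overall([0.2, 0.3, 0.4, 0.5, 0.6, 0.7], 0.5, PARAMS)
        bumped = d_overall([0.25, 0.3, 0.4, 0.5, 0.6, 0.7], 0.5, PARAMS)
        assert bumped > base

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            d_overall([], 0.5, PARAMS)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
           st.floats(0.01, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_in_unit_interval(self, ds, conc):
        val = d_overall(ds, conc, PARAMS)
        assert 0.0 < val <= 1.0 + 1e-12


class TestGroupScore:
    def test_singleton_is_identity(self):
        assert group_score([0.37]) == pytest.approx(0.37)

    def test_geometric_mean_example(self):
        assert group_score([0.04, 0.25]) == pytest.approx(0.1, rel=1e-12)

    def test_all_ones(self):
        assert group_score([1.0, 1.0]) == 1.0

    def test_empty_subset_raises(self):
        with pytest.raises(ValueError):
            group_score([])


class TestRankGenes:
    def test_distinct_scores_strictly_ordered(self):
        table = pd.DataFrame({"D_overall": [0.2, 0.9, 0.5]}, index=["a", "b", "c"])
        ranked = rank_genes(table)
        assert list(ranked.index) == ["b", "c", "a"]
        assert ranked["rank"].tolist() == [1, 2, 3]

    def test_ties_broken_by_p_sum_then_gene_id(self):
        table = pd.DataFrame(
            {"D_overall": [0.5, 0.5, 0.5], "p_combined_sum": [2.0, 1.0, 1.0]},
            index=["z", "y", "x"],
        )
        ranked = rank_genes(table)
        assert list(ranked.index) == ["x", "y", "z"]

    def test_rank_assignment_is_deterministic(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"D_overall": rng.choice([0.1, 0.5], 50)},
                             index=[f"g{i}" for i in range(50)])
        a = rank_genes(table)
        b = rank_genes(table.sample(frac=1, random_state=1))
        assert list(a.index) == list(b.index)


def _toy_de(genes, expressed, p, fc):
    return pd.DataFrame(
        {
            "expressed": expressed,
            "p_count": p,
            "p_tpm": p,
            "p_combined": p,
            "log2fc_count": fc,
            "log2fc_tpm": fc,
            "log2fc_mean": fc,
        },
        index=pd.Index(genes, name="gene"),
    )


class TestScoreGenes:
    def setup_method(self):
        genes = ["gA", "gB", "gC", "gD"]
        self.de_tables = {
            "ds1": _toy_de(genes, [True, True, True, False],
                           [1e-6, 0.3, 0.02, 1.0], [2.0, 0.05, -1.6, 0.0]),
            "ds2": _toy_de(genes, [True, True, False, False],
                           [1e-4, 0.5, 1.0, 1.0], [1.8, -0.04, 0.0, 0.0]),
        }
        self.mb = pd.Series([True, True, False, True],
                            index=["gA", "gB", "gC", "gD"])

    def test_universe_is_union_of_expressed_genes(self):
        scores = score_genes(self.de_tables, self.mb)
        assert set(scores.index) == {"gA", "gB", "gC"}  # gD expressed nowhere

    def test_concordant_strong_gene_ranks_first(self):
        scores = score_genes(self.de_tables, self.mb)
        assert scores.index[0] == "gA"
        assert scores.loc["gA", "concordance"] == 1.0

    def test_gene_unexpressed_in_one_dataset_gets_floor_there(self):
        scores = score_genes(self.de_tables, self.mb)
        assert scores.loc["gC", "D:ds2"] == 0.01

    def test_d_overall_reproduced_by_direct_formula(self):
        scores = score_genes(self.de_tables, self.mb)
        row = scores.loc["gB"]
        w_c = 0.1 / 0.9 * 2  # two datasets, 10% share
        expected = np.exp(
            (np.log(row["D:ds1"]) + np.log(row["D:ds2"])
             + w_c * np.log(row["concordance_desirability"])) / (2 + w_c)
        )
        assert row["D_overall"] == pytest.approx(expected, rel=1e-12)

    def test_gene_at_floor_everywhere_scores_001(self):
        de = {"ds1": _toy_de(["g1", "g2"], [True, False], [1e-8, 1.0], [3.0, 0.0]),
              "ds2": _toy_de(["g1", "g2"], [True, False], [1e-8, 1.0], [3.0, 0.0])}
        scores = score_genes(de, pd.Series(True, index=["g1", "g2"]),
                             universe=pd.Index(["g1", "g2"]))
        assert scores.loc["g2", "D_overall"] == pytest.approx(0.01, abs=1e-12)

    def test_flipping_a_majority_sign_never_increases_d_overall(self):
        base = score_genes(self.de_tables, self.mb)
        flipped_tables = {k: v.copy() for k, v in self.de_tables.items()}
        flipped_tables["ds2"].loc["gA", "log2fc_mean"] = -1.8  # break concordance
        flipped = score_genes(flipped_tables, self.mb)
        assert flipped.loc["gA", "D_overall"] <= base.loc["gA", "D_overall"] + 1e-15

    def test_rnk_export_round_trips(self, tmp_path):
        scores = score_genes(self.de_tables, self.mb)
        path = tmp_path / "out.rnk"
        ranked = to_rnk(scores, str(path))
        back = pd.read_csv(path, sep="\t", header=None, index_col=0)[1]
        np.testing.assert_allclose(back.to_numpy(), ranked.to_numpy())
        assert list(back.index) == list(scores.sort_values("rank").index)


@given(
    values=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    weights=st.lists(st.floats(0.01, 2.0), min_size=2, max_size=6),
)
@settings(max_examples=100, deadline=None)
def test_weighted_geometric_mean_between_min_and_max(values, weights):
    weights = weights[: len(values)]
    values = values[: len(weights)]
    g = weighted_geometric_mean(values, weights)
    assert min(values) - 1e-12 <= g <= max(values) + 1e-12
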
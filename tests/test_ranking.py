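"""GCH forms, ranking rules, GMR calls, cross-condition tables, concordance."""

import math

import numpy as np
import pandas as pd
import pytest

from gmr.coordination import CoordinationProfile
from gmr.errors import DataError, ValidationError
from gmr.ranking import (
    concordance_report,
    cross_condition_table,
    gch_scores,
    gmr_call,
    rank_genes,
)
from gmr.stability import DatasetSummary


def summary_from_revs(revs: dict[str, float]) -> DatasetSummary:
    table = pd.DataFrame(
        {
            "mean_expression": 1.0,
            "n_probes": 1,
            "dof": 3,
            "rev": pd.Series(revs),
            "res": np.nan,
            "rev_floored": False,
        }
    ).sort_index()
    med = table["rev"].median()
    table["res"] = np.log(med / table["rev"])
    return DatasetSummary("test", 4, 0.05, table)


def profile_from_cps(cps: dict[str, float]) -> CoordinationProfile:
    return CoordinationProfile("test", 4, pd.Series(cps, name="cp"))


class TestGCHScores:
    def test_neutral_gene_scores_one(self):
        summary = summary_from_revs({"A": 0.2, "B": 0.2, "C": 0.2})
        profile = profile_from_cps({"A": 0.0, "B": 0.0, "C": 0.0})
        scores = gch_scores(summary, profile).set_index("gene")
        assert scores.at["A", "gch"] == pytest.approx(1.0)

    def test_maximal_coordination_factor_is_e4(self):
        summary = summary_from_revs({"A": 0.2, "B": 0.2, "C": 0.2})
        profile = profile_from_cps({"A": 1.0, "B": 0.0, "C": 0.0})
        scores = gch_scores(summary, profile).set_index("gene")
        assert scores.at["A", "gch"] == pytest.approx(math.exp(4), rel=1e-9)
        assert scores.at["A", "gch"] == pytest.approx(54.598, abs=5e-4)

    def test_direct_evaluation_approx4(self):
        # REV = median/2, CP = 0.5 -> 2 e^2
        summary = summary_from_revs({"A": 0.1, "B": 0.2, "C": 0.4})
        profile = profile_from_cps({"A": 0.5, "B": 0.0, "C": 0.0})
        scores = gch_scores(summary, profile).set_index("gene")
        assert scores.at["A", "gch"] == pytest.approx(2 * math.e**2, rel=1e-9)

    def test_exact_ratio_form(self):
        summary = summary_from_revs({"A": 0.1, "B": 0.2, "C": 0.4})
        profile = profile_from_cps({"A": 0.5, "B": 0.25, "C": 0.25})
        scores = gch_scores(summary, profile, form="exact_ratio").set_index("gene")
        expected = math.exp(math.log(2.0) + 0.5 / ((0.5 + 0.25 + 0.25) / 3))
        assert scores.at["A", "gch"] == pytest.approx(expected, rel=1e-9)
        assert scores.attrs["form"] == "exact_ratio"

    @pytest.mark.parametrize("form", ["approx4", "exact_ratio"])
    def test_monotone_in_stability_and_coordination(self, form):
        summary = summary_from_revs({"A": 0.1, "B": 0.2, "C": 0.4, "D": 0.4})
        profile = profile_from_cps({"A": 0.2, "B": 0.2, "C": 0.2, "D": 0.5})
        scores = gch_scores(summary, profile, form=form).set_index("gene")
        # lower REV at equal CP -> higher GCH; higher CP at equal REV -> higher
        assert scores.at["A", "gch"] > scores.at["B", "gch"] > scores.at["C", "gch"]
        assert scores.at["D", "gch"] > scores.at["C", "gch"]

    def test_approx4_ranking_equals_res_plus_4cp_ordering(self):
        rng = np.random.default_rng(17)
        genes = [f"G{i}" for i in range(20)]
        summary = summary_from_revs(
            {g: float(rng.uniform(0.05, 0.8)) for g in genes}
        )
        profile = profile_from_cps({g: float(rng.uniform(0, 1)) for g in genes})
        ranked = gch_scores(summary, profile)
        key = summary.table["res"] + 4 * profile.cp
        expected = key.sort_values(ascending=False).index
        assert list(ranked["gene"]) == list(expected)

    def test_universe_mismatch_rejected(self):
        summary = summary_from_revs({"A": 0.1, "B": 0.2})
        profile = profile_from_cps({"A": 0.5})
        with pytest.raises(DataError):
            gch_scores(summary, profile)

    def test_unknown_form_rejected(self):
        summary = summary_from_revs({"A": 0.1, "B": 0.2})
        profile = profile_from_cps({"A": 0.5, "B": 0.1})
        with pytest.raises(ValidationError):
            gch_scores(summary, profile, form="snippet")


class TestRankGenes:
    def test_descending_with_ranks(self):
        table = pd.DataFrame({"gene": ["a", "b", "c"], "gch": [5.0, 9.0, 1.0]})
        ranked = rank_genes(table)
        assert list(ranked["gene"]) == ["b", "a", "c"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_ties_alphabetical(self):
        table = pd.DataFrame({"gene": ["zz", "aa"], "gch": [3.0, 3.0]})
        ranked = rank_genes(table)
        assert list(ranked["gene"]) == ["aa", "zz"]

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(8)], "gch": rng.uniform(1, 9, 8)}
        )
        shuffled = table.sample(frac=1, random_state=4).reset_index(drop=True)
        pd.testing.assert_frame_equal(rank_genes(table), rank_genes(shuffled))


class TestGMRCall:
    def test_actionable_gap(self):
        # hierarchy with a 82.95 / 48.40 gap: clearly actionable at 1.5
        table = rank_genes(
            pd.DataFrame(
                {"gene": ["ALG13", "NUDT18", "OTHER"], "gch": [82.95, 48.40, 10.0]}
            )
        )
        call = gmr_call(table)
        assert call.gmr_gene == "ALG13"
        assert call.gap_ratio == pytest.approx(1.714, abs=1e-3)
        assert call.actionable

    def test_dominant_gmr(self):
        table = rank_genes(
            pd.DataFrame({"gene": ["WFDC3", "RPL31"], "gch": [173.58, 39.11]})
        )
        call = gmr_call(table)
        assert call.gap_ratio == pytest.approx(4.438, abs=1e-3)
        assert call.actionable

    def test_equal_top_two_not_actionable(self):
        table = rank_genes(pd.DataFrame({"gene": ["a", "b"], "gch": [7.0, 7.0]}))
        call = gmr_call(table)
        assert call.gap_ratio == 1.0
        assert not call.actionable

    def test_single_gene_rejected(self):
        with pytest.raises(DataError):
            gmr_call(rank_genes(pd.DataFrame({"gene": ["a"], "gch": [1.0]})))


class TestCrossConditionTable:
    def ranked(self, scores: dict[str, float]):
        return rank_genes(
            pd.DataFrame({"gene": list(scores), "gch": list(scores.values())})
        )

    def test_shape_two_conditions(self):
        tables = {
            "cancer": self.ranked({"A": 9, "B": 8, "C": 7, "D": 1}),
            "normal": self.ranked({"A": 1, "B": 2, "C": 3, "D": 9}),
        }
        matrix = cross_condition_table(tables, top_k=3)
        assert len(matrix) <= 6
        assert {"gch_cancer", "gch_normal"} <= set(matrix.columns)
        # top genes of cancer appear once each
        assert set(matrix["gene"]) == {"A", "B", "C", "D"}

    def test_unquantified_elsewhere_is_na(self):
        tables = {
            "cancer": self.ranked({"A": 9, "B": 8}),
            "normal": self.ranked({"B": 2, "D": 9}),
        }
        matrix = cross_condition_table(tables, top_k=2).set_index("gene")
        assert np.isnan(matrix.at["A", "gch_normal"])
        assert np.isnan(matrix.at["D", "gch_cancer"])
        assert matrix.at["B", "gch_cancer"] == 8

    def test_duplicated_condition_columns_identical(self):
        ranked = self.ranked({"A": 9, "B": 8, "C": 7})
        matrix = cross_condition_table({"x": ranked, "y": ranked.copy()}, top_k=3)
        np.testing.assert_allclose(matrix["gch_x"], matrix["gch_y"])

    def test_single_condition_rejected(self):
        with pytest.raises(DataError):
            cross_condition_table({"only": self.ranked({"A": 1, "B": 2})})


class TestConcordance:
    def test_flags(self):
        table, frac = concordance_report(
            pd.Series({"g1": 10.0, "g2": 2.0}),
            pd.Series({"g1": 2.0, "g2": 10.0}),
            pd.Series({"g1": 0.9, "g2": 0.1}),
            pd.Series({"g1": 0.1, "g2": 0.9}),
        )
        assert table["concordant"].all()
        assert frac == 1.0

    def test_discordant(self):
        _, frac = concordance_report(
            pd.Series({"g1": 10.0}),
            pd.Series({"g1": 2.0}),
            pd.Series({"g1": 0.1}),
            pd.Series({"g1": 0.9}),
        )
        assert frac == 0.0

    def test_crossed_four_gene_design(self):
        # two genes higher in each condition, consequences follow the GCHs
        gch_a = pd.Series({"a1": 30.0, "a2": 25.0, "p1": 3.0, "p2": 4.0})
        gch_b = pd.Series({"a1": 5.0, "a2": 6.0, "p1": 28.0, "p2": 31.0})
        wpr_a = pd.Series({"a1": 9.0, "a2": 7.0, "p1": 0.5, "p2": 0.6})
        wpr_b = pd.Series({"a1": 1.0, "a2": 1.5, "p1": 8.0, "p2": 9.0})
        _, frac = concordance_report(gch_a, gch_b, wpr_a, wpr_b)
        assert frac == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            concordance_report(
                pd.Series({"g1": 1.0}),
                pd.Series({"g1": 1.0, "g2": 2.0}),
                pd.Series({"g1": 1.0}),
                pd.Series({"g1": 1.0}),
            )
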
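import numpy as np
import pytest

from clusterbalance import (
    GeneratorConfig,
    ImportanceRanking,
    alignment_report,
    assign_levels,
    clean,
    generate,
    interview_rank,
    load_concordance_fixture,
    load_interview_fixture,
    load_survey_fixture,
    permutation_importance,
    standardize,
    survey_score,
)
from clusterbalance.alignment import AlignmentError, InterviewMatrix, SurveyCounts
from clusterbalance.evaluation import build_adapter, default_specs

from conftest import make_table


class TestInterviewRank:
    def test_fixture_spot_checks(self):
        df = interview_rank(load_interview_fixture()).set_index("feature")
        assert df.loc["TSH", "frequency"] == 5 and df.loc["TSH", "rank"] == 1
        assert df.loc["on_thyroxine", "frequency"] == 4 and df.loc["on_thyroxine", "rank"] == 2
        assert df.loc["TT4_measured", "frequency"] == 3 and df.loc["TT4_measured", "rank"] == 2
        assert df.loc["query_hyperthyroid", "frequency"] == 2 and df.loc["query_hyperthyroid", "rank"] == 3

    def test_all_zero_row_rank_three(self):
        m = InterviewMatrix(("a", "b"), np.array([[0, 0, 0], [1, 1, 1]]))
        df = interview_rank(m).set_index("feature")
        assert df.loc["a", "frequency"] == 0 and df.loc["a", "rank"] == 3
        assert df.loc["b", "rank"] == 1

    def test_permutation_equivariance(self):
        m = load_interview_fixture()
        perm = np.random.default_rng(0).permutation(len(m.features))
        m2 = InterviewMatrix(tuple(np.array(m.features)[perm]), m.selections[perm])
        df1 = interview_rank(m).set_index("feature")
        df2 = interview_rank(m2).set_index("feature")
        assert df1.loc[df2.index].equals(df2)

    def test_non_binary_entry_rejected(self):
        with pytest.raises(AlignmentError):
            InterviewMatrix(("a",), np.array([[2, 0]]))


class TestSurveyScore:
    def test_fixture_weighted_sums(self):
        ranking = survey_score(load_survey_fixture())
        scores = dict(zip(ranking.features, ranking.scores))
        assert scores["TSH"] == 80  # 3*23 + 2*4 + 1*3
        assert scores["lithium"] == 37  # 3*2 + 2*3 + 1*25
        assert ranking.serials[list(ranking.features).index("TSH")] == 1

    def test_all_low_floor(self):
        c = SurveyCounts(("a",), np.array([0]), np.array([0]), np.array([30]), 30)
        assert survey_score(c).scores[0] == 30

    def test_fixture_rows_sum_to_respondents(self):
        c = load_survey_fixture()
        assert c.respondent_total == 30
        np.testing.assert_array_equal(
            np.asarray(c.high) + np.asarray(c.medium) + np.asarray(c.low),
            np.full(len(c.features), 30),
        )

    def test_inconsistent_totals_warn(self):
        with pytest.warns(UserWarning, match="respondent total"):
            SurveyCounts(("a", "b"), np.array([1, 5]), np.array([1, 5]), np.array([1, 5]), 30)


class TestAssignLevels:
    def test_reference_partition_reproduced(self):
        xai, _ = load_concordance_fixture()
        relevelled = assign_levels(
            ImportanceRanking.from_scores(xai.features, -xai.serials.astype(float))
        )
        assert relevelled.levels == xai.levels

    def test_all_high(self):
        r = ImportanceRanking.from_scores(("a", "b", "c"), [3.0, 2.0, 1.0])
        assert set(assign_levels(r, (3, 0, 0)).levels) == {"High"}

    def test_uniform_scores_follow_feature_order(self):
        r = ImportanceRanking.from_scores(("a", "b", "c"), [1.0, 1.0, 1.0])
        out = assign_levels(r, (1, 1, 1))
        assert out.levels == ("High", "Medium", "Low")

    def test_monotone_in_score(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=12)
        r = assign_levels(
            ImportanceRanking.from_scores([f"f{i}" for i in range(12)], scores), (3, 4, 5)
        )
        level_ord = {"High": 0, "Medium": 1, "Low": 2}
        for i in range(12):
            for j in range(12):
                if scores[i] > scores[j]:
                    assert level_ord[r.levels[i]] <= level_ord[r.levels[j]]

    def test_count_mismatch_errors(self):
        r = ImportanceRanking.from_scores(("a", "b"), [1.0, 2.0])
        with pytest.raises(AlignmentError):
            assign_levels(r, (2, 7, 11))

    def test_gap_method_cuts_at_largest_drops(self):
        r = ImportanceRanking.from_scores(("a", "b", "c", "d"), [10.0, 9.5, 4.0, 0.5])
        out = assign_levels(r, method="gap")
        assert out.levels == ("High", "High", "Medium", "Low")


class TestAlignmentReport:
    def test_reference_concordance(self):
        xai, expert = load_concordance_fixture()
        rep = alignment_report(xai, expert)
        assert rep.match_fraction == pytest.approx(18 / 20)
        assert set(rep.disagreements) == {"I131_treatment", "goitre"}

    def test_identical_rankings(self):
        xai, _ = load_concordance_fixture()
        rep = alignment_report(xai, xai)
        assert rep.match_fraction == 1.0
        assert rep.spearman == pytest.approx(1.0)

    def test_reversed_serials_anticorrelated(self):
        feats = tuple("abcde")
        a = ImportanceRanking.from_scores(feats, [5.0, 4.0, 3.0, 2.0, 1.0])
        b = ImportanceRanking.from_scores(feats, [1.0, 2.0, 3.0, 4.0, 5.0])
        a = assign_levels(a, (1, 2, 2))
        b = assign_levels(b, (1, 2, 2))
        assert alignment_report(a, b).spearman == pytest.approx(-1.0)

    def test_match_fraction_symmetric(self):
        xai, expert = load_concordance_fixture()
        assert alignment_report(xai, expert).match_fraction == alignment_report(
            expert, xai
        ).match_fraction

    def test_feature_set_mismatch_errors(self):
        a = assign_levels(ImportanceRanking.from_scores(("a", "b"), [1.0, 2.0]), (1, 1, 0))
        c = assign_levels(ImportanceRanking.from_scores(("a", "x"), [1.0, 2.0]), (1, 1, 0))
        with pytest.raises(AlignmentError):
            alignment_report(a, c)


class TestPermutationImportance:
    def test_planted_single_signal_ranked_first(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(400, 4))
        y = (X[:, 1] > 0).astype(int)
        table = make_table(X, y)
        ad = build_adapter(default_specs()["DT"]).fit(table.X, table.y)
        ranking = permutation_importance(ad, table, repeats=5, seed=7)
        assert ranking.serials[1] == 1

    def test_pure_noise_feature_near_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 3))
        y = (X[:, 0] > 0).astype(int)
        table = make_table(X, y)
        ad = build_adapter(default_specs()["DT"]).fit(table.X, table.y)
        ranking = permutation_importance(ad, table, repeats=10, seed=8)
        assert abs(ranking.scores[2]) < 0.05

    def test_more_repeats_reduce_variance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 3))
        y = ((X[:, 0] + 0.5 * rng.normal(size=300)) > 0).astype(int)
        table = make_table(X, y)
        ad = build_adapter(default_specs()["DT"]).fit(table.X, table.y)

        def spread(repeats):
            vals = [
                permutation_importance(ad, table, repeats=repeats, seed=s).scores[0]
                for s in range(6)
            ]
            return np.std(vals)

        assert spread(16) <= spread(2) + 1e-9
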
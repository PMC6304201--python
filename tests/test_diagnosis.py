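"""Diagnosis ranking and the scikit-learn estimator surface."""

import numpy as np
import pytest
from sklearn.base import clone

from neutrosim import (
    NeutrosophicClassifier,
    Pooling,
    Profile,
    RelationTable,
    SVNSElement,
    rank_diagnoses,
    score_matrix,
)
from neutrosim.registry import MEASURE_IDS, list_measures


class TestRankDiagnoses:
    @pytest.mark.parametrize("measure", sorted(MEASURE_IDS))
    def test_p1_is_malaria_under_every_svns_measure(self, p1, table1, measure):
        report = rank_diagnoses(p1, table1, measure, convention=Pooling.PER_ITEM)
        assert report.winners == ("Q2",)
        assert not report.ties

    @pytest.mark.parametrize("measure", ["s1", "s2", "s1_star", "s2_star"])
    def test_p2_is_typhoid_under_the_core_ivns_measures(self, p2, table3, measure):
        report = rank_diagnoses(p2, table3, measure, convention=Pooling.PER_ITEM)
        assert report.winners == ("Q3",)

    def test_single_row_table_always_wins(self, p1, table1):
        single = RelationTable(("Q1",), table1.criteria, (table1.cells[0],))
        for measure in MEASURE_IDS:
            assert rank_diagnoses(p1, single, measure).winner == "Q1"

    def test_sm_and_sd_produce_identical_rankings(self, p1, table1):
        # both are monotone decreasing in the same distance
        for convention in Pooling.ALL:
            r_sm = rank_diagnoses(p1, table1, "sm", convention=convention)
            r_sd = rank_diagnoses(p1, table1, "sd", convention=convention)
            assert r_sm.ranking == r_sd.ranking

    def test_row_permutation_permutes_report(self, p1, table1):
        perm = ("Q3", "Q1", "Q5", "Q2", "Q4")
        idx = [table1.diagnoses.index(d) for d in perm]
        shuffled = RelationTable(perm, table1.criteria, tuple(table1.cells[k] for k in idx))
        base = rank_diagnoses(p1, table1, "s2_star")
        moved = rank_diagnoses(p1, shuffled, "s2_star")
        assert dict(base.scores) == dict(moved.scores)
        assert base.ranking == moved.ranking
        assert base.winner == moved.winner

    def test_tie_reports_all_cowinners_in_table_order(self, table1):
        # a patient equal to row Q1 duplicated under two labels ties exactly
        dup = RelationTable(
            ("A", "B", "C"),
            table1.criteria,
            (table1.cells[0], table1.cells[3], table1.cells[0]),
        )
        patient = table1.row("Q1")
        report = rank_diagnoses(patient, dup, "s1_star")
        assert report.ties
        assert report.winners == ("A", "C")
        assert report.ranking[:2] == ("A", "C")

    def test_low_confidence_flag_never_alters_winner(self, p1, table1):
        strict = rank_diagnoses(p1, table1, "s1_star", min_similarity=0.99)
        loose = rank_diagnoses(p1, table1, "s1_star", min_similarity=0.1)
        assert strict.low_confidence and not loose.low_confidence
        assert strict.winner == loose.winner

    def test_mismatches_fail_fast(self, p1, p2, table1, table3):
        with pytest.raises(ValueError, match="kind"):
            rank_diagnoses(p2, table1, "s1_star")
        with pytest.raises(ValueError, match="unknown measure"):
            rank_diagnoses(p1, table1, "sx")
        renamed = Profile.from_triples(
            [el.as_array() for el in p1.elements], names=["a", "b", "c", "d", "e"]
        )
        with pytest.raises(ValueError, match="criteria"):
            rank_diagnoses(renamed, table1, "s1_star")

    def test_report_serialization(self, p1, table1):
        report = rank_diagnoses(p1, table1, "s2_star")
        doc = report.to_dict()
        assert set(doc["scores"]) == set(table1.diagnoses)
        assert doc["winners"] == ["Q2"]
        assert "Q2" in report.to_text()


class TestScoreMatrix:
    def test_full_svns_grid_matches_reports(self, p1, table1):
        measures = [m.id for m in list_measures("svns")]
        grid = score_matrix([p1], table1, measures)
        assert grid.shape == (9, 5)
        for measure in measures:
            expected = dict(rank_diagnoses(p1, table1, measure).scores)
            row = grid.loc[("P1", measure)]
            assert {d: row[d] for d in table1.diagnoses} == expected

    def test_empty_measure_list_gives_empty_grid(self, p1, table1):
        assert score_matrix([p1], table1, []).empty

    def test_selected_ivns_grid_column(self, p2, table3):
        grid = score_matrix([p2], table3, ["sc1", "sc2"])
        q3 = grid["Q3"].round(4).tolist()
        assert q3 == [0.7915, 0.9086]


class TestEstimator:
    def test_fit_relation_table_predict_profiles(self, p1, table1):
        clf = NeutrosophicClassifier(measure="s1_star").fit(table1)
        assert list(clf.classes_) == list(table1.diagnoses)
        assert clf.predict([p1])[0] == "Q2"

    def test_fit_array_predict_array(self, p1, table1):
        X = np.array([table1.row(d).as_array().ravel() for d in table1.diagnoses])
        clf = NeutrosophicClassifier(measure="s2_star", kind="svns")
        clf.fit(X, list(table1.diagnoses))
        pred = clf.predict(p1.as_array().ravel()[None, :])
        assert pred[0] == "Q2"

    def test_decision_function_matches_report_scores(self, p2, table3):
        clf = NeutrosophicClassifier(measure="s2_star", kind="ivns").fit(table3)
        scores = clf.decision_function([p2])[0]
        expected = [s for _, s in clf.report(p2).scores]
        assert scores.tolist() == expected

    def test_sklearn_protocol(self, table1, p1):
        clf = NeutrosophicClassifier(measure="sy", sc_variant="sc2")
        params = clf.get_params()
        assert params["measure"] == "sy"
        cloned = clone(clf)
        assert cloned.get_params() == params
        cloned.set_params(measure="sm").fit(table1)
        assert cloned.predict([p1])[0] == "Q2"

    def test_unfitted_predict_raises(self, p1):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            NeutrosophicClassifier().predict([p1])

    def test_bad_array_shapes_rejected(self):
        clf = NeutrosophicClassifier(kind="svns")
        with pytest.raises(ValueError, match="multiple of 3"):
            clf.fit(np.zeros((2, 7)), ["a", "b"])
        with pytest.raises(ValueError, match="y"):
            clf.fit(np.zeros((2, 6)))
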
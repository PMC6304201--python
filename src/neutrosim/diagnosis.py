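"""Similarity-ranking diagnosis: nearest-prototype classification.

Each candidate diagnosis is a prototype profile (one row of a
:class:`~neutrosim.core.RelationTable`); a patient is assigned the
diagnosis whose row maximizes the chosen similarity measure — an argmax
rule over the score vector.  The estimator below follows the
scikit-learn protocol (``fit``/``predict``/``decision_function``) so it
composes with pipelines and model selection; :func:`rank_diagnoses` and
:func:`score_matrix` are the plain-function surface over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .core import IVNSElement, Pooling, Profile, RelationTable, SVNSElement
from .registry import evaluate, get_measure

__all__ = ["NeutrosophicClassifier", "DiagnosisReport", "rank_diagnoses", "score_matrix"]


@dataclass(frozen=True)
class DiagnosisReport:
    """Per-diagnosis similarity scores, ranking and argmax for one patient.

    ``ranking`` sorts labels by descending score, keeping table row order
    among exact ties; ``winners`` lists every label attaining the maximum
    (``ties`` is set when there is more than one).
    """

    measure: str
    convention: str
    scores: tuple  # of (diagnosis label, similarity) in table row order
    ranking: tuple
    winners: tuple
    ties: bool
    low_confidence: bool = field(default=False)

    @property
    def winner(self) -> str:
        return self.winners[0]

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "convention": self.convention,
            "scores": {label: score for label, score in self.scores},
            "ranking": list(self.ranking),
            "winners": list(self.winners),
            "ties": self.ties,
            "low_confidence": self.low_confidence,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = [f"measure={self.measure} convention={self.convention}"]
        width = max(len(label) for label, _ in self.scores)
        for rank, label in enumerate(self.ranking, start=1):
            score = dict(self.scores)[label]
            mark = " <- winner" if label in self.winners else ""
            lines.append(f"  {rank}. {label:<{width}}  {score:.6f}{mark}")
        if self.ties:
            lines.append("  note: tie among " + ", ".join(self.winners))
        if self.low_confidence:
            lines.append("  note: best similarity below the warning threshold")
        return "\n".join(lines)


def _rank(scores: list, labels: tuple) -> tuple:
    order = sorted(range(len(labels)), key=lambda k: -scores[k])  # stable among ties
    ranking = tuple(labels[k] for k in order)
    best = max(scores)
    winners = tuple(label for label, s in zip(labels, scores) if s == best)
    return ranking, winners


def rank_diagnoses(
    patient: Profile,
    table: RelationTable,
    measure: str = "s1_star",
    convention: str = Pooling.PER_ITEM,
    sc_variant: str = "sc1",
    min_similarity: float | None = None,
) -> DiagnosisReport:
    """Score a patient against every diagnosis row and rank by similarity.

    ``min_similarity`` is an optional warning threshold: when even the best
    score falls below it the report's ``low_confidence`` flag is set.  It
    never changes the ranking or the winner.
    """
    if patient.kind != table.kind:
        raise ValueError(f"patient kind {patient.kind} != table kind {table.kind}")
    if patient.criteria != table.criteria:
        raise ValueError(
            f"criteria differ: patient {patient.criteria} vs table {table.criteria}"
        )
    get_measure(measure, table.kind)  # fail fast on unknown ids
    labels = table.diagnoses
    scores = [
        evaluate(measure, patient, row, convention=convention, sc_variant=sc_variant)
        for _, row in table.rows()
    ]
    ranking, winners = _rank(scores, labels)
    return DiagnosisReport(
        measure=measure,
        convention=convention,
        scores=tuple(zip(labels, scores)),
        ranking=ranking,
        winners=winners,
        ties=len(winners) > 1,
        low_confidence=min_similarity is not None and max(scores) < min_similarity,
    )


def score_matrix(
    patients: list,
    table: RelationTable,
    measures: list,
    convention: str = Pooling.PER_ITEM,
    sc_variant: str = "sc1",
    patient_labels: list | None = None,
) -> pd.DataFrame:
    """Full measures x diagnoses similarity grid for each patient.

    Returns a DataFrame indexed by (patient, measure) with one column per
    diagnosis, in table order.  An empty measure list yields an empty grid.
    """
    if patient_labels is None:
        patient_labels = [f"P{k + 1}" for k in range(len(patients))]
    rows = {}
    for plabel, patient in zip(patient_labels, patients):
        for measure in measures:
            report = rank_diagnoses(
                patient, table, measure, convention=convention, sc_variant=sc_variant
            )
            rows[(plabel, measure)] = dict(report.scores)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(table.diagnoses))
    if rows:
        frame.index = pd.MultiIndex.from_tuples(frame.index, names=["patient", "measure"])
    return frame


def _profile_from_row(row: np.ndarray, kind: str, criteria: tuple) -> Profile:
    width = 3 if kind == "svns" else 6
    parts = row.reshape(-1, width)
    if kind == "svns":
        elements = [SVNSElement(*p) for p in parts]
    else:
        elements = [IVNSElement(*p) for p in parts]
    return Profile(tuple(zip(criteria, elements)))


class NeutrosophicClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-prototype classifier under a neutrosophic similarity measure.

    ``fit`` accepts either a :class:`RelationTable` (labels taken from its
    diagnosis rows; ``y`` may be omitted) or a numeric matrix whose rows are
    flattened profiles — ``(T, I, F)`` per criterion for ``kind='svns'``
    (3n columns) or the six interval bounds per criterion for
    ``kind='ivns'`` (6n columns) — with ``y`` the prototype labels.
    ``predict`` assigns each sample the label of its most similar
    prototype; exact ties resolve to the earliest fitted prototype.

    Parameters
    ----------
    measure : str
        Registry id of the similarity measure (default the min/max +
        distance hybrid ``"s1_star"``).
    kind : str
        ``"svns"`` or ``"ivns"``; ignored when fitting a RelationTable,
        which carries its own kind.
    convention : str
        Pooling convention for the distance/ratio aggregation
        (``"per_item"`` default).
    sc_variant : str
        Improved-cosine variant feeding the ``"sy"`` measure.
    """

    def __init__(
        self,
        measure: str = "s1_star",
        kind: str = "svns",
        convention: str = Pooling.PER_ITEM,
        sc_variant: str = "sc1",
    ):
        self.measure = measure
        self.kind = kind
        self.convention = convention
        self.sc_variant = sc_variant

    def fit(self, X, y=None):
        if isinstance(X, RelationTable):
            table = X
            if y is not None and list(y) != list(table.diagnoses):
                raise ValueError("y must be None or equal the table's diagnosis labels")
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            width = 3 if self.kind == "svns" else 6
            if X.shape[1] % width:
                raise ValueError(
                    f"{self.kind} rows need a multiple of {width} columns, got {X.shape[1]}"
                )
            if y is None:
                raise ValueError("y (prototype labels) is required with array input")
            y = np.asarray(y)
            if len(y) != X.shape[0]:
                raise ValueError("X and y length mismatch")
            if len(set(map(str, y))) != len(y):
                raise ValueError("prototype labels must be unique")
            n = X.shape[1] // width
            criteria = tuple(f"x{k + 1}" for k in range(n))
            profiles = [_profile_from_row(row, self.kind, criteria) for row in X]
            table = RelationTable(
                diagnoses=tuple(str(label) for label in y),
                criteria=criteria,
                cells=tuple(tuple(p.elements) for p in profiles),
            )
        get_measure(self.measure, table.kind)
        self.table_ = table
        self.kind_ = table.kind
        self.classes_ = np.asarray(table.diagnoses)
        self.n_features_in_ = len(table.criteria) * (3 if table.kind == "svns" else 6)
        return self

    def _as_profiles(self, X) -> list:
        if isinstance(X, Profile):
            X = [X]
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], Profile):
            for p in X:
                if p.kind != self.kind_ or p.criteria != self.table_.criteria:
                    raise ValueError("profile kind/criteria do not match the fitted table")
            return list(X)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return [
            _profile_from_row(row, self.kind_, self.table_.criteria) for row in X
        ]

    def decision_function(self, X) -> np.ndarray:
        """Similarity of each sample to each fitted prototype, shape
        (n_samples, n_prototypes) in prototype order."""
        check_is_fitted(self, "table_")
        profiles = self._as_profiles(X)
        return np.array(
            [
                [
                    evaluate(
                        self.measure,
                        p,
                        row,
                        convention=self.convention,
                        sc_variant=self.sc_variant,
                    )
                    for _, row in self.table_.rows()
                ]
                for p in profiles
            ]
        )

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[scores.argmax(axis=1)]

    def report(self, patient: Profile, min_similarity: float | None = None) -> DiagnosisReport:
        """Full ranking report for a single patient profile."""
        check_is_fitted(self, "table_")
        return rank_diagnoses(
            patient,
            self.table_,
            self.measure,
            convention=self.convention,
            sc_variant=self.sc_variant,
            min_similarity=min_similarity,
        )
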
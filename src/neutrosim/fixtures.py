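"""Bundled worked-example data.

The classic five-diagnosis / five-symptom medical-diagnosis benchmark:
diagnoses Q1 (viral fever), Q2 (malaria), Q3 (typhoid), Q4 (gastritis),
Q5 (stenocardia) evaluated against symptoms S1 (fever), S2 (headache),
S3 (stomach pain), S4 (cough), S5 (chest pain), plus two patients — P1
with single-valued evaluations and P2 with interval-valued ones — and
the two single-element proportional pairs that defeat the plain cosine
measures.  ``load_fixture`` returns freshly built (hence immutable-by-
construction) objects.
"""

from __future__ import annotations

from .core import IVNSElement, Profile, RelationTable, SVNSElement, to_ivns

__all__ = ["load_fixture", "FIXTURE_NAMES", "DIAGNOSIS_MEANINGS", "SYMPTOM_MEANINGS"]

DIAGNOSIS_MEANINGS = {
    "Q1": "viral fever",
    "Q2": "malaria",
    "Q3": "typhoid",
    "Q4": "gastritis",
    "Q5": "stenocardia",
}
SYMPTOM_MEANINGS = {
    "S1": "fever",
    "S2": "headache",
    "S3": "stomach pain",
    "S4": "cough",
    "S5": "chest pain",
}

_SYMPTOMS = ("S1", "S2", "S3", "S4", "S5")
_DIAGNOSES = ("Q1", "Q2", "Q3", "Q4", "Q5")

# diagnosis x symptom (T, I, F) triples of the SVNS knowledge base
_TABLE1 = {
    "Q1": [(0.4, 0.6, 0.0), (0.3, 0.2, 0.5), (0.1, 0.3, 0.7), (0.4, 0.3, 0.3), (0.1, 0.2, 0.7)],
    "Q2": [(0.7, 0.3, 0.0), (0.2, 0.2, 0.6), (0.0, 0.1, 0.9), (0.7, 0.3, 0.0), (0.1, 0.1, 0.8)],
    "Q3": [(0.3, 0.4, 0.3), (0.6, 0.3, 0.1), (0.2, 0.1, 0.7), (0.2, 0.2, 0.6), (0.1, 0.0, 0.9)],
    "Q4": [(0.1, 0.2, 0.7), (0.2, 0.4, 0.4), (0.8, 0.2, 0.0), (0.2, 0.1, 0.7), (0.2, 0.1, 0.7)],
    "Q5": [(0.1, 0.1, 0.8), (0.0, 0.2, 0.8), (0.2, 0.0, 0.8), (0.2, 0.0, 0.8), (0.8, 0.1, 0.1)],
}

_P1 = [(0.8, 0.2, 0.1), (0.6, 0.3, 0.1), (0.2, 0.1, 0.8), (0.6, 0.5, 0.1), (0.1, 0.4, 0.6)]

# patient P2: ([T_L,T_U],[I_L,I_U],[F_L,F_U]) per symptom, flattened
_P2 = [
    (0.3, 0.5, 0.2, 0.3, 0.4, 0.5),
    (0.7, 0.9, 0.1, 0.2, 0.1, 0.2),
    (0.4, 0.6, 0.2, 0.3, 0.3, 0.4),
    (0.3, 0.6, 0.1, 0.3, 0.4, 0.7),
    (0.5, 0.8, 0.1, 0.4, 0.1, 0.3),
]

_EXAMPLE1 = ((0.4, 0.2, 0.6), (0.2, 0.1, 0.3))
_EXAMPLE2 = (
    (0.3, 0.4, 0.2, 0.3, 0.4, 0.5),
    (0.6, 0.8, 0.4, 0.6, 0.8, 1.0),
)

FIXTURE_NAMES = ("table1", "table3", "p1", "p2", "example1_pair", "example2_pair")


def _table1() -> RelationTable:
    return RelationTable(
        diagnoses=_DIAGNOSES,
        criteria=_SYMPTOMS,
        cells=tuple(
            tuple(SVNSElement(*cell) for cell in _TABLE1[d]) for d in _DIAGNOSES
        ),
    )


def _table3() -> RelationTable:
    # the same knowledge base lifted to degenerate intervals
    svns = _table1()
    return RelationTable(
        diagnoses=svns.diagnoses,
        criteria=svns.criteria,
        cells=tuple(
            tuple(to_ivns(profile).elements) for _, profile in svns.rows()
        ),
    )


def load_fixture(name: str):
    """Return a bundled profile, table or profile pair by name.

    Names: ``table1`` (SVNS knowledge base), ``table3`` (its degenerate
    interval lift), ``p1``/``p2`` (patients), ``example1_pair`` /
    ``example2_pair`` (cosine counterexample pairs).
    """
    if name == "table1":
        return _table1()
    if name == "table3":
        return _table3()
    if name == "p1":
        return Profile.from_triples(_P1, _SYMPTOMS)
    if name == "p2":
        return Profile.from_intervals(_P2, _SYMPTOMS)
    if name == "example1_pair":
        return (
            Profile((("x", SVNSElement(*_EXAMPLE1[0])),)),
            Profile((("x", SVNSElement(*_EXAMPLE1[1])),)),
        )
    if name == "example2_pair":
        return (
            Profile((("x", IVNSElement(*_EXAMPLE2[0])),)),
            Profile((("x", IVNSElement(*_EXAMPLE2[1])),)),
        )
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
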
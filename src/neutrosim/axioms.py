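"""Axiom verification for similarity measures.

A *genuine* similarity measure S must satisfy three axioms:

1. range: ``0 <= S(a, b) <= 1``;
2. identity: ``S(a, b) = 1`` if and only if ``a = b``;
3. symmetry: ``S(a, b) = S(b, a)``.

:func:`check_axioms` samples seeded random profile pairs and records every
violation with a replayable witness.  The "only if" half of axiom 2
(*genuineness*) is the interesting one: the plain cosine measures violate
it on proportional unequal vectors, and
:func:`collinear_counterexample` constructs such a pair directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import IVNSElement, Profile, SVNSElement, profiles_equal, random_profile
from .registry import evaluate, get_measure

__all__ = ["AxiomReport", "check_axioms", "collinear_counterexample"]

#: |S - 1| below this counts as "scores 1" in the genuineness check;
#: cosine of exactly proportional vectors is 1 only up to double rounding.
ONE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class Violation:
    axiom: str  # range | identity | symmetry | genuineness
    witness: tuple  # (profile a, profile b)
    observed: float

    def to_dict(self) -> dict:
        return {
            "axiom": self.axiom,
            "witness": [
                [el.as_array().tolist() for el in p.elements] for p in self.witness
            ],
            "observed": self.observed,
        }


@dataclass(frozen=True)
class AxiomReport:
    measure: str
    kind: str
    samples: int
    seed: int
    violations: tuple

    @property
    def passed(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "kind": self.kind,
            "samples": self.samples,
            "seed": self.seed,
            "passed": self.passed,
            "violations": [v.to_dict() for v in self.violations],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def check_axioms(
    measure: str,
    kind: str = "svns",
    n_criteria: int = 5,
    samples: int = 1000,
    seed: int = 0,
    check_genuineness: bool = True,
) -> AxiomReport:
    """Sample random profile pairs and test the similarity axioms.

    Per sample: range and symmetry on an independent pair, identity on a
    profile against itself, and (optionally) genuineness — a pair scoring
    within ``ONE_TOLERANCE`` of 1 while unequal is a violation.  For the
    cosine measures a proportional pair from
    :func:`collinear_counterexample` is injected once so the known
    pathology is exhibited rather than left to luck.
    """
    if samples < 1:
        raise ValueError("samples must be >= 1")
    info = get_measure(measure, kind)
    rng = np.random.default_rng(seed)
    violations = []

    pairs = [
        (
            random_profile(kind, n_criteria, int(rng.integers(2**31))),
            random_profile(kind, n_criteria, int(rng.integers(2**31))),
        )
        for _ in range(samples)
    ]
    if check_genuineness and not info.genuine:
        # deterministic witness for the collinearity pathology
        pairs[0] = collinear_counterexample(kind, seed)

    for a, b in pairs:
        s_ab = evaluate(measure, a, b)
        s_ba = evaluate(measure, b, a)
        if not 0.0 <= s_ab <= 1.0:
            violations.append(Violation("range", (a, b), s_ab))
        if abs(s_ab - s_ba) > 1e-12:
            violations.append(Violation("symmetry", (a, b), s_ab - s_ba))
        s_aa = evaluate(measure, a, a)
        if abs(s_aa - 1.0) > 1e-12:
            violations.append(Violation("identity", (a, a), s_aa))
        if check_genuineness and abs(s_ab - 1.0) <= ONE_TOLERANCE:
            if not profiles_equal(a, b):
                violations.append(Violation("genuineness", (a, b), s_ab))

    return AxiomReport(
        measure=measure, kind=kind, samples=samples, seed=seed, violations=tuple(violations)
    )


def collinear_counterexample(kind: str = "svns", seed: int = 0) -> tuple:
    """Construct unequal single-criterion profiles with proportional
    membership vectors, on which the plain cosine measures score exactly 1.

    The base vector is drawn away from zero and scaled by k in [0.4, 0.8]
    so both profiles stay inside [0, 1] and are clearly unequal; a single
    criterion suffices because the pathology is per element.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.3, 1.0, size=3)
    k = rng.uniform(0.4, 0.8)
    scaled = k * base
    if kind == "svns":
        a = Profile((("x1", SVNSElement(*base)),))
        b = Profile((("x1", SVNSElement(*scaled)),))
    elif kind == "ivns":
        # degenerate-free intervals: [v/2, v] keeps lo <= hi and scales uniformly
        a = Profile(
            (("x1", IVNSElement(base[0] / 2, base[0], base[1] / 2, base[1], base[2] / 2, base[2])),)
        )
        b = Profile(
            (
                (
                    "x1",
                    IVNSElement(
                        scaled[0] / 2, scaled[0], scaled[1] / 2, scaled[1], scaled[2] / 2, scaled[2]
                    ),
                ),
            )
        )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return a, b
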
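"""Core domain types for neutrosophic sets.

A neutrosophic evaluation attaches three independent membership degrees to
each element of a universe: truth (T), indeterminacy (I) and falsity (F).
Unlike intuitionistic fuzzy memberships the three degrees are not required
to sum to one; only ``T + I + F <= 3`` is imposed.  Two flavours are
supported:

* **SVNS** (single-valued): T, I, F are single reals in [0, 1].
* **IVNS** (interval-valued): each membership is a closed subinterval of
  [0, 1]; an IVNS whose intervals are all degenerate (lo == hi) reduces to
  an SVNS.

A :class:`Profile` is an ordered, named-criteria vector of such elements
(one patient, or one row of a diagnosis knowledge base); a
:class:`RelationTable` is a diagnoses-by-criteria matrix of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "SVNSElement",
    "IVNSElement",
    "Profile",
    "RelationTable",
    "Pooling",
    "validate_element",
    "contains",
    "profiles_equal",
    "to_svns",
    "to_ivns",
    "random_profile",
]

logger = logging.getLogger("neutrosim")


class Pooling:
    """Aggregation convention for multi-criterion distances and ratios.

    ``POOLED`` folds all criteria into one global formula (a single square
    root, or one grand min/max ratio); ``PER_ITEM`` evaluates the formula
    per criterion and averages the n per-criterion values.  The two
    coincide for n = 1 but differ in general.
    """

    POOLED = "pooled"
    PER_ITEM = "per_item"
    ALL = (POOLED, PER_ITEM)

    @staticmethod
    def check(value: str) -> str:
        if value not in Pooling.ALL:
            raise ValueError(
                f"unknown pooling convention {value!r}; expected one of {Pooling.ALL}"
            )
        return value


def _check_unit(value: float, name: str, clamp: bool) -> float:
    value = float(value)
    if np.isnan(value):
        raise ValueError(f"membership component {name} is NaN")
    if not 0.0 <= value <= 1.0:
        if clamp:
            clipped = min(1.0, max(0.0, value))
            logger.warning("clamped %s from %g to %g", name, value, clipped)
            return clipped
        raise ValueError(f"membership component {name}={value} outside [0, 1]")
    return value


@dataclass(frozen=True)
class SVNSElement:
    """One criterion's (truth, indeterminacy, falsity) triple."""

    t: float
    i: float
    f: float

    def __post_init__(self) -> None:
        for name in ("t", "i", "f"):
            object.__setattr__(self, name, _check_unit(getattr(self, name), name, False))
        total = self.t + self.i + self.f
        if total > 3.0:
            raise ValueError(f"component sum t+i+f={total} exceeds 3")

    @classmethod
    def clamped(cls, t: float, i: float, f: float) -> "SVNSElement":
        """Build an element, clipping out-of-range components into [0, 1]."""
        return cls(
            _check_unit(t, "t", True), _check_unit(i, "i", True), _check_unit(f, "f", True)
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.t, self.i, self.f])


@dataclass(frozen=True)
class IVNSElement:
    """One criterion's three closed membership subintervals of [0, 1]."""

    t_lo: float
    t_hi: float
    i_lo: float
    i_hi: float
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        for name in ("t_lo", "t_hi", "i_lo", "i_hi", "f_lo", "f_hi"):
            object.__setattr__(self, name, _check_unit(getattr(self, name), name, False))
        for lo, hi in (("t_lo", "t_hi"), ("i_lo", "i_hi"), ("f_lo", "f_hi")):
            if getattr(self, lo) > getattr(self, hi):
                raise ValueError(
                    f"interval [{lo}, {hi}] = [{getattr(self, lo)}, {getattr(self, hi)}]"
                    " has lo > hi"
                )
        total = self.t_hi + self.i_hi + self.f_hi
        if total > 3.0:
            raise ValueError(f"upper-bound sum {total} exceeds 3")

    @classmethod
    def clamped(
        cls, t_lo: float, t_hi: float, i_lo: float, i_hi: float, f_lo: float, f_hi: float
    ) -> "IVNSElement":
        """Build an element, clipping bounds into [0, 1] and sorting endpoints."""
        vals = [
            _check_unit(v, n, True)
            for v, n in zip(
                (t_lo, t_hi, i_lo, i_hi, f_lo, f_hi),
                ("t_lo", "t_hi", "i_lo", "i_hi", "f_lo", "f_hi"),
            )
        ]
        for k in (0, 2, 4):
            if vals[k] > vals[k + 1]:
                logger.warning("sorted interval endpoints (%g, %g)", vals[k], vals[k + 1])
                vals[k], vals[k + 1] = vals[k + 1], vals[k]
        return cls(*vals)

    @property
    def degenerate(self) -> bool:
        return self.t_lo == self.t_hi and self.i_lo == self.i_hi and self.f_lo == self.f_hi

    def as_array(self) -> np.ndarray:
        return np.array([self.t_lo, self.t_hi, self.i_lo, self.i_hi, self.f_lo, self.f_hi])


Element = Union[SVNSElement, IVNSElement]


def validate_element(element: Element) -> Element:
    """Return ``element`` unchanged iff it satisfies all invariants.

    Construction already validates, so this only type-checks and re-asserts;
    it exists as the single entry point for validating externally built data.
    """
    if isinstance(element, SVNSElement):
        return SVNSElement(element.t, element.i, element.f)
    if isinstance(element, IVNSElement):
        return IVNSElement(
            element.t_lo, element.t_hi, element.i_lo, element.i_hi, element.f_lo, element.f_hi
        )
    raise TypeError(f"not a neutrosophic element: {type(element).__name__}")


@dataclass(frozen=True)
class Profile:
    """An ordered, named-criteria vector of neutrosophic elements."""

    entries: tuple  # of (criterion_name, element)

    def __post_init__(self) -> None:
        entries = tuple((str(name), validate_element(el)) for name, el in self.entries)
        if not entries:
            raise ValueError("a profile needs at least one criterion")
        names = [name for name, _ in entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate criterion names in {names}")
        kinds = {type(el) for _, el in entries}
        if len(kinds) != 1:
            raise ValueError("mixed SVNS/IVNS elements in one profile")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def from_triples(
        cls, triples: Iterable[Sequence[float]], names: Sequence[str] | None = None
    ) -> "Profile":
        triples = list(triples)
        if names is None:
            names = [f"S{k + 1}" for k in range(len(triples))]
        return cls(tuple((n, SVNSElement(*tr)) for n, tr in zip(names, triples)))

    @classmethod
    def from_intervals(
        cls, sextuples: Iterable[Sequence[float]], names: Sequence[str] | None = None
    ) -> "Profile":
        sextuples = list(sextuples)
        if names is None:
            names = [f"S{k + 1}" for k in range(len(sextuples))]
        return cls(tuple((n, IVNSElement(*sx)) for n, sx in zip(names, sextuples)))

    @property
    def kind(self) -> str:
        return "svns" if isinstance(self.entries[0][1], SVNSElement) else "ivns"

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def criteria(self) -> tuple:
        return tuple(name for name, _ in self.entries)

    @property
    def elements(self) -> tuple:
        return tuple(el for _, el in self.entries)

    def as_array(self) -> np.ndarray:
        """(n, 3) for SVNS, (n, 6) ordered T_L,T_U,I_L,I_U,F_L,F_U for IVNS."""
        return np.array([el.as_array() for _, el in self.entries])


def _check_conformable(a: Profile, b: Profile) -> None:
    if a.kind != b.kind:
        raise ValueError(f"profile kinds differ: {a.kind} vs {b.kind}")
    if a.criteria != b.criteria:
        raise ValueError(
            f"criterion names/order differ: {a.criteria} vs {b.criteria}"
        )


def contains(a: Profile, b: Profile) -> bool:
    """Neutrosophic containment a ⊆ b: at every criterion T is no larger
    while I and F are no smaller (all six bounds, for intervals)."""
    _check_conformable(a, b)
    for (_, ea), (_, eb) in zip(a.entries, b.entries):
        if isinstance(ea, SVNSElement):
            if not (ea.t <= eb.t and ea.i >= eb.i and ea.f >= eb.f):
                return False
        else:
            if not (
                ea.t_lo <= eb.t_lo
                and ea.t_hi <= eb.t_hi
                and ea.i_lo >= eb.i_lo
                and ea.i_hi >= eb.i_hi
                and ea.f_lo >= eb.f_lo
                and ea.f_hi >= eb.f_hi
            ):
                return False
    return True


def profiles_equal(a: Profile, b: Profile) -> bool:
    """Set equality: mutual containment, i.e. componentwise equality."""
    return contains(a, b) and contains(b, a)


def to_svns(profile: Profile) -> Profile:
    """Reduce a degenerate IVNS profile (all intervals lo == hi) to SVNS."""
    if profile.kind != "ivns":
        raise ValueError("to_svns expects an IVNS profile")
    entries = []
    for name, el in profile.entries:
        if not el.degenerate:
            raise ValueError(f"criterion {name!r} has a non-degenerate interval")
        entries.append((name, SVNSElement(el.t_lo, el.i_lo, el.f_lo)))
    return Profile(tuple(entries))


def to_ivns(profile: Profile) -> Profile:
    """Lift an SVNS profile to the degenerate-interval IVNS that reduces back."""
    if profile.kind != "svns":
        raise ValueError("to_ivns expects an SVNS profile")
    return Profile(
        tuple(
            (name, IVNSElement(el.t, el.t, el.i, el.i, el.f, el.f))
            for name, el in profile.entries
        )
    )


def random_profile(kind: str, n: int, seed: int) -> Profile:
    """Draw a valid random profile, reproducibly.

    Components are uniform on [0, 1]; interval endpoints are sorted so every
    draw satisfies the element invariants by construction.  (The T+I+F <= 3
    bound holds automatically for unit-interval components.)
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"x{k + 1}" for k in range(n)]
    if kind == "svns":
        vals = rng.uniform(size=(n, 3))
        return Profile(tuple((nm, SVNSElement(*row)) for nm, row in zip(names, vals)))
    if kind == "ivns":
        vals = np.sort(rng.uniform(size=(n, 3, 2)), axis=2)
        return Profile(
            tuple(
                (nm, IVNSElement(t[0], t[1], i[0], i[1], f[0], f[1]))
                for nm, (t, i, f) in zip(names, vals)
            )
        )
    raise ValueError(f"unknown kind {kind!r}")


@dataclass(frozen=True)
class RelationTable:
    """Diagnoses x criteria matrix of neutrosophic elements.

    Each row is the canonical evaluation of one candidate diagnosis against
    every symptom — the knowledge base a patient profile is ranked against.
    """

    diagnoses: tuple
    criteria: tuple
    cells: tuple = field(repr=False)  # tuple of row-tuples of elements

    def __post_init__(self) -> None:
        diagnoses = tuple(str(d) for d in self.diagnoses)
        criteria = tuple(str(c) for c in self.criteria)
        if len(set(diagnoses)) != len(diagnoses):
            raise ValueError("duplicate diagnosis labels")
        if len(set(criteria)) != len(criteria):
            raise ValueError("duplicate criterion labels")
        cells = tuple(tuple(validate_element(el) for el in row) for row in self.cells)
        if len(cells) != len(diagnoses) or any(len(r) != len(criteria) for r in cells):
            raise ValueError("cell matrix is not diagnoses x criteria rectangular")
        kinds = {type(el) for row in cells for el in row}
        if len(kinds) != 1:
            raise ValueError("mixed SVNS/IVNS elements in one table")
        object.__setattr__(self, "diagnoses", diagnoses)
        object.__setattr__(self, "criteria", criteria)
        object.__setattr__(self, "cells", cells)

    @property
    def kind(self) -> str:
        return "svns" if isinstance(self.cells[0][0], SVNSElement) else "ivns"

    def row(self, diagnosis: str) -> Profile:
        """The profile of one diagnosis across all criteria."""
        try:
            idx = self.diagnoses.index(diagnosis)
        except ValueError:
            raise KeyError(f"unknown diagnosis {diagnosis!r}") from None
        return Profile(tuple(zip(self.criteria, self.cells[idx])))

    def rows(self):
        return [(d, self.row(d)) for d in self.diagnoses]
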
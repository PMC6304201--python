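"""Measure registry: string identifiers for every similarity measure.

Identifiers are shared between the two kinds — ``("s1_star", "ivns")``
resolves to the interval-valued hybrid — so callers (the classifier, the
axiom engine, the CLI) can name a measure without importing the family
modules.  Each entry records whether the measure consumes the pooling
convention and/or the improved-cosine variant, and whether it is claimed
to be *genuine* (scores 1 only on equal profiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from . import ivns, svns
from .core import Pooling, Profile

__all__ = ["MeasureInfo", "MEASURE_IDS", "get_measure", "evaluate", "list_measures"]


@dataclass(frozen=True)
class MeasureInfo:
    id: str
    kind: str
    func: Callable
    takes_convention: bool
    takes_sc_variant: bool
    genuine: bool
    label: str


def _entry(mid, kind, func, conv, scv, genuine, label):
    return ((mid, kind), MeasureInfo(mid, kind, func, conv, scv, genuine, label))


_REGISTRY = dict(
    [
        _entry("s1", "svns", svns.s1_minmax, True, False, True, "min/max overlap S1"),
        _entry("s2", "svns", svns.s2_cosine, False, False, False, "cosine S2"),
        _entry("s1_star", "svns", svns.s1_star, True, False, True, "hybrid S1*"),
        _entry("s2_star", "svns", svns.s2_star, True, False, True, "hybrid S2*"),
        _entry("sm", "svns", svns.sm_svns, True, False, True, "distance complement SM"),
        _entry("sd", "svns", svns.sd_svns, True, False, True, "distance reciprocal SD"),
        _entry("sc1", "svns", svns.sc1_svns, False, False, True, "improved cosine SC1"),
        _entry("sc2", "svns", svns.sc2_svns, False, False, True, "improved cosine SC2"),
        _entry("sy", "svns", svns.sy_svns, True, True, True, "ratio SY"),
        _entry("s1", "ivns", ivns.s1_minmax_ivns, True, False, True, "min/max overlap S1"),
        _entry("s2", "ivns", ivns.s2_cosine_ivns, False, False, False, "cosine S2"),
        _entry("s1_star", "ivns", ivns.s1_star_ivns, True, False, True, "hybrid S1*"),
        _entry("s2_star", "ivns", ivns.s2_star_ivns, True, False, True, "hybrid S2*"),
        _entry("sm", "ivns", ivns.sm_ivns, True, False, True, "distance complement SM"),
        _entry("sd", "ivns", ivns.sd_ivns, True, False, True, "distance reciprocal SD"),
        _entry("sc1", "ivns", ivns.sc1_ivns, False, False, True, "improved cosine SC1"),
        _entry("sc2", "ivns", ivns.sc2_ivns, False, False, True, "improved cosine SC2"),
        _entry("sy", "ivns", ivns.sy_ivns, True, True, True, "ratio SY"),
    ]
)

MEASURE_IDS = tuple(sorted({mid for mid, _ in _REGISTRY}))


def list_measures(kind: str | None = None) -> list[MeasureInfo]:
    return [m for m in _REGISTRY.values() if kind is None or m.kind == kind]


def get_measure(measure: str, kind: str) -> MeasureInfo:
    try:
        return _REGISTRY[(measure, kind)]
    except KeyError:
        raise ValueError(
            f"unknown measure {measure!r} for kind {kind!r}; known ids: {MEASURE_IDS}"
        ) from None


def evaluate(
    measure: str,
    a: Profile,
    b: Profile,
    convention: str = Pooling.PER_ITEM,
    sc_variant: str = "sc1",
) -> float:
    """Evaluate a measure by id on two profiles of matching kind."""
    info = get_measure(measure, a.kind)
    kwargs = {}
    if info.takes_convention:
        kwargs["convention"] = convention
    if info.takes_sc_variant:
        kwargs["sc_variant"] = sc_variant
    return info.func(a, b, **kwargs)
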
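"""Similarity measures between single-valued neutrosophic profiles.

Nine measures are provided.  Four are the core family:

* :func:`s1_minmax` — overlap ratio of componentwise minima to maxima;
* :func:`s2_cosine` — mean per-criterion cosine of the (T, I, F) vectors
  (not a genuine similarity: proportional unequal vectors score 1);
* :func:`s1_star`, :func:`s2_star` — Euclidean-distance hybrids,
  ``(S + 1 - D)/2``, which restore the "score 1 only on equality" axiom.

Five more serve comparison: ``SM = 1 - D``, ``SD = 1/(1 + D)``, the two
improved cosines ``SC1``/``SC2`` (cosine of a scaled componentwise
difference, immune to the proportionality pathology), and the ratio form
``SY = SC/(SC + D)``.
"""

from __future__ import annotations

import numpy as np

from ._kernels import mean_cosine, minmax_ratio
from .core import Pooling, Profile, _check_conformable
from .distances import d_svns

__all__ = [
    "s1_minmax",
    "s2_cosine",
    "s1_star",
    "s2_star",
    "sm_svns",
    "sd_svns",
    "sc1_svns",
    "sc2_svns",
    "sy_svns",
]


def _arrays(a: Profile, b: Profile):
    _check_conformable(a, b)
    if a.kind != "svns":
        raise ValueError(f"expected svns profiles, got {a.kind}")
    return a.as_array(), b.as_array()


def s1_minmax(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Min/max overlap similarity of the membership triples."""
    u, v = _arrays(a, b)
    return minmax_ratio(u, v, convention)


def s2_cosine(a: Profile, b: Profile) -> float:
    """Mean per-criterion cosine of the (T, I, F) vectors."""
    u, v = _arrays(a, b)
    return mean_cosine(u, v)


def s1_star(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Hybrid of the min/max similarity and the Euclidean distance:
    ``(S1 + 1 - D)/2`` with both terms under the same convention."""
    return 0.5 * (s1_minmax(a, b, convention) + 1.0 - d_svns(a, b, convention))


def s2_star(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Hybrid of the cosine similarity and the Euclidean distance:
    ``(S2 + 1 - D)/2``.  Scores 1 only on equal profiles, unlike the
    plain cosine."""
    return 0.5 * (s2_cosine(a, b) + 1.0 - d_svns(a, b, convention))


def sm_svns(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Distance complement ``1 - D``."""
    return 1.0 - d_svns(a, b, convention)


def sd_svns(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Distance reciprocal ``1/(1 + D)``; range (1/2, 1]."""
    return 1.0 / (1.0 + d_svns(a, b, convention))


def sc1_svns(a: Profile, b: Profile) -> float:
    """Improved cosine on the largest componentwise difference:
    mean over criteria of ``cos(pi * max(|dT|, |dI|, |dF|) / 2)``."""
    u, v = _arrays(a, b)
    worst = np.abs(u - v).max(axis=1)
    return float(np.cos(np.pi * worst / 2.0).mean())


def sc2_svns(a: Profile, b: Profile) -> float:
    """Improved cosine on the summed componentwise differences:
    mean over criteria of ``cos(pi * (|dT| + |dI| + |dF|) / 6)``."""
    u, v = _arrays(a, b)
    total = np.abs(u - v).sum(axis=1)
    return float(np.cos(np.pi * total / 6.0).mean())


def sy_svns(
    a: Profile,
    b: Profile,
    convention: str = Pooling.PER_ITEM,
    sc_variant: str = "sc1",
) -> float:
    """Ratio form ``SC/(SC + D)``; 1 when the distance vanishes.

    The improved-cosine term is selectable (``sc1`` default, or ``sc2``).
    """
    if sc_variant == "sc1":
        sc = sc1_svns(a, b)
    elif sc_variant == "sc2":
        sc = sc2_svns(a, b)
    else:
        raise ValueError(f"unknown sc_variant {sc_variant!r}; expected 'sc1' or 'sc2'")
    d = d_svns(a, b, convention)
    if d == 0.0:
        return 1.0
    return sc / (sc + d)
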
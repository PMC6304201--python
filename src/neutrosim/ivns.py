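"""Similarity measures between interval-valued neutrosophic profiles.

The nine interval-valued counterparts of :mod:`neutrosim.svns`: the same
recipes applied to the six interval bounds (T_L, T_U, I_L, I_U, F_L, F_U)
per criterion.  On degenerate intervals (lo == hi everywhere) every
measure here agrees exactly with its single-valued counterpart on the
reduced profiles.
"""

from __future__ import annotations

import numpy as np

from ._kernels import mean_cosine, minmax_ratio
from .core import Pooling, Profile, _check_conformable
from .distances import d_ivns

__all__ = [
    "s1_minmax_ivns",
    "s2_cosine_ivns",
    "s1_star_ivns",
    "s2_star_ivns",
    "sm_ivns",
    "sd_ivns",
    "sc1_ivns",
    "sc2_ivns",
    "sy_ivns",
]


def _arrays(a: Profile, b: Profile):
    _check_conformable(a, b)
    if a.kind != "ivns":
        raise ValueError(f"expected ivns profiles, got {a.kind}")
    return a.as_array(), b.as_array()  # columns: T_L, T_U, I_L, I_U, F_L, F_U


def s1_minmax_ivns(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Min/max overlap ratio over all six interval bounds."""
    u, v = _arrays(a, b)
    return minmax_ratio(u, v, convention)


def s2_cosine_ivns(a: Profile, b: Profile) -> float:
    """Mean per-criterion cosine of the six-component bound vectors."""
    u, v = _arrays(a, b)
    return mean_cosine(u, v)


def s1_star_ivns(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """``(S1 + 1 - D)/2`` on interval profiles, one convention for both terms."""
    return 0.5 * (s1_minmax_ivns(a, b, convention) + 1.0 - d_ivns(a, b, convention))


def s2_star_ivns(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """``(S2 + 1 - D)/2`` on interval profiles; genuine, unlike the cosine."""
    return 0.5 * (s2_cosine_ivns(a, b) + 1.0 - d_ivns(a, b, convention))


def sm_ivns(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Distance complement ``1 - D``."""
    return 1.0 - d_ivns(a, b, convention)


def sd_ivns(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Distance reciprocal ``1/(1 + D)``."""
    return 1.0 / (1.0 + d_ivns(a, b, convention))


def sc1_ivns(a: Profile, b: Profile) -> float:
    """Improved cosine: mean over criteria of
    ``cos(pi/4 * (max |d lower| + max |d upper|))``, the maxima running
    over the three memberships' lower and upper bounds respectively."""
    u, v = _arrays(a, b)
    diff = np.abs(u - v)
    lower = diff[:, 0::2].max(axis=1)
    upper = diff[:, 1::2].max(axis=1)
    return float(np.cos(np.pi / 4.0 * (lower + upper)).mean())


def sc2_ivns(a: Profile, b: Profile) -> float:
    """Improved cosine: mean over criteria of
    ``cos(pi/12 * sum of all six absolute bound differences)``."""
    u, v = _arrays(a, b)
    total = np.abs(u - v).sum(axis=1)
    return float(np.cos(np.pi / 12.0 * total).mean())


def sy_ivns(
    a: Profile,
    b: Profile,
    convention: str = Pooling.PER_ITEM,
    sc_variant: str = "sc1",
) -> float:
    """Ratio form ``SC/(SC + D)``; 1 when the distance vanishes."""
    if sc_variant == "sc1":
        sc = sc1_ivns(a, b)
    elif sc_variant == "sc2":
        sc = sc2_ivns(a, b)
    else:
        raise ValueError(f"unknown sc_variant {sc_variant!r}; expected 'sc1' or 'sc2'")
    d = d_ivns(a, b, convention)
    if d == 0.0:
        return 1.0
    return sc / (sc + d)
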
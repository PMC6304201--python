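"""Normalized Euclidean distances between neutrosophic profiles.

For SVNS profiles the squared componentwise differences of (T, I, F) are
averaged; for IVNS profiles all six interval bounds enter.  The divisor
(3n or 6n pooled; 3 or 6 per criterion) normalizes the distance into
[0, 1] because every componentwise difference is at most 1.

Two aggregation conventions are exposed (see :class:`~neutrosim.core.Pooling`):

* ``pooled``: one global square root,
  ``sqrt( sum_i sum_c (delta_ic)^2 / (3n) )``;
* ``per_item``: the mean over criteria of per-criterion Euclidean
  distances, ``(1/n) sum_i sqrt( sum_c (delta_ic)^2 / 3 )``.

The per-criterion mean is the package default throughout because it is the
convention under which the bundled worked-example tables are internally
consistent; see docs/methods.md for the full reconciliation.
"""

from __future__ import annotations

import numpy as np

from .core import Pooling, Profile, _check_conformable

__all__ = ["d_svns", "d_ivns"]


def _euclidean(a: Profile, b: Profile, expected_kind: str, convention: str) -> float:
    Pooling.check(convention)
    _check_conformable(a, b)
    if a.kind != expected_kind:
        raise ValueError(f"expected {expected_kind} profiles, got {a.kind}")
    sq = (a.as_array() - b.as_array()) ** 2  # (n, 3) or (n, 6)
    width = sq.shape[1]
    if convention == Pooling.POOLED:
        return float(np.sqrt(sq.sum() / (width * a.n)))
    return float(np.mean(np.sqrt(sq.sum(axis=1) / width)))


def d_svns(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Normalized Euclidean distance between two SVNS profiles, in [0, 1]."""
    return _euclidean(a, b, "svns", convention)


def d_ivns(a: Profile, b: Profile, convention: str = Pooling.PER_ITEM) -> float:
    """Normalized Euclidean distance between two IVNS profiles, in [0, 1].

    On degenerate intervals this coincides (per convention) with
    :func:`d_svns` of the reduced profiles, the six bounds appearing as
    three duplicated pairs whose 1/6 weighting reproduces the 1/3 one.
    """
    return _euclidean(a, b, "ivns", convention)
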
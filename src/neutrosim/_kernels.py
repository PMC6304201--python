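"""Shared numeric kernels for the SVNS and IVNS similarity families.

Both families apply the same four recipes to a pair of per-criterion
component matrices (n x 3 membership triples, or n x 6 interval bounds):
a min/max overlap ratio, a per-criterion cosine, and the two improved
cosines driven by absolute component differences.  The interval variants
only change which columns feed each recipe, so the arithmetic lives here
once.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import Pooling


def minmax_ratio(u: np.ndarray, v: np.ndarray, convention: str) -> float:
    """Ratio of summed componentwise minima to summed componentwise maxima.

    ``pooled`` takes one grand ratio over all criteria; ``per_item``
    averages the n per-criterion ratios.  A criterion whose max-sum is zero
    (both elements identically zero) counts as perfectly similar and
    contributes 1.
    """
    Pooling.check(convention)
    mins = np.minimum(u, v).sum(axis=1)
    maxs = np.maximum(u, v).sum(axis=1)
    if convention == Pooling.POOLED:
        tot = maxs.sum()
        return 1.0 if tot == 0.0 else float(mins.sum() / tot)
    ratios = np.where(maxs == 0.0, 1.0, mins / np.where(maxs == 0.0, 1.0, maxs))
    return float(ratios.mean())


def mean_cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Mean over criteria of the cosine between component vectors.

    Zero-vector policy: two zero vectors are maximally similar (1); a zero
    vector against a nonzero one is maximally dissimilar (0).  Either case
    logs a warning since the cosine itself is undefined there.
    """
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    both_zero = (nu == 0.0) & (nv == 0.0)
    one_zero = ((nu == 0.0) | (nv == 0.0)) & ~both_zero
    if both_zero.any() or one_zero.any():
        warnings.warn(
            "zero membership vector(s) in cosine similarity; applying 1/0 limit policy",
            stacklevel=3,
        )
    denom = np.where((nu == 0.0) | (nv == 0.0), 1.0, nu * nv)
    cosines = (u * v).sum(axis=1) / denom
    cosines = np.where(both_zero, 1.0, np.where(one_zero, 0.0, cosines))
    # guard rounding overshoot so downstream acos-free code stays in [0, 1]
    return float(np.clip(cosines, 0.0, 1.0).mean())
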
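"""Rank-preserving Gaussianisation of the z triangle and quantile thresholds.

The differential-synchronisation values are remapped onto exact standard
normal scores: the element of (1-based, ascending) rank ``r`` among the
``N`` stored pairs becomes ``Phi^-1((r - 0.5) / N)``.  Ties receive the
average of their ranks before mapping, so the transform is deterministic
and invariant to input order.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

from .sync import DiffSyncMatrix

__all__ = ["gaussianize", "quantile_threshold"]


def _average_ranks(vals: np.ndarray) -> np.ndarray:
    """1-based ranks with ties averaged (ties are common: z = 0 whenever
    both correlations are non-positive)."""
    order = np.argsort(vals)
    sv = vals[order]
    new_group = np.empty(sv.size, dtype=bool)
    new_group[0] = True
    np.not_equal(sv[1:], sv[:-1], out=new_group[1:])
    starts = np.flatnonzero(new_group)
    counts = np.diff(np.append(starts, sv.size))
    avg = starts + (counts + 1) / 2.0  # 1-based average rank per tie group
    ranks = np.empty(sv.size)
    ranks[order] = np.repeat(avg, counts)
    return ranks


def gaussianize(z: DiffSyncMatrix) -> DiffSyncMatrix:
    """Map the stored z values onto standard normal scores, preserving ranks."""
    vals = z.z
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("gaussianize needs at least 2 distinct values")
    scores = ndtri((_average_ranks(vals) - 0.5) / vals.size)
    return DiffSyncMatrix(space=z.space, z=scores, normalised=True)


def quantile_threshold(z: DiffSyncMatrix, top_fraction: float) -> float:
    """Threshold retaining the top ``top_fraction`` of normalised edges.

    After Gaussianisation the upper-tail quantile of the triangle is the
    standard normal quantile, so the threshold is ``Phi^-1(1 - top_fraction)``
    rounded to two decimals (0.01 -> 2.33).
    """
    if not z.normalised:
        raise ValueError("quantile_threshold requires a normalised matrix")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    return round(float(ndtri(1.0 - top_fraction)), 2)
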
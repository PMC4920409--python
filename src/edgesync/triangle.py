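"""Condensed upper-triangle storage for voxel-pair matrices.

All pairwise quantities (synchronisation, differential synchronisation)
are stored once per unordered pair ``(i, j)`` with ``i < j``, in the same
row-major order as :func:`numpy.triu_indices` / SciPy's condensed
distance vectors: the pair ``(i, j)`` lives at position
``i * (2n - i - 1) / 2 + (j - i - 1)``.
"""

from __future__ import annotations

import json
from functools import lru_cache
from pathlib import Path

import numpy as np

__all__ = [
    "tri_size",
    "tri_index",
    "tri_pairs",
    "pairs_from_condensed",
    "save_triangle",
    "load_triangle",
]


def tri_size(n: int) -> int:
    """Number of unordered pairs over ``n`` items."""
    return n * (n - 1) // 2


def tri_index(i, j, n: int):
    """Condensed position of pair(s) ``(i, j)`` with ``i < j``.

    Vectorised; ``i`` and ``j`` may be arrays of equal shape.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i >= j):
        raise ValueError("tri_index requires i < j")
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


@lru_cache(maxsize=8)
def _row_starts(n: int) -> np.ndarray:
    i = np.arange(n - 1, dtype=np.int64)
    return i * (2 * n - i - 1) // 2


@lru_cache(maxsize=4)
def tri_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """``(i, j)`` index arrays for every condensed position, cached."""
    return np.triu_indices(n, k=1)


def pairs_from_condensed(k, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`tri_index`: condensed positions -> ``(i, j)`` arrays."""
    k = np.asarray(k, dtype=np.int64)
    if k.size and (k.min() < 0 or k.max() >= tri_size(n)):
        raise ValueError("condensed index out of range")
    starts = _row_starts(n)
    i = np.searchsorted(starts, k, side="right") - 1
    j = k - starts[i] + i + 1
    return i, j


def save_triangle(path: str | Path, values: np.ndarray, meta: dict) -> None:
    """Write a condensed triangle as raw little-endian float64 with a JSON sidecar.

    The sidecar ``<path>.json`` records the number of voxels, the dtype and
    any caller-supplied metadata (voxel order is always ascending voxel id).
    """
    path = Path(path)
    values = np.ascontiguousarray(values, dtype="<f8")
    values.tofile(path)
    sidecar = {"n_values": int(values.size), "dtype": "<f8", **meta}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1) + "\n"
    )


def load_triangle(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.fromfile(path, dtype=meta["dtype"])
    if values.size != meta["n_values"]:
        raise ValueError(f"{path}: expected {meta['n_values']} values, got {values.size}")
    return values, meta
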
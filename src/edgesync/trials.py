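"""Run loading, drift removal, trial extraction and per-trial normalisation.

The pipeline works on in-mask voxels only.  Voxel ids are assigned in
ascending ``(x, y, z)`` lexicographic order of the 0-based lattice
coordinates; every pairwise matrix downstream uses this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelSpace",
    "BoldRun",
    "OnsetTable",
    "TrialArray",
    "load_bold_run",
    "highpass_detrend",
    "extract_trials",
    "normalize_trials",
]


@dataclass(frozen=True, eq=False)  # identity hash: instances are cache keys
class VoxelSpace:
    """A 3D brain mask with voxel geometry and a voxel-id bijection."""

    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={mask.ndim}")
        if mask.sum() < 2:
            raise ValueError("mask must contain at least 2 voxels")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive reals, got {vs}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mask.shape

    @cached_property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @cached_property
    def coords(self) -> np.ndarray:
        """(n, 3) lattice coordinates, lexicographically sorted by (x, y, z)."""
        return np.argwhere(self.mask)

    @cached_property
    def coords_mm(self) -> np.ndarray:
        return self.coords * np.asarray(self.voxel_size_mm)

    @cached_property
    def id_grid(self) -> np.ndarray:
        """3D lookup: lattice coordinate -> voxel id, -1 off mask."""
        grid = np.full(self.dims, -1, dtype=np.int64)
        grid[self.mask] = np.arange(self.n_voxels)
        return grid

    def distance_mm(self, i, j) -> np.ndarray:
        d = self.coords_mm[np.asarray(i)] - self.coords_mm[np.asarray(j)]
        return np.linalg.norm(d, axis=-1)

    def same_grid(self, other: "VoxelSpace") -> bool:
        return (
            self.dims == other.dims
            and np.array_equal(self.mask, other.mask)
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
        )


def _check_same_space(a: VoxelSpace, b: VoxelSpace) -> None:
    if a is not b and not a.same_grid(b):
        raise ValueError("voxel spaces do not match")


@dataclass
class BoldRun:
    """Per-voxel time series of one run: shape (n_voxels, L)."""

    space: VoxelSpace
    series: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=np.float64)
        if self.series.ndim != 2 or self.series.shape[0] != self.space.n_voxels:
            raise ValueError(
                f"series must be (n_voxels, L) = ({self.space.n_voxels}, L), "
                f"got {self.series.shape}"
            )
        if self.series.shape[1] < 2:
            raise ValueError("run must have at least 2 volumes")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.series.shape[1]


@dataclass(frozen=True)
class OnsetTable:
    """Trial onsets: two conditions, equal trial counts, one common length.

    ``onset_volume`` is 0-based. Trials must not overlap, and both
    conditions must have the same number of trials K and the same
    length T (in volumes).
    """

    conditions: tuple
    onsets: tuple
    lengths: tuple

    def __post_init__(self):
        conds = tuple(str(c) for c in self.conditions)
        onsets = tuple(int(o) for o in self.onsets)
        lengths = tuple(int(t) for t in self.lengths)
        if not (len(conds) == len(onsets) == len(lengths)) or not conds:
            raise ValueError("conditions, onsets and lengths must be equal-length, non-empty")
        if any(o < 0 for o in onsets):
            raise ValueError("onset volumes must be non-negative")
        if any(t <= 0 for t in lengths):
            raise ValueError("trial lengths must be positive")
        if len(set(lengths)) != 1:
            raise ValueError(f"all trials must share one length, got {sorted(set(lengths))}")
        labels = sorted(set(conds))
        if len(labels) != 2:
            raise ValueError(f"exactly two condition labels required, got {labels}")
        counts = {lab: conds.count(lab) for lab in labels}
        if counts[labels[0]] != counts[labels[1]]:
            raise ValueError(f"conditions must have equal trial counts, got {counts}")
        order = np.argsort(onsets)
        T = lengths[0]
        for a, b in zip(order[:-1], order[1:]):
            if onsets[b] < onsets[a] + T:
                raise ValueError(
                    f"overlapping trials at onsets {onsets[a]} and {onsets[b]} (T={T})"
                )
        object.__setattr__(self, "conditions", conds)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "lengths", lengths)

    @property
    def trial_length(self) -> int:
        return self.lengths[0]

    @property
    def labels(self) -> tuple[str, str]:
        return tuple(sorted(set(self.conditions)))

    def onsets_for(self, condition: str) -> list[int]:
        sel = [o for c, o in zip(self.conditions, self.onsets) if c == str(condition)]
        if not sel:
            raise ValueError(f"condition {condition!r} absent from onset table")
        return sel

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OnsetTable":
        df = pd.read_csv(path, sep="\t")
        required = ["condition", "onset_volume", "length_volumes"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing onset columns {missing}")
        return cls(
            conditions=tuple(df["condition"].astype(str)),
            onsets=tuple(df["onset_volume"].astype(int)),
            lengths=tuple(df["length_volumes"].astype(int)),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "condition": self.conditions,
                "onset_volume": self.onsets,
                "length_volumes": self.lengths,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class TrialArray:
    """Voxel x trial x time stack of one condition: shape (n, K, T)."""

    space: VoxelSpace
    condition: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != self.space.n_voxels:
            raise ValueError(
                f"values must be (n_voxels, K, T), got {self.values.shape} for "
                f"n_voxels={self.space.n_voxels}"
            )
        n, K, T = self.values.shape
        if K < 2:
            raise ValueError(f"need at least 2 trials, got K={K}")
        if T < 3:
            raise ValueError(f"need at least 3 volumes per trial, got T={T}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trial values must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def trial_length(self) -> int:
        return self.values.shape[2]


def load_bold_run(
    volume_path: str | Path,
    mask_path: str | Path,
    tr_seconds: float | None = None,
    voxel_size_mm: tuple[float, float, float] | None = None,
) -> BoldRun:
    """Load a 4D volume and 3D mask into an in-mask ``BoldRun``.

    Voxel size and TR come from the volume header unless overridden.
    """
    vol_img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    vol = np.asarray(vol_img.dataobj, dtype=np.float64)
    mask = np.asarray(mask_img.dataobj) != 0
    if vol.ndim == 3:
        vol = vol[..., np.newaxis]
    if vol.ndim != 4:
        raise ValueError(f"{volume_path}: expected a 3D/4D volume, got ndim={vol.ndim}")
    if mask.ndim != 3:
        raise ValueError(f"{mask_path}: expected a 3D mask, got ndim={mask.ndim}")
    if vol.shape[:3] != mask.shape:
        raise ValueError(
            f"grid mismatch: volume {vol.shape[:3]} vs mask {mask.shape}"
        )
    if not np.allclose(vol_img.affine, mask_img.affine, atol=1e-3):
        raise ValueError("grid mismatch: volume and mask affines differ")
    if not mask.any():
        raise ValueError(f"{mask_path}: mask is empty")

    zooms = vol_img.header.get_zooms()
    if voxel_size_mm is None:
        voxel_size_mm = tuple(float(z) for z in zooms[:3])
    if tr_seconds is None:
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0

    space = VoxelSpace(mask=mask, voxel_size_mm=voxel_size_mm)
    series = vol[mask]  # boolean indexing preserves (x, y, z) lexicographic order
    if not np.all(np.isfinite(series)):
        bad = np.unique(np.nonzero(~np.isfinite(series))[0])
        raise ValueError(f"non-finite values inside mask at voxel ids {bad[:10].tolist()}")
    return BoldRun(space=space, series=series, tr_seconds=tr_seconds)


def _drift_basis(L: int, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Orthonormal drift regressors: constant, linear trend, and
    discrete-cosine terms with frequency below the cutoff."""
    t = np.arange(L)
    cols = [np.ones(L), t - t.mean()]
    m = 1
    while m / (2.0 * L * tr_seconds) < cutoff_hz:
        cols.append(np.cos(np.pi * m * (t + 0.5) / L))
        m += 1
    X = np.column_stack(cols)
    q, _ = np.linalg.qr(X)
    return q


def highpass_detrend(run: BoldRun, cutoff_hz: float) -> BoldRun:
    """Remove slow baseline drifts by regressing out a low-frequency basis.

    The basis spans the constant, a linear trend and all discrete-cosine
    functions with frequency below ``cutoff_hz``; the operation is an
    orthogonal projection (linear, idempotent) and leaves each voxel
    series with zero mean.
    """
    nyquist = 1.0 / (2.0 * run.tr_seconds)
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at/above Nyquist {nyquist} Hz")
    Q = _drift_basis(run.n_volumes, run.tr_seconds, cutoff_hz)
    Y = run.series
    resid = Y - (Y @ Q) @ Q.T
    return BoldRun(space=run.space, series=resid, tr_seconds=run.tr_seconds)


def extract_trials(run: BoldRun, onsets: OnsetTable, condition: str) -> TrialArray:
    """Cut the run into the K fixed-length trials of one condition, in onset order."""
    T = onsets.trial_length
    starts = sorted(onsets.onsets_for(condition))
    L = run.n_volumes
    for o in starts:
        if o + T > L:
            raise ValueError(f"trial at onset {o} with T={T} exceeds run length L={L}")
    stack = np.stack([run.series[:, o : o + T] for o in starts], axis=1)
    return TrialArray(space=run.space, condition=str(condition), values=stack)


def normalize_trials(trials: TrialArray) -> TrialArray:
    """Normalise each (voxel, trial) series to mean 0, sample sd 1 (divisor T-1)."""
    v = trials.values
    mean = v.mean(axis=2, keepdims=True)
    sd = v.std(axis=2, ddof=1, keepdims=True)
    zero = sd[..., 0] == 0
    if zero.any():
        vox, tri = np.nonzero(zero)
        pairs = list(zip(vox[:10].tolist(), tri[:10].tolist()))
        raise ValueError(
            f"constant (zero-variance) trial series at (voxel, trial) ids {pairs}"
            + ("..." if vox.size > 10 else "")
        )
    return TrialArray(
        space=trials.space, condition=trials.condition, values=(v - mean) / sd
    )
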
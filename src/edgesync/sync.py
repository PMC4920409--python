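"""Effect-size series and differential synchronisation matrices.

For each condition the across-trial mean and sample standard deviation of
every voxel's trial stack give an effect-size time course
``s_i(t) = mu_i(t) / sigma_i(t)``.  The synchronisation of a voxel pair is
the Fisher z-transform of the positive Pearson correlation between their
effect-size courses (non-positive correlations map to 0), and differential
synchronisation is the element-wise difference between the two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trials import TrialArray, VoxelSpace, _check_same_space
from .triangle import tri_size

__all__ = [
    "EffectSeries",
    "SyncMatrix",
    "DiffSyncMatrix",
    "CORRELATION_CLAMP",
    "effect_series",
    "sync_matrix",
    "diff_sync",
    "conjunction",
]

#: correlations are clamped to at most 1 - this before the Fisher transform
CORRELATION_CLAMP = 1e-7


@dataclass
class EffectSeries:
    """Per-voxel effect-size time course of one condition.

    ``degenerate`` flags (voxel, time) cells where the across-trial
    standard deviation vanished; there ``s`` is defined as 0.
    """

    space: VoxelSpace
    condition: str
    mu: np.ndarray
    sigma: np.ndarray
    s: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self):
        for name in ("mu", "sigma", "s"):
            arr = getattr(self, name)
            if arr.shape != self.mu.shape or arr.ndim != 2:
                raise ValueError(f"{name} must be (n_voxels, T)")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("s must be finite")

    @property
    def trial_length(self) -> int:
        return self.s.shape[1]


@dataclass
class SyncMatrix:
    """Upper-triangular synchronisation values theta >= 0 for one condition."""

    space: VoxelSpace
    condition: str
    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.shape != (tri_size(self.space.n_voxels),):
            raise ValueError("theta must be a condensed upper triangle")
        if np.any(self.theta < 0):
            raise ValueError("theta must be non-negative")


@dataclass
class DiffSyncMatrix:
    """Upper-triangular differential synchronisation z (possibly normalised)."""

    space: VoxelSpace
    z: np.ndarray
    normalised: bool = False

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.shape != (tri_size(self.space.n_voxels),):
            raise ValueError("z must be a condensed upper triangle")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z must be finite")


def effect_series(trials: TrialArray) -> EffectSeries:
    """Across-trial mean, sample sd (divisor K-1) and their ratio s = mu/sigma."""
    if trials.n_trials < 2:
        raise ValueError("effect series needs at least 2 trials")
    v = trials.values
    mu = v.mean(axis=1)
    sigma = v.std(axis=1, ddof=1)
    degenerate = sigma == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(degenerate, 0.0, mu / np.where(degenerate, 1.0, sigma))
    return EffectSeries(
        space=trials.space,
        condition=trials.condition,
        mu=mu,
        sigma=sigma,
        s=s,
        degenerate=degenerate,
    )


def _fisher_positive(r: np.ndarray) -> np.ndarray:
    r = np.clip(r, -(1.0 - CORRELATION_CLAMP), 1.0 - CORRELATION_CLAMP)
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = 0.5 * np.log((1.0 + r[pos]) / (1.0 - r[pos]))
    return out


def sync_matrix(effects: EffectSeries, block_size: int = 512) -> SyncMatrix:
    """Pairwise synchronisation over all voxel pairs, computed in row blocks.

    Pairs involving a constant effect-size course (undefined correlation)
    get theta = 0.  Peak extra memory is O(n * block_size) on top of the
    condensed triangle.
    """
    s = effects.s
    n, T = s.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got T={T}")
    centred = s - s.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centred / safe[:, None]
    unit[constant] = 0.0  # correlation with anything is treated as 0 -> theta 0

    r = np.empty(tri_size(n))
    for b0 in range(0, n - 1, block_size):
        b1 = min(b0 + block_size, n - 1)
        R = unit[b0:b1] @ unit.T
        for i in range(b0, b1):
            start = i * (2 * n - i - 1) // 2
            r[start : start + (n - 1 - i)] = R[i - b0, i + 1 :]
    theta = _fisher_positive(r)
    return SyncMatrix(space=effects.space, condition=effects.condition, theta=theta)


def diff_sync(theta_a: SyncMatrix, theta_b: SyncMatrix) -> DiffSyncMatrix:
    """Element-wise difference z = theta_A - theta_B."""
    _check_same_space(theta_a.space, theta_b.space)
    return DiffSyncMatrix(
        space=theta_a.space, z=theta_a.theta - theta_b.theta, normalised=False
    )


def conjunction(z1: DiffSyncMatrix, z2: DiffSyncMatrix) -> DiffSyncMatrix:
    """Combine two normalised runs by the element-wise minimum."""
    _check_same_space(z1.space, z2.space)
    if not (z1.normalised and z2.normalised):
        raise ValueError("conjunction requires normalised inputs")
    return DiffSyncMatrix(space=z1.space, z=np.minimum(z1.z, z2.z), normalised=True)
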
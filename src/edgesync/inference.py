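"""Permutation null for local edge densities and the empirical Fdr.

The null is built by swapping task labels per trial: a Bernoulli(0.5)
vector rho of length K decides, for each trial, whether its condition
labels are exchanged.  The same rho applies to every voxel, which keeps
the spatial correlation structure of the data intact in the null.  The
full pipeline (effect series, synchronisation, differencing, rank
Gaussianisation, thresholding, local edge density) is re-run inside every
replicate, so null and observed triangles share an identical marginal
distribution by construction.

With prior null probability pi0 (fixed to 1, the conservative choice) the
empirical false-discovery rate at a density score d is
``Fdr(d) = pi0 * (1 - F0(d)) / (1 - Fz(d))``, with F0/Fz the null and
observed cumulative distributions of D_e estimated by cumulative
histogram counting on a shared grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import reduce

import numpy as np

from .graph import AdjacencyScheme, EdgeDensityMap, EdgeSet, candidate_edges, density_map
from .normalize import gaussianize, quantile_threshold
from .sync import DiffSyncMatrix, EffectSeries, conjunction, diff_sync, effect_series, sync_matrix
from .trials import TrialArray

__all__ = [
    "PermutationVector",
    "NullEnsemble",
    "FdrCurve",
    "PipelineParams",
    "draw_permutation",
    "permuted_effect_series",
    "observed_density_map",
    "null_density_samples",
    "estimate_cdf",
    "default_grid",
    "fdr_curve",
    "significance_cutoff",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationVector:
    """Per-trial swap indicators: rho[k] = 1 means trial k's labels swap."""

    rho: np.ndarray
    seed: int

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=np.uint8)
        if rho.ndim != 1 or not np.isin(rho, (0, 1)).all():
            raise ValueError("rho must be a 1D binary vector")
        object.__setattr__(self, "rho", rho)


@dataclass
class NullEnsemble:
    """Pooled D_e values from P label-permutation replicates."""

    samples: np.ndarray
    per_replicate_counts: np.ndarray
    P: int
    seeds: list

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if self.samples.size and (self.samples.min() < 0 or self.samples.max() > 1):
            raise ValueError("null samples must lie in [0, 1]")


@dataclass
class FdrCurve:
    """Paired empirical cdfs over D_e and the induced Fdr function."""

    grid: np.ndarray
    F0: np.ndarray
    Fz: np.ndarray
    fdr: np.ndarray
    pi0: float = 1.0
    cutoff: float | None = None


@dataclass(frozen=True)
class PipelineParams:
    """Knobs of the edge-selection stage shared by observed and null runs."""

    top_fraction: float = 0.01
    min_distance_mm: float = 15.0
    adjacency: AdjacencyScheme = field(default_factory=AdjacencyScheme)


def draw_permutation(K: int, seed: int) -> PermutationVector:
    """K independent Bernoulli(0.5) swap indicators, reproducible from the seed."""
    if K < 2:
        raise ValueError("K must be >= 2")
    rho = np.random.default_rng(seed).integers(0, 2, size=K, dtype=np.uint8)
    return PermutationVector(rho=rho, seed=int(seed))


def permuted_effect_series(
    trials_a: TrialArray, trials_b: TrialArray, rho: PermutationVector
) -> tuple[EffectSeries, EffectSeries]:
    """Effect series after swapping the labels of the trials flagged by rho.

    The same rho applies to every voxel.  rho = 0 everywhere reproduces
    the unpermuted effect series exactly.
    """
    if trials_a.values.shape != trials_b.values.shape:
        raise ValueError("trial arrays must have identical shapes")
    if rho.rho.size != trials_a.n_trials:
        raise ValueError("rho length must equal the trial count K")
    swap = rho.rho.astype(bool)[None, :, None]
    mixed_a = np.where(swap, trials_b.values, trials_a.values)
    mixed_b = np.where(swap, trials_a.values, trials_b.values)
    ea = effect_series(
        TrialArray(space=trials_a.space, condition=trials_a.condition, values=mixed_a)
    )
    eb = effect_series(
        TrialArray(space=trials_b.space, condition=trials_b.condition, values=mixed_b)
    )
    return ea, eb


def _normalised_z(ea: EffectSeries, eb: EffectSeries) -> DiffSyncMatrix:
    return gaussianize(diff_sync(sync_matrix(ea), sync_matrix(eb)))


def _edges_and_densities(
    zns: list[DiffSyncMatrix], params: PipelineParams
) -> tuple[EdgeSet, EdgeDensityMap]:
    zn = reduce(conjunction, zns)
    z_t = quantile_threshold(zn, params.top_fraction)
    edges = candidate_edges(zn, z_t, params.min_distance_mm, zn.space)
    return edges, density_map(edges, zn, params.adjacency)


def observed_density_map(
    runs: list[tuple[TrialArray, TrialArray]], params: PipelineParams
) -> tuple[EdgeSet, EdgeDensityMap]:
    """Unpermuted pipeline: per-run normalised z, conjunction, edges, D_e."""
    if not runs:
        raise ValueError("at least one run required")
    zns = [_normalised_z(effect_series(a), effect_series(b)) for a, b in runs]
    return _edges_and_densities(zns, params)


def null_density_samples(
    runs: list[tuple[TrialArray, TrialArray]],
    params: PipelineParams,
    P: int,
    seed: int,
) -> NullEnsemble:
    """Pooled null D_e from P label-swap replicates of the full pipeline.

    One independent rho is drawn per run per replicate (runs contain
    distinct trials); all rho seeds are derived from ``seed`` and recorded.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if not runs:
        raise ValueError("at least one run required")
    root = np.random.default_rng(seed)
    samples: list[np.ndarray] = []
    counts = np.empty(P, dtype=np.int64)
    seeds: list[list[int]] = []
    for p in range(P):
        rep_seeds = [int(s) for s in root.integers(0, 2**63 - 1, size=len(runs))]
        seeds.append(rep_seeds)
        zns = []
        for (ta, tb), s in zip(runs, rep_seeds):
            rho = draw_permutation(ta.n_trials, s)
            ea, eb = permuted_effect_series(ta, tb, rho)
            zns.append(_normalised_z(ea, eb))
        _, dmap = _edges_and_densities(zns, params)
        samples.append(dmap.density)
        counts[p] = len(dmap)
    pooled = np.concatenate(samples) if samples else np.empty(0)
    return NullEnsemble(samples=pooled, per_replicate_counts=counts, P=P, seeds=seeds)


def default_grid(n_bins: int = 1000) -> np.ndarray:
    """Equal-width D_e bin edges on [0, 1]; 0.001 resolves all distinct D_e."""
    return np.linspace(0.0, 1.0, n_bins + 1)


def estimate_cdf(samples: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Right-continuous empirical cdf on the grid from cumulative counts."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("cannot estimate a cdf from empty samples")
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1D and strictly ascending")
    ordered = np.sort(samples)
    return np.searchsorted(ordered, grid, side="right") / samples.size


def fdr_curve(
    F0: np.ndarray, Fz: np.ndarray, pi0: float = 1.0, grid: np.ndarray | None = None
) -> FdrCurve:
    """Empirical Fdr(d) = min(1, pi0 * (1 - F0(d)) / (1 - Fz(d))) on the grid.

    Where the observed tail 1 - Fz vanishes, the last finite Fdr value is
    carried forward.
    """
    F0 = np.asarray(F0, dtype=np.float64)
    Fz = np.asarray(Fz, dtype=np.float64)
    if F0.shape != Fz.shape:
        raise ValueError("F0 and Fz must share one grid")
    if not 0.0 < pi0 <= 1.0:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    if grid is None:
        grid = default_grid(F0.size - 1)
    grid = np.asarray(grid, dtype=np.float64)
    if grid.shape != F0.shape:
        raise ValueError("grid length must match the cdfs")

    num = pi0 * (1.0 - F0)
    den = 1.0 - Fz
    fdr = np.ones_like(num)
    ok = den > 0
    fdr[ok] = np.minimum(1.0, num[ok] / den[ok])
    if not ok.all():
        # carry the last finite value into the exhausted observed tail
        idx = np.where(ok, np.arange(ok.size), -1)
        last = np.maximum.accumulate(idx)
        filled = last >= 0
        fdr[~ok & filled] = fdr[last[~ok & filled]]
    return FdrCurve(grid=grid, F0=F0, Fz=Fz, fdr=fdr, pi0=pi0)


def significance_cutoff(curve: FdrCurve, alpha: float) -> float | None:
    """Smallest grid density with Fdr below alpha; edges above it are significant."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    below = curve.fdr < alpha
    if not below.any():
        curve.cutoff = None
        return None
    first = int(np.argmax(below))
    if np.any(curve.fdr[first:] >= alpha):
        logger.warning("Fdr curve is non-monotone beyond the cutoff at %g", curve.grid[first])
    curve.cutoff = float(curve.grid[first])
    return curve.cutoff
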
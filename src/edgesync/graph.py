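"""Voxel-lattice adjacency, candidate-edge selection and local edge density.

An edge is an unordered pair of in-mask voxels whose normalised z exceeds
the threshold z_t (strictly) and whose endpoints are at least a minimum
Euclidean distance apart (15 mm by default, so the endpoint neighbourhoods
cannot overlap).  Its local edge density D_e is the fraction of
suprathreshold pairs among all pairs crossing between the closed
(centre-included) adjacency neighbourhoods of the two endpoints: for two
full 26-neighbourhoods that is a denominator of 27 * 27 = 729, and the
edge itself is one of the counted crossing pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from weakref import WeakKeyDictionary

import numpy as np

from .sync import DiffSyncMatrix
from .trials import VoxelSpace
from .triangle import pairs_from_condensed, tri_index

__all__ = [
    "AdjacencyScheme",
    "EdgeSet",
    "EdgeDensityMap",
    "closed_neighbourhood",
    "candidate_edges",
    "local_edge_density",
    "density_map",
]


@dataclass(frozen=True)
class AdjacencyScheme:
    """6-, 18- or 26-connectivity on the voxel lattice."""

    kind: int = 26

    def __post_init__(self):
        if self.kind not in (6, 18, 26):
            raise ValueError(f"adjacency kind must be 6, 18 or 26, got {self.kind}")

    @property
    def offsets(self) -> np.ndarray:
        return _offsets(self.kind)


@lru_cache(maxsize=3)
def _offsets(kind: int) -> np.ndarray:
    d = np.array(
        [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    )
    order = np.abs(d).sum(axis=1)
    if kind == 6:
        return d[order == 1]
    if kind == 18:
        return d[order <= 2]
    return d


@dataclass
class EdgeSet:
    """Suprathreshold, non-short edges: (m, 2) voxel-id pairs with i < j."""

    space: VoxelSpace
    edges: np.ndarray
    z_t: float
    min_distance_mm: float
    z: np.ndarray | None = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size and np.any(self.edges[:, 0] >= self.edges[:, 1]):
            raise ValueError("edges must be stored with i < j")
        if self.min_distance_mm <= 0:
            raise ValueError("min_distance_mm must be positive")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=np.float64)
            if self.z.shape != (len(self.edges),):
                raise ValueError("z must have one value per edge")

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class EdgeDensityMap:
    """Local edge density D_e in [0, 1] per edge; absent edges have D_e = 0."""

    space: VoxelSpace
    edges: np.ndarray
    density: np.ndarray
    z_t: float
    adjacency: AdjacencyScheme

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.density.shape != (len(self.edges),):
            raise ValueError("one density per edge required")
        if self.density.size and (self.density.min() < 0 or self.density.max() > 1):
            raise ValueError("densities must lie in [0, 1]")

    def value(self, i: int, j: int) -> float:
        i, j = (i, j) if i < j else (j, i)
        hit = np.nonzero((self.edges[:, 0] == i) & (self.edges[:, 1] == j))[0]
        return float(self.density[hit[0]]) if hit.size else 0.0

    def __len__(self) -> int:
        return len(self.edges)


def closed_neighbourhood(
    voxel_id: int, space: VoxelSpace, adjacency: AdjacencyScheme
) -> np.ndarray:
    """The voxel itself plus its in-mask adjacent voxels, as sorted voxel ids."""
    if not 0 <= voxel_id < space.n_voxels:
        raise ValueError(f"voxel id {voxel_id} not in mask")
    centre = space.coords[voxel_id]
    pts = centre + adjacency.offsets
    dims = np.asarray(space.dims)
    ok = np.all((pts >= 0) & (pts < dims), axis=1)
    ids = space.id_grid[tuple(pts[ok].T)]
    ids = ids[ids >= 0]
    return np.sort(np.append(ids, voxel_id))


def candidate_edges(
    zn: DiffSyncMatrix, z_t: float, min_distance_mm: float, space: VoxelSpace
) -> EdgeSet:
    """All pairs with normalised z strictly above z_t and distance >= min_distance_mm."""
    if not zn.normalised:
        raise ValueError("candidate_edges requires a normalised z matrix")
    if min_distance_mm <= 0:
        raise ValueError("min_distance_mm must be positive")
    n = space.n_voxels
    k = np.flatnonzero(zn.z > z_t)
    i, j = pairs_from_condensed(k, n)
    dist = space.distance_mm(i, j)
    keep = dist >= min_distance_mm  # "less than 15 mm" excluded: boundary kept
    return EdgeSet(
        space=space,
        edges=np.column_stack([i[keep], j[keep]]),
        z_t=float(z_t),
        min_distance_mm=float(min_distance_mm),
        z=zn.z[k[keep]],
    )


def _crossing_count(
    Ni: np.ndarray, Nj: np.ndarray, z: np.ndarray, z_t: float, n: int
) -> int:
    p = np.repeat(Ni, Nj.size)
    q = np.tile(Nj, Ni.size)
    lo = np.minimum(p, q)
    hi = np.maximum(p, q)
    return int((z[tri_index(lo, hi, n)] > z_t).sum())


def local_edge_density(
    edge: tuple[int, int],
    zn: DiffSyncMatrix,
    z_t: float,
    adjacency: AdjacencyScheme,
    space: VoxelSpace,
) -> float:
    """D_e of one edge: suprathreshold crossing pairs / all crossing pairs.

    Only pairs with one endpoint in each closed neighbourhood are counted;
    the denominator is the product of the in-mask neighbourhood sizes
    (729 for two full 26-neighbourhoods).
    """
    i, j = edge
    Ni = closed_neighbourhood(i, space, adjacency)
    Nj = closed_neighbourhood(j, space, adjacency)
    if np.intersect1d(Ni, Nj, assume_unique=True).size:
        raise ValueError(
            f"neighbourhoods of edge ({i}, {j}) overlap; endpoints too close"
        )
    count = _crossing_count(Ni, Nj, zn.z, z_t, space.n_voxels)
    return count / (Ni.size * Nj.size)


# closed neighbourhoods per voxel, cached per (space, adjacency kind)
_NBHD_CACHE: WeakKeyDictionary = WeakKeyDictionary()


def _neighbourhood_table(space: VoxelSpace, adjacency: AdjacencyScheme) -> dict:
    per_space = _NBHD_CACHE.setdefault(space, {})
    return per_space.setdefault(adjacency.kind, {})


def density_map(
    edges: EdgeSet, zn: DiffSyncMatrix, adjacency: AdjacencyScheme
) -> EdgeDensityMap:
    """Local edge density for every edge in the set."""
    space = edges.space
    n = space.n_voxels
    z_t = edges.z_t

    # symmetric suprathreshold lookup; O(n^2) bools, fine at desk scale
    supra = np.zeros((n, n), dtype=bool)
    k = np.flatnonzero(zn.z > z_t)
    si, sj = pairs_from_condensed(k, n)
    supra[si, sj] = True
    supra[sj, si] = True

    nbhd = _neighbourhood_table(space, adjacency)
    for v in np.unique(edges.edges):
        if int(v) not in nbhd:
            nbhd[int(v)] = closed_neighbourhood(int(v), space, adjacency)

    # neighbourhoods reach 1 voxel out, so a Chebyshev gap >= 3 lattice steps
    # guarantees disjointness; only closer edges need the explicit check
    if len(edges):
        cheb = np.abs(
            space.coords[edges.edges[:, 0]] - space.coords[edges.edges[:, 1]]
        ).max(axis=1)
    dens = np.empty(len(edges))
    for e, (i, j) in enumerate(edges.edges):
        Ni = nbhd[int(i)]
        Nj = nbhd[int(j)]
        if cheb[e] < 3 and np.intersect1d(Ni, Nj, assume_unique=True).size:
            raise ValueError(
                f"neighbourhoods of edge ({i}, {j}) overlap; endpoints too close"
            )
        dens[e] = supra[Ni[:, None], Nj].sum() / (Ni.size * Nj.size)
    return EdgeDensityMap(
        space=space, edges=edges.edges, density=dens, z_t=z_t, adjacency=adjacency
    )
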
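"""Hubness maps and result export (NIfTI volume, edge table, manifest)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .graph import EdgeDensityMap, EdgeSet
from .inference import FdrCurve
from .trials import VoxelSpace

__all__ = ["HubnessMap", "hubness", "seed_restricted_edges", "export_results"]


@dataclass
class HubnessMap:
    """Per-voxel count of significant edges ending in that voxel."""

    space: VoxelSpace
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.space.n_voxels,):
            raise ValueError("counts must have one entry per in-mask voxel")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def hubness(significant_edges: EdgeSet, space: VoxelSpace) -> HubnessMap:
    """Count, per voxel, the significant edges having it as an endpoint."""
    counts = np.bincount(
        significant_edges.edges.ravel(), minlength=space.n_voxels
    ).astype(np.int64)
    if counts.size > space.n_voxels:
        raise ValueError("edge endpoints outside the voxel space")
    return HubnessMap(space=space, counts=counts)


def seed_restricted_edges(significant_edges: EdgeSet, roi: np.ndarray) -> EdgeSet:
    """Edges with at least one endpoint inside the region-of-interest id set."""
    roi = np.unique(np.asarray(roi, dtype=np.int64))
    if roi.size == 0:
        raise ValueError("roi must not be empty")
    if roi.min() < 0 or roi.max() >= significant_edges.space.n_voxels:
        raise ValueError("roi ids must lie inside the mask")
    keep = np.isin(significant_edges.edges[:, 0], roi) | np.isin(
        significant_edges.edges[:, 1], roi
    )
    return EdgeSet(
        space=significant_edges.space,
        edges=significant_edges.edges[keep],
        z_t=significant_edges.z_t,
        min_distance_mm=significant_edges.min_distance_mm,
        z=None if significant_edges.z is None else significant_edges.z[keep],
    )


def _edge_table(
    edges: EdgeSet, dmap: EdgeDensityMap, curve: FdrCurve | None
) -> pd.DataFrame:
    space = edges.space
    i = edges.edges[:, 0]
    j = edges.edges[:, 1]
    ci = space.coords[i]
    cj = space.coords[j]
    mi = space.coords_mm[i]
    mj = space.coords_mm[j]
    dens = np.array([dmap.value(int(a), int(b)) for a, b in edges.edges])
    cols = {
        "voxel_i": i,
        "voxel_j": j,
        "ix": ci[:, 0], "iy": ci[:, 1], "iz": ci[:, 2],
        "jx": cj[:, 0], "jy": cj[:, 1], "jz": cj[:, 2],
        "ix_mm": mi[:, 0], "iy_mm": mi[:, 1], "iz_mm": mi[:, 2],
        "jx_mm": mj[:, 0], "jy_mm": mj[:, 1], "jz_mm": mj[:, 2],
        "z": edges.z if edges.z is not None else np.full(len(edges), np.nan),
        "edge_density": dens,
    }
    if curve is not None:
        bins = np.clip(
            np.searchsorted(curve.grid, dens, side="right") - 1, 0, curve.fdr.size - 1
        )
        cols["fdr"] = curve.fdr[bins]
    return pd.DataFrame(cols)


def export_results(
    hub: HubnessMap,
    edges: EdgeSet,
    dmap: EdgeDensityMap,
    curve: FdrCurve | None,
    manifest: dict,
    out_dir: str | Path,
    affine: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write hubness NIfTI, edge TSV, Fdr-curve TSV and a JSON run manifest.

    Outputs are byte-stable for identical inputs (sorted keys, no
    timestamps in the NIfTI header).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    space = hub.space
    if affine is None:
        affine = np.diag(list(space.voxel_size_mm) + [1.0])

    vol = np.zeros(space.dims, dtype=np.int32)
    vol[space.mask] = hub.counts
    hub_path = out_dir / "hubness.nii.gz"
    nib.save(nib.Nifti1Image(vol, affine), str(hub_path))

    edges_path = out_dir / "edges.tsv"
    _edge_table(edges, dmap, curve).to_csv(edges_path, sep="\t", index=False)

    paths = {"hubness": hub_path, "edges": edges_path}
    if curve is not None:
        curve_path = out_dir / "fdr_curve.tsv"
        pd.DataFrame(
            {"grid": curve.grid, "F0": curve.F0, "Fz": curve.Fz, "fdr": curve.fdr}
        ).to_csv(curve_path, sep="\t", index=False)
        paths["fdr_curve"] = curve_path

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    paths["manifest"] = manifest_path
    return paths
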
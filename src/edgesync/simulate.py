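"""Synthetic two-condition block-design data with known ground truth.

Planted clusters respond with a shared waveform whose per-trial sign
``g_k`` is +1 with probability ``(1 + c) / 2``: consistency ``c = 1``
gives identical responses on every trial, ``c = 0`` gives sign-flipping
responses whose per-trial correlation magnitude is unchanged but whose
across-trial effect size collapses.  Clusters sharing a ``group`` id (and
condition) share the same sign sequence, so cross-cluster pairs stay
per-trial synchronised.  Setting amplitude 0 (or planting nothing) yields
an exchangeable null where both conditions are identically distributed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.stats import gamma as gamma_dist

from .trials import OnsetTable, TrialArray, VoxelSpace

__all__ = [
    "PlantedCluster",
    "SimulationSpec",
    "GroundTruth",
    "default_waveform",
    "generate",
    "write_nifti_fixture",
]


def default_waveform(T: int, tr_seconds: float = 0.72) -> np.ndarray:
    """Boxcar response convolved with a double-gamma impulse, peak-scaled to 1."""
    t = np.arange(T) * tr_seconds
    impulse = gamma_dist.pdf(t, 6) - 0.35 * gamma_dist.pdf(t, 16)
    w = np.convolve(np.ones(T), impulse)[:T]
    peak = np.abs(w).max()
    if peak == 0:
        raise ValueError("degenerate waveform")
    return w / peak


@dataclass(frozen=True)
class PlantedCluster:
    """A rectangular voxel block responding in one condition."""

    origin: tuple[int, int, int]
    shape: tuple[int, int, int]
    condition: str
    amplitude: float
    consistency: float = 1.0
    group: int = 0

    def __post_init__(self):
        if not 0.0 <= self.consistency <= 1.0:
            raise ValueError("consistency must lie in [0, 1]")
        if any(s < 1 for s in self.shape):
            raise ValueError("cluster shape must be positive")

    def voxel_ids(self, space: VoxelSpace) -> np.ndarray:
        sl = tuple(slice(o, o + s) for o, s in zip(self.origin, self.shape))
        ids = space.id_grid[sl].ravel()
        ids = ids[ids >= 0]
        if ids.size == 0:
            raise ValueError(f"cluster at {self.origin} lies outside the mask")
        return np.sort(ids)


@dataclass(frozen=True)
class SimulationSpec:
    dims: tuple[int, int, int]
    n_trials: int = 20
    trial_length: int = 16
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 0.72
    clusters: tuple[PlantedCluster, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0
    waveform: np.ndarray | None = None

    def __post_init__(self):
        if self.n_trials < 2 or self.trial_length < 3:
            raise ValueError("need K >= 2 trials and T >= 3 volumes per trial")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "clusters", tuple(self.clusters))

    def space(self) -> VoxelSpace:
        return VoxelSpace(
            mask=np.ones(self.dims, dtype=bool), voxel_size_mm=self.voxel_size_mm
        )


@dataclass
class GroundTruth:
    """Planted cross-cluster voxel pairs per condition, plus provenance."""

    space: VoxelSpace
    edges: dict  # condition -> (m, 2) int array, i < j
    clusters: tuple[PlantedCluster, ...]
    seed: int

    def long_range(self, condition: str, min_distance_mm: float) -> np.ndarray:
        """Planted edges far enough apart to survive the short-edge exclusion."""
        e = self.edges.get(condition, np.empty((0, 2), dtype=np.int64))
        if e.size == 0:
            return e
        keep = self.space.distance_mm(e[:, 0], e[:, 1]) >= min_distance_mm
        return e[keep]


def _cross_pairs(ids_a: np.ndarray, ids_b: np.ndarray) -> np.ndarray:
    p = np.repeat(ids_a, ids_b.size)
    q = np.tile(ids_b, ids_a.size)
    lo, hi = np.minimum(p, q), np.maximum(p, q)
    pairs = np.unique(np.column_stack([lo, hi]), axis=0)
    return pairs[pairs[:, 0] != pairs[:, 1]]


def generate(spec: SimulationSpec) -> tuple[TrialArray, TrialArray, GroundTruth]:
    """Draw one synthetic dataset: condition-A trials, condition-B trials, truth."""
    space = spec.space()
    n, K, T = space.n_voxels, spec.n_trials, spec.trial_length
    rng = np.random.default_rng(spec.seed)
    data = {
        "A": rng.normal(0.0, spec.noise_sd, size=(n, K, T)),
        "B": rng.normal(0.0, spec.noise_sd, size=(n, K, T)),
    }
    w = spec.waveform if spec.waveform is not None else default_waveform(T, spec.tr_seconds)
    if w.shape != (T,):
        raise ValueError(f"waveform must have length T={T}")

    # one sign sequence per (condition, group); clusters in a group must agree on c
    signs: dict[tuple[str, int], np.ndarray] = {}
    for cl in spec.clusters:
        if cl.condition not in data:
            raise ValueError(f"cluster condition must be 'A' or 'B', got {cl.condition!r}")
        key = (cl.condition, cl.group)
        if key not in signs:
            p_plus = (1.0 + cl.consistency) / 2.0
            signs[key] = np.where(rng.random(K) < p_plus, 1.0, -1.0)
    for cl in spec.clusters:
        g = signs[(cl.condition, cl.group)]
        ids = cl.voxel_ids(space)
        data[cl.condition][ids] += g[None, :, None] * cl.amplitude * w[None, None, :]

    edges: dict[str, np.ndarray] = {}
    for cond in ("A", "B"):
        blocks = [cl.voxel_ids(space) for cl in spec.clusters if cl.condition == cond]
        pairs = [
            _cross_pairs(blocks[a], blocks[b])
            for a in range(len(blocks))
            for b in range(a + 1, len(blocks))
        ]
        edges[cond] = (
            np.unique(np.concatenate(pairs), axis=0)
            if pairs
            else np.empty((0, 2), dtype=np.int64)
        )

    truth = GroundTruth(space=space, edges=edges, clusters=spec.clusters, seed=spec.seed)
    return (
        TrialArray(space=space, condition="A", values=data["A"]),
        TrialArray(space=space, condition="B", values=data["B"]),
        truth,
    )


def write_nifti_fixture(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a run as NIfTI + onset TSV + ground-truth JSON.

    Trials are concatenated A/B-interleaved with no gaps, so the run has
    2*K*T volumes; the files round-trip exactly through run loading and
    trial extraction (float64 storage, uncompressed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ta, tb, truth = generate(spec)
    space = truth.space
    K, T = spec.n_trials, spec.trial_length
    L = 2 * K * T

    vol = np.zeros(spec.dims + (L,), dtype=np.float64)
    conditions, onsets = [], []
    for k in range(K):
        oa, ob = 2 * k * T, (2 * k + 1) * T
        vol[space.mask, oa : oa + T] = ta.values[:, k, :]
        vol[space.mask, ob : ob + T] = tb.values[:, k, :]
        conditions += ["A", "B"]
        onsets += [oa, ob]

    affine = np.diag(list(spec.voxel_size_mm) + [1.0])
    run_img = nib.Nifti1Image(vol, affine)
    run_img.header.set_zooms(spec.voxel_size_mm + (spec.tr_seconds,))
    run_path = out_dir / "run.nii"
    nib.save(run_img, str(run_path))

    mask_img = nib.Nifti1Image(space.mask.astype(np.uint8), affine)
    mask_path = out_dir / "mask.nii"
    nib.save(mask_img, str(mask_path))

    onsets_path = out_dir / "onsets.tsv"
    OnsetTable(
        conditions=tuple(conditions), onsets=tuple(onsets), lengths=(T,) * (2 * K)
    ).to_tsv(onsets_path)

    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "seed": spec.seed,
                "dims": list(spec.dims),
                "voxel_size_mm": list(spec.voxel_size_mm),
                "n_trials": K,
                "trial_length": T,
                "noise_sd": spec.noise_sd,
                "clusters": [
                    {
                        "origin": list(cl.origin),
                        "shape": list(cl.shape),
                        "condition": cl.condition,
                        "amplitude": cl.amplitude,
                        "consistency": cl.consistency,
                        "group": cl.group,
                    }
                    for cl in spec.clusters
                ],
                "edges": {c: e.tolist() for c, e in truth.edges.items()},
            },
            sort_keys=True,
            indent=1,
        )
        + "\n"
    )
    return {
        "run": run_path,
        "mask": mask_path,
        "onsets": onsets_path,
        "truth": truth_path,
    }
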
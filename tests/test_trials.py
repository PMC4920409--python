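import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgesync.trials import (
    BoldRun,
    OnsetTable,
    TrialArray,
    VoxelSpace,
    extract_trials,
    highpass_detrend,
    load_bold_run,
    normalize_trials,
)

from .conftest import full_space


def _write_pair(tmp_path, vol, mask, voxel_size=(3.0, 3.0, 3.0), tr=0.72):
    affine = np.diag(list(voxel_size) + [1.0])
    vol_img = nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine)
    if vol.ndim == 4:
        vol_img.header.set_zooms(voxel_size + (tr,))
    vol_path = tmp_path / "run.nii"
    mask_path = tmp_path / "mask.nii"
    nib.save(vol_img, str(vol_path))
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(mask_path))
    return vol_path, mask_path


class TestVoxelSpace:
    def test_voxel_ids_are_lexicographic(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[1, 0, 1] = mask[0, 1, 0] = mask[0, 0, 1] = True
        space = VoxelSpace(mask=mask, voxel_size_mm=(3, 3, 3))
        assert space.coords.tolist() == [[0, 0, 1], [0, 1, 0], [1, 0, 1]]
        assert space.id_grid[1, 0, 1] == 2

    def test_rejects_tiny_mask(self):
        with pytest.raises(ValueError, match="at least 2"):
            VoxelSpace(mask=np.zeros((3, 3, 3), dtype=bool), voxel_size_mm=(3, 3, 3))

    def test_rejects_bad_voxel_size(self):
        with pytest.raises(ValueError, match="positive"):
            full_space((3, 3, 3), voxel_size_mm=(3.0, -1.0, 3.0))

    def test_distance_mm(self):
        space = full_space((6, 1, 1))
        assert space.distance_mm(0, 5) == pytest.approx(15.0)


class TestLoadBoldRun:
    def test_shape_bookkeeping(self, tmp_path, rng):
        vol = rng.normal(size=(4, 4, 4, 20))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask.ravel()[:10] = True
        run = load_bold_run(*_write_pair(tmp_path, vol, mask))
        assert run.space.n_voxels == 10
        assert run.n_volumes == 20
        assert run.tr_seconds == pytest.approx(0.72)
        assert run.space.voxel_size_mm == (3.0, 3.0, 3.0)
        # in-mask voxels in id order
        np.testing.assert_allclose(run.series, vol[mask])

    def test_grid_mismatch(self, tmp_path, rng):
        vol = rng.normal(size=(5, 4, 4, 6))
        p1, _ = _write_pair(tmp_path, vol, np.ones((5, 4, 4)))
        sub = tmp_path / "m2"
        sub.mkdir()
        _, p2 = _write_pair(sub, rng.normal(size=(4, 4, 4, 6)), np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="grid mismatch"):
            load_bold_run(p1, p2)

    def test_empty_mask(self, tmp_path, rng):
        vol = rng.normal(size=(4, 4, 4, 6))
        paths = _write_pair(tmp_path, vol, np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            load_bold_run(*paths)

    def test_nonfinite_inside_mask(self, tmp_path, rng):
        vol = rng.normal(size=(4, 4, 4, 6))
        vol[0, 0, 0, 3] = np.nan
        paths = _write_pair(tmp_path, vol, np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="non-finite"):
            load_bold_run(*paths)


def _run_from(series, tr=0.72):
    series = np.atleast_2d(series)
    space = full_space((series.shape[0] + 1, 1, 1))
    padded = np.vstack([series, np.zeros_like(series[:1])])
    return BoldRun(space=space, series=padded, tr_seconds=tr)


class TestHighpassDetrend:
    CUTOFF = 1.0 / 90.0

    def test_ramp_is_removed(self):
        ramp = np.linspace(0.0, 10.0, 200)
        out = highpass_detrend(_run_from(ramp), self.CUTOFF)
        assert np.abs(out.series[0]).max() < 1e-6 * 10.0

    def test_constant_maps_to_zero(self):
        out = highpass_detrend(_run_from(np.full(100, 7.0)), self.CUTOFF)
        np.testing.assert_allclose(out.series[0], 0.0, atol=1e-10)

    def test_fast_sinusoid_passes(self):
        t = np.arange(200) * 0.72
        sig = np.sin(2 * np.pi * 0.2 * t)
        out = highpass_detrend(_run_from(sig), self.CUTOFF)
        assert np.corrcoef(out.series[0], sig)[0, 1] > 0.99
        # independent oracle: lstsq projection onto the same drift span
        L = 200
        m = np.arange(1, 4)
        X = np.column_stack(
            [np.ones(L), np.arange(L)]
            + [np.cos(np.pi * k * (np.arange(L) + 0.5) / L) for k in m]
        )
        beta, *_ = np.linalg.lstsq(X, sig, rcond=None)
        np.testing.assert_allclose(out.series[0], sig - X @ beta, atol=1e-8)

    def test_projection_is_idempotent(self, rng):
        series = rng.normal(size=(3, 120))
        run = BoldRun(space=full_space((3, 1, 1)), series=series, tr_seconds=0.72)
        once = highpass_detrend(run, self.CUTOFF)
        twice = highpass_detrend(once, self.CUTOFF)
        np.testing.assert_allclose(twice.series, once.series, atol=1e-10)

    def test_output_zero_mean(self, rng):
        run = _run_from(rng.normal(size=150) + 5.0)
        out = highpass_detrend(run, self.CUTOFF)
        np.testing.assert_allclose(out.series.mean(axis=1), 0.0, atol=1e-10)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass_detrend(_run_from(np.arange(50.0), tr=1.0), 0.5)


class TestOnsetTable:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            OnsetTable(conditions=("A", "B"), onsets=(0, 8), lengths=(16, 16))

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError, match="equal trial counts"):
            OnsetTable(conditions=("A", "A", "B"), onsets=(0, 16, 32), lengths=(16,) * 3)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="one length"):
            OnsetTable(conditions=("A", "B"), onsets=(0, 16), lengths=(16, 8))

    def test_tsv_round_trip(self, tmp_path):
        table = OnsetTable(
            conditions=("A", "B", "A", "B"), onsets=(0, 16, 32, 48), lengths=(16,) * 4
        )
        path = tmp_path / "onsets.tsv"
        table.to_tsv(path)
        again = OnsetTable.from_tsv(path)
        assert again == table


class TestExtractTrials:
    def test_slices_match(self, rng):
        space = full_space((3, 1, 1))
        series = rng.normal(size=(3, 32))
        run = BoldRun(space=space, series=series, tr_seconds=1.0)
        table = OnsetTable(
            conditions=("A", "A", "B", "B"), onsets=(0, 16, 8, 24), lengths=(8,) * 4
        )
        trials = extract_trials(run, table, "A")
        assert trials.values.shape == (3, 2, 8)
        np.testing.assert_array_equal(trials.values[:, 0, :], series[:, 0:8])
        np.testing.assert_array_equal(trials.values[:, 1, :], series[:, 16:24])

    def test_out_of_range_onset(self, rng):
        run = BoldRun(
            space=full_space((2, 1, 1)), series=rng.normal(size=(2, 32)), tr_seconds=1.0
        )
        table = OnsetTable(conditions=("A", "B"), onsets=(20, 0), lengths=(16, 16))
        with pytest.raises(ValueError, match="exceeds run length"):
            extract_trials(run, table, "A")

    def test_absent_condition(self, rng):
        run = BoldRun(
            space=full_space((2, 1, 1)), series=rng.normal(size=(2, 32)), tr_seconds=1.0
        )
        table = OnsetTable(conditions=("A", "B"), onsets=(0, 16), lengths=(16, 16))
        with pytest.raises(ValueError, match="absent"):
            extract_trials(run, table, "C")

    def test_no_volume_reused_and_shape_exact(self, rng):
        run = BoldRun(
            space=full_space((2, 1, 1)), series=rng.normal(size=(2, 64)), tr_seconds=1.0
        )
        table = OnsetTable(
            conditions=("A", "B") * 2, onsets=(0, 16, 32, 48), lengths=(16,) * 4
        )
        used = []
        for cond in ("A", "B"):
            trials = extract_trials(run, table, cond)
            assert trials.values.shape == (2, 2, 16)
            for o in table.onsets_for(cond):
                used.extend(range(o, o + 16))
        assert len(used) == len(set(used)) == 64


def _trials(values) -> TrialArray:
    values = np.asarray(values, dtype=float)
    space = full_space((values.shape[0] + 1, 1, 1))
    padded = np.concatenate([values, np.linspace(0, 1, values.shape[1] * values.shape[2]).reshape(1, *values.shape[1:])])
    return TrialArray(space=space, condition="A", values=padded)


class TestNormalizeTrials:
    def test_worked_example(self):
        out = normalize_trials(_trials([[[1.0, 2.0, 3.0], [4.0, 6.0, 8.0]]]))
        np.testing.assert_allclose(out.values[0, 0], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(out.values[0, 1], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        once = normalize_trials(_trials(rng.normal(size=(2, 3, 8))))
        twice = normalize_trials(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_zero_variance_reported(self):
        with pytest.raises(ValueError, match=r"\(voxel, trial\)"):
            normalize_trials(_trials([[[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]]))

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(min_value=0.1, max_value=100.0),
        shift=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_scale_shift_invariance(self, scale, shift):
        base = np.random.default_rng(7).normal(size=(2, 2, 6))
        a = normalize_trials(_trials(base))
        b = normalize_trials(_trials(scale * base + shift))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_moments(self, rng):
        out = normalize_trials(_trials(rng.normal(2.0, 3.0, size=(3, 4, 10)))).values
        np.testing.assert_allclose(out.mean(axis=2), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=2, ddof=1), 1.0, atol=1e-12)
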
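import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taskdecode.preproc import (
    BrainMask,
    VoxelSignalMatrix,
    concat_tasks,
    extract_masked_signals,
    load_mask,
    map_to_volume,
    normalize_voxels,
    read_design_tsv,
    save_mask,
    subsample_voxels,
    truncate_to_common_length,
    write_design_tsv,
)
from taskdecode.synth import make_block_design


def make_mask(dims, n_true, seed=0):
    rng = np.random.default_rng(seed)
    flat = np.zeros(int(np.prod(dims)), dtype=bool)
    flat[rng.permutation(flat.size)[:n_true]] = True
    return BrainMask(flat.reshape(dims))


class TestExtractAndMap:
    def test_shape_contract(self):
        mask = make_mask((3, 3, 3), 3)
        vol = np.zeros((3, 3, 3, 5))
        m = extract_masked_signals(vol, mask)
        assert m.data.shape == (5, 3)

    def test_empty_mask_raises(self):
        mask = BrainMask(np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(ValueError, match="no inside voxels"):
            extract_masked_signals(np.zeros((2, 2, 2, 4)), mask)

    def test_dimension_mismatch_raises(self):
        mask = make_mask((3, 3, 3), 3)
        with pytest.raises(ValueError):
            extract_masked_signals(np.zeros((4, 3, 3, 5)), mask)

    def test_known_voxel_series(self):
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool))
        vol = np.zeros((3, 3, 3, 5))
        vol[1, 1, 1, :] = [1, 2, 3, 4, 5]
        m = extract_masked_signals(vol, mask)
        # F-order linearization: (1,1,1) -> 1 + 3*1 + 9*1 = 13
        np.testing.assert_array_equal(m.data[:, 13], [1, 2, 3, 4, 5])

    def test_one_hot_maps_to_single_voxel(self):
        mask = make_mask((4, 3, 2), 7, seed=1)
        vec = np.zeros(7)
        vec[4] = 2.5
        vol = map_to_volume(vec, mask)
        assert (vol != 0).sum() == 1
        coord = mask.coordinates()[4]
        assert vol[tuple(coord)] == 2.5

    def test_zero_vector_zero_volume(self):
        mask = make_mask((3, 3, 3), 5)
        assert np.all(map_to_volume(np.zeros(5), mask) == 0)

    def test_length_mismatch_raises(self):
        mask = make_mask((3, 3, 3), 5)
        with pytest.raises(ValueError):
            map_to_volume(np.zeros(6), mask)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_round_trip_exact(self, seed):
        rng = np.random.default_rng(seed)
        mask = make_mask((4, 4, 3), 10, seed=seed)
        vec = rng.standard_normal(10)
        vol = map_to_volume(vec, mask)
        series = extract_masked_signals(vol[..., None], mask).data[0]
        np.testing.assert_array_equal(series, vec)


class TestTruncate:
    def test_paper_frame_counts_truncate_to_176(self):
        counts = (176, 253, 232, 284, 316, 274, 405)
        mats = {
            f"t{i}": VoxelSignalMatrix(np.random.default_rng(i).normal(size=(c, 4)))
            for i, c in enumerate(counts)
        }
        out = truncate_to_common_length(mats)
        assert all(m.t == 176 for m in out.values())

    def test_single_task_unchanged(self):
        m = VoxelSignalMatrix(np.arange(20.0).reshape(10, 2))
        out = truncate_to_common_length({"a": m})
        np.testing.assert_array_equal(out["a"].data, m.data)

    def test_leading_frames_kept(self):
        a = VoxelSignalMatrix(np.arange(10.0)[:, None])
        b = VoxelSignalMatrix(np.arange(8.0)[:, None])
        out = truncate_to_common_length({"a": a, "b": b})
        assert out["a"].t == out["b"].t == 8
        np.testing.assert_array_equal(out["a"].data[:, 0], np.arange(8.0))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            truncate_to_common_length({})


class TestNormalize:
    def test_hand_arithmetic(self):
        m = normalize_voxels(VoxelSignalMatrix(np.array([[1.0], [2.0], [3.0]])))
        np.testing.assert_allclose(
            m.data[:, 0], [-0.70710678, 0.0, 0.70710678], atol=1e-8
        )

    def test_constant_column_flagged_excluded(self):
        m = normalize_voxels(
            VoxelSignalMatrix(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 4.0]]))
        )
        assert m.excluded == (0,)
        assert np.all(m.data[:, 0] == 0)

    def test_idempotent(self, rng):
        m = normalize_voxels(VoxelSignalMatrix(rng.normal(size=(12, 6))))
        m2 = normalize_voxels(m)
        np.testing.assert_allclose(m2.data, m.data, atol=1e-12)

    def test_invariant_zero_mean_unit_norm(self, rng):
        m = normalize_voxels(VoxelSignalMatrix(rng.normal(size=(30, 40))))
        assert np.abs(m.data.mean(axis=0)).max() < 1e-8
        assert np.abs(np.linalg.norm(m.data, axis=0) - 1).max() < 1e-8
        assert m.normalized

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError):
            normalize_voxels(VoxelSignalMatrix(np.ones((1, 3))))


class TestConcat:
    def _mats(self, rng, tasks, t=6, n=4):
        return {
            task: VoxelSignalMatrix(rng.normal(size=(t, n)), task_id=task, subject_id="s")
            for task in tasks
        }

    def test_shape_and_label_blocks(self, rng):
        mats = self._mats(rng, ["a", "b"])
        m = concat_tasks(mats, ["a", "b"])
        assert m.data.shape == (6, 8)
        assert list(m.col_task[:4]) == ["a"] * 4
        np.testing.assert_array_equal(m.data[:, :4], mats["a"].data)

    def test_reversed_order_swaps_blocks(self, rng):
        mats = self._mats(rng, ["a", "b"])
        fwd = concat_tasks(mats, ["a", "b"])
        rev = concat_tasks(mats, ["b", "a"])
        np.testing.assert_array_equal(rev.data[:, :4], fwd.data[:, 4:])

    def test_seven_tasks(self, rng):
        tasks = [f"t{i}" for i in range(7)]
        m = concat_tasks(self._mats(rng, tasks, n=5), tasks)
        assert m.data.shape == (6, 35)

    def test_content_preserved_bit_exact(self, rng):
        mats = self._mats(rng, ["a", "b", "c"])
        m = concat_tasks(mats, ["a", "b", "c"])
        for i, task in enumerate(["a", "b", "c"]):
            np.testing.assert_array_equal(
                m.data[:, 4 * i : 4 * (i + 1)], mats[task].data
            )

    def test_frame_mismatch_raises(self, rng):
        mats = {
            "a": VoxelSignalMatrix(rng.normal(size=(6, 4))),
            "b": VoxelSignalMatrix(rng.normal(size=(5, 4))),
        }
        with pytest.raises(ValueError):
            concat_tasks(mats, ["a", "b"])


class TestSubsample:
    def test_count(self, rng):
        m = VoxelSignalMatrix(rng.normal(size=(5, 1000)))
        idx, sub = subsample_voxels(m, 0.1, seed=0)
        assert len(idx) == 100 == sub.n
        assert len(set(idx.tolist())) == 100

    def test_fraction_one_identity(self, rng):
        m = VoxelSignalMatrix(rng.normal(size=(5, 20)))
        idx, sub = subsample_voxels(m, 1.0, seed=0)
        np.testing.assert_array_equal(idx, np.arange(20))
        np.testing.assert_array_equal(sub.data, m.data)

    def test_seed_determinism(self, rng):
        m = VoxelSignalMatrix(rng.normal(size=(5, 200)))
        idx1, _ = subsample_voxels(m, 0.25, seed=42)
        idx2, _ = subsample_voxels(m, 0.25, seed=42)
        np.testing.assert_array_equal(idx1, idx2)

    def test_fraction_out_of_range_raises(self, rng):
        m = VoxelSignalMatrix(rng.normal(size=(5, 20)))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                subsample_voxels(m, bad, seed=0)

    def test_uniformity_monte_carlo(self):
        # 200 seeded draws of 10% from 1000 voxels; per-voxel selection counts
        # must lie in a wide binomial band around p = 0.1
        from scipy.stats import binom

        m = VoxelSignalMatrix(np.zeros((2, 1000)))
        counts = np.zeros(1000)
        n_draws = 200
        for seed in range(n_draws):
            idx, _ = subsample_voxels(m, 0.1, seed=seed)
            counts[idx] += 1
        lo = binom.ppf(5e-5, n_draws, 0.1)
        hi = binom.ppf(1 - 5e-5, n_draws, 0.1)
        assert counts.min() >= lo
        assert counts.max() <= hi


def test_mask_nifti_round_trip(tmp_path):
    mask = make_mask((5, 4, 3), 17, seed=3)
    save_mask(tmp_path / "m.nii.gz", mask)
    back = load_mask(tmp_path / "m.nii.gz")
    np.testing.assert_array_equal(back.inside, mask.inside)


def test_design_tsv_round_trip(tmp_path):
    d = make_block_design("t", 1.0, 60, [(5, 10, "a"), (30, 10, "b")])
    write_design_tsv(tmp_path / "d.tsv", d)
    back = read_design_tsv(tmp_path / "d.tsv", "t", 1.0, 60)
    assert back.blocks == d.blocks
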
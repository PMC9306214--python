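"""Distance transform, marker construction and the priority-flood watershed,
each checked against an independent brute-force oracle."""

import numpy as np
import pytest

from conftest import ball_mask, random_blob_mask
from nucleiws.volume_core import BinaryMask, LabelVolume
from nucleiws.watershed import (MarkerVolume, WatershedConfig, cc_markers,
                                distance_transform, hminima_markers,
                                remove_small_objects, run_method,
                                ws_from_markers)
from oracles import (dt_bruteforce, flood_bruteforce,
                     hmaxima_markers_bruteforce, label_components)


def as_mask(arr, z_aniso=1.0):
    return BinaryMask(arr, "M3D", (1.0, 1.0, z_aniso), space="expanded")


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Same label partition up to renaming."""
    if not np.array_equal(a > 0, b > 0):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return (len(pairs) == len({p[0] for p in pairs})
            and len(pairs) == len({p[1] for p in pairs}))


class TestDistanceTransform:
    def test_isolated_voxel_is_one(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        dt = distance_transform(as_mask(m))
        assert dt[2, 2, 2] == pytest.approx(1.0)
        assert dt.sum() == pytest.approx(1.0)

    def test_single_voxel_column_is_all_ones(self):
        m = np.zeros((7, 3, 3), bool)
        m[:, 1, 1] = True
        dt = distance_transform(as_mask(m, z_aniso=1.0))
        np.testing.assert_allclose(dt[:, 1, 1], 1.0)

    def test_ball_max_at_center(self):
        m = ball_mask((13, 13, 13), (6, 6, 6), 5)
        dt = distance_transform(as_mask(m))
        assert 5.0 <= dt.max() <= 6.0
        assert dt[6, 6, 6] == dt.max()

    def test_anisotropic_sampling_enters_distances(self):
        m = np.zeros((5, 9, 9), bool)
        m[2, 4, 4] = True
        m[1, 4, 4] = True
        m[3, 4, 4] = True
        dt = distance_transform(as_mask(m, z_aniso=3.0))
        # center voxel: nearest background is 1 xy step away, not z
        assert dt[2, 4, 4] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 13, 3))
        m = random_blob_mask(rng, shape)
        z_aniso = float(rng.choice([1.0, 3.0]))
        got = distance_transform(as_mask(m, z_aniso))
        want = dt_bruteforce(m, z_aniso)
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestMarkers:
    def test_cc_two_cubes_two_markers(self):
        m = np.zeros((6, 12, 6), bool)
        m[1:4, 1:4, 1:4] = True
        m[1:4, 7:10, 1:4] = True
        assert cc_markers(as_mask(m)).n_markers == 2

    def test_cc_diagonal_touch_is_one_marker_under_26(self):
        m = np.zeros((4, 4, 4), bool)
        m[1, 1, 1] = True
        m[2, 2, 2] = True
        assert cc_markers(as_mask(m)).n_markers == 1
        assert cc_markers(as_mask(m), connectivity=6).n_markers == 2

    def test_cc_empty(self):
        assert cc_markers(as_mask(np.zeros((3, 3, 3), bool))).n_markers == 0

    def test_two_ball_markers_split_and_merge_with_h(self, two_ball_mask):
        assert hminima_markers(two_ball_mask, 1.0).n_markers == 2
        assert hminima_markers(two_ball_mask, 4.0).n_markers == 1

    def test_thin_slab_plateau_single_marker(self):
        m = np.zeros((5, 9, 9), bool)
        m[2, 1:8, 1:8] = True     # one voxel thick: DT constant 1 on the slab
        for h in (0.5, 1.0, 3.0):
            assert hminima_markers(as_mask(m), h).n_markers == 1

    def test_empty_mask_no_markers(self):
        assert hminima_markers(as_mask(np.zeros((4, 4, 4), bool)), 1.0).n_markers == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_reconstruction_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        shape = tuple(rng.integers(6, 13, 3))
        m = random_blob_mask(rng, shape)
        h = float(rng.choice([0.5, 1.0, 1.5, 2.0]))
        got = hminima_markers(as_mask(m), h).labels
        want = hmaxima_markers_bruteforce(m, h)
        assert partitions_equal(got, want)

    def test_marker_count_non_increasing_in_h(self):
        rng = np.random.default_rng(1234)
        grid = [0.5, 1.0, 1.5, 2.0, 3.0]
        for _ in range(200):
            m = random_blob_mask(rng, tuple(rng.integers(8, 15, 3)))
            mask = as_mask(m)
            dt = distance_transform(mask)
            counts = [hminima_markers(mask, h, dt=dt).n_markers for h in grid]
            assert all(a >= b for a, b in zip(counts, counts[1:])), counts


class TestFlood:
    def test_two_balls_split_near_neck(self, two_ball_mask):
        m = two_ball_mask.voxels
        markers = np.zeros(m.shape, np.int32)
        markers[11, 10, 11] = 1
        markers[11, 19, 11] = 2
        lv = ws_from_markers(two_ball_mask, MarkerVolume(markers, 2))
        assert lv.n_objects == 2
        assert np.array_equal(lv.labels > 0, m)
        # the split surface lies within one voxel of the mid plane y=14.5
        y_of_1 = np.nonzero(lv.labels == 1)[1]
        y_of_2 = np.nonzero(lv.labels == 2)[1]
        assert y_of_1.max() <= 15 and y_of_2.min() >= 14

    def test_single_marker_floods_whole_mask(self, two_ball_mask):
        markers = np.zeros(two_ball_mask.shape, np.int32)
        markers[11, 10, 11] = 1
        lv = ws_from_markers(two_ball_mask, MarkerVolume(markers, 1))
        assert lv.n_objects == 1
        assert np.array_equal(lv.labels > 0, two_ball_mask.voxels)

    def test_markers_equal_mask_is_identity_footprint(self, two_ball_mask):
        markers = two_ball_mask.voxels.astype(np.int32)
        lv = ws_from_markers(two_ball_mask, MarkerVolume(markers, 1))
        assert lv.n_objects == 1
        assert np.array_equal(lv.labels > 0, two_ball_mask.voxels)

    def test_markers_outside_mask_warn_and_drop(self):
        m = np.zeros((4, 6, 6), bool)
        m[1:3, 1:3, 1:3] = True
        markers = np.zeros(m.shape, np.int32)
        markers[1, 1, 1] = 1
        markers[3, 5, 5] = 2  # outside
        with pytest.warns(UserWarning, match="outside"):
            lv = ws_from_markers(as_mask(m), MarkerVolume(markers, 2))
        assert lv.n_objects == 1

    def test_no_markers_returns_empty_with_warning(self):
        m = np.ones((3, 3, 3), bool)
        with pytest.warns(UserWarning, match="no markers"):
            lv = ws_from_markers(as_mask(m), MarkerVolume(np.zeros(m.shape, np.int32), 0))
        assert lv.n_objects == 0

    def test_each_marker_contained_in_its_region(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = random_blob_mask(rng, (10, 10, 10))
            mask = as_mask(m)
            mk = hminima_markers(mask, 1.0)
            if mk.n_markers == 0:
                continue
            lv = ws_from_markers(mask, mk)
            for lab in range(1, mk.n_markers + 1):
                region_of = np.unique(lv.labels[mk.labels == lab])
                assert region_of.size == 1 and region_of[0] > 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_priority_flood_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        shape = tuple(rng.integers(6, 13, 3))
        m = random_blob_mask(rng, shape)
        if not m.any():
            return
        mask = as_mask(m)
        dt = distance_transform(mask)
        mk = hminima_markers(mask, 1.0, dt=dt)
        if mk.n_markers == 0:
            return
        got = ws_from_markers(mask, mk, dt=dt).labels
        want = flood_bruteforce(-dt, m, mk.labels)
        # identical tie policy on both routes -> exact agreement
        np.testing.assert_array_equal(got, want)


class TestMethods:
    def test_method_a_splits_with_seed_components(self, two_ball_mask):
        seeds = np.zeros(two_ball_mask.shape, bool)
        seeds[10:13, 9:12, 10:13] = True
        seeds[10:13, 18:21, 10:13] = True
        sb = BinaryMask(seeds, "seeds", two_ball_mask.spacing, space="expanded")
        lv = run_method(two_ball_mask, sb, WatershedConfig(method="A"))
        assert lv.n_objects == 2

    def test_method_b_single_ball_one_nucleus(self):
        m = ball_mask((13, 13, 13), (6, 6, 6), 5)
        for h in (1.0, 2.0, 5.0):
            lv = run_method(as_mask(m), None, WatershedConfig(method="B", h=h))
            assert lv.n_objects == 1

    def test_method_c_splits_touching_seeds_where_a_cannot(self):
        # two touching seed balls: one CC component but two DT domes
        shape = (17, 28, 17)
        seeds = ball_mask(shape, (8, 9, 8), 5) | ball_mask(shape, (8, 18, 8), 5)
        mask = ball_mask(shape, (8, 9, 8), 7) | ball_mask(shape, (8, 18, 8), 7)
        mb = as_mask(mask)
        sb = BinaryMask(seeds, "seeds", mb.spacing, space="expanded")
        a = run_method(mb, sb, WatershedConfig(method="A"))
        c = run_method(mb, sb, WatershedConfig(method="C", h=1.0))
        assert a.n_objects == 1
        assert c.n_objects == 2

    def test_methods_a_and_c_agree_on_disjoint_round_seeds(self, two_ball_mask):
        seeds = ball_mask(two_ball_mask.shape, (11, 10, 11), 3) \
            | ball_mask(two_ball_mask.shape, (11, 19, 11), 3)
        sb = BinaryMask(seeds, "seeds", two_ball_mask.spacing, space="expanded")
        a = run_method(two_ball_mask, sb, WatershedConfig(method="A"))
        c = run_method(two_ball_mask, sb, WatershedConfig(method="C", h=1.0))
        assert partitions_equal(a.labels, c.labels)

    def test_method_argument_validation(self, two_ball_mask):
        sb = BinaryMask(np.ones(two_ball_mask.shape, bool), "seeds",
                        two_ball_mask.spacing, space="expanded")
        with pytest.raises(ValueError, match="requires seeds"):
            run_method(two_ball_mask, None, WatershedConfig(method="A"))
        with pytest.raises(ValueError, match="no seeds"):
            run_method(two_ball_mask, sb, WatershedConfig(method="B", h=1.0))


class TestSmallObjectFilter:
    def _volumes(self, sizes):
        lab = np.zeros((2, 4, sum(sizes) + len(sizes)), np.int32)
        x = 0
        for i, s in enumerate(sizes, 1):
            lab[0, 0, x:x + s] = i
            x += s + 1
        return LabelVolume(lab, (1, 1, 1), space="expanded", expansion_factor=1)

    def test_removes_at_most_five_percent_of_mean(self):
        lv = remove_small_objects(self._volumes([100, 100, 3]), 0.05)
        assert lv.n_objects == 2

    def test_keeps_just_above_cutoff(self):
        lv = remove_small_objects(self._volumes([100, 100, 4]), 0.05)
        assert lv.n_objects == 3

    def test_single_object_always_kept(self):
        lv = remove_small_objects(self._volumes([7]), 0.05)
        assert lv.n_objects == 1

    def test_labels_recompacted(self):
        lv = remove_small_objects(self._volumes([3, 100, 100]), 0.05)
        assert sorted(np.unique(lv.labels).tolist()) == [0, 1, 2]
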
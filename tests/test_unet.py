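"""U-Net architecture constants, patch tiling, weight maps, training schedule
and the prediction thresholds."""

import numpy as np
import pytest

from nucleiws.preprocessing import expand_stack
from nucleiws.synth import SimConfig, generate_spheroid
from nucleiws.targets import interpolate_ground_truth, make_m3d
from nucleiws.unet import (TrainConfig, UNetMasker, build_network, build_unet,
                           extract_patches, load_model, lr_at_epoch,
                           make_weight_map, predict_masks, save_model,
                           train_model)
from nucleiws.unet.masking import infer_offsets, train_offsets
from nucleiws.volume_core import BinaryMask, LabelVolume, VolumeStack


class TestArchitecture:
    def test_2d_parameter_count_is_3p3_million(self):
        spec = build_unet("2D")
        assert round(spec.param_count / 1e6, 1) == 3.3

    def test_3d_parameter_count_is_3p2_million(self):
        spec = build_unet("3D")
        assert round(spec.param_count / 1e6, 1) == 3.2

    def test_2d_and_3d_counts_within_five_percent(self):
        p2 = build_unet("2D").param_count
        p3 = build_unet("3D").param_count
        assert abs(p2 - p3) / max(p2, p3) < 0.05

    def test_filter_rules(self):
        s2, s3 = build_unet("2D"), build_unet("3D")
        assert s2.encoder_filters == [28, 56, 84, 112, 140]
        assert s2.decoder_filters == [112, 84, 56, 28]
        assert s3.encoder_filters == [16, 32, 48, 64, 80]
        assert s3.decoder_filters == [64, 48, 32, 16]
        assert s3.pool_factors == (2, 2, 1) and s2.pool_factors == (2, 2)

    def test_spec_param_count_matches_instantiated_network(self):
        for variant in ("2D", "3D"):
            assert build_unet(variant).param_count \
                == build_network(variant).n_parameters()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_unet("4D")

    def test_output_shape_matches_input_with_one_channel(self):
        net = build_network("3D")
        x = np.random.default_rng(0).random((1, 8, 32, 32, 1)).astype(np.float32)
        assert net.forward(x).shape == (1, 8, 32, 32, 1)


class TestTiling:
    @pytest.mark.parametrize("Z,want", [(30, [0, 6]), (48, [0, 24]),
                                        (24, [0]), (20, [0]), (50, [0, 24, 26])])
    def test_infer_offsets_shift_final_tile_back(self, Z, want):
        assert infer_offsets(Z, 24) == want

    @pytest.mark.parametrize("Z,want", [(24, [0]), (30, [0, 12]),
                                        (36, [0, 12]), (37, [0, 12, 24])])
    def test_train_offsets_stride_12_with_boundary_fill(self, Z, want):
        assert train_offsets(Z, 24) == want

    def test_patches_are_minmax_normalised(self):
        rng = np.random.default_rng(1)
        vs = VolumeStack(rng.uniform(50, 200, (24, 32, 32)).astype(np.float32),
                         (1, 1, 1), space="expanded", expansion_factor=1)
        patches, _ = extract_patches(vs, "3D", "infer", 24)
        assert patches.min() == pytest.approx(0.0)
        assert patches.max() == pytest.approx(1.0)

    def test_constant_patch_maps_to_zero(self):
        vs = VolumeStack(np.full((4, 32, 32), 9.0, np.float32), (1, 1, 1),
                         space="expanded", expansion_factor=1)
        patches, _ = extract_patches(vs, "2D", "infer")
        assert not patches.any()

    def test_2d_mode_yields_one_patch_per_slice(self):
        rng = np.random.default_rng(2)
        vs = VolumeStack(rng.random((7, 32, 32)).astype(np.float32),
                         (1, 1, 1), space="expanded", expansion_factor=1)
        patches, offs = extract_patches(vs, "2D", "train")
        assert patches.shape == (7, 32, 32) and offs == list(range(7))

    def test_inference_tiling_covers_every_voxel(self):
        for Z in (20, 24, 30, 50, 49):
            offs = infer_offsets(Z, 24)
            covered = np.zeros(Z, bool)
            for o in offs:
                covered[o:o + 24] = True
            assert covered.all(), (Z, offs)

    def test_non_multiple_of_16_rejected(self):
        vs = VolumeStack(np.zeros((4, 30, 30), np.float32), (1, 1, 1),
                         space="expanded", expansion_factor=1)
        with pytest.raises(ValueError, match="divisible by 16"):
            extract_patches(vs, "2D")


class TestWeightMap:
    def _gt(self, arr):
        return LabelVolume(np.asarray(arr, np.int32), (1, 1, 1),
                           space="expanded", expansion_factor=1)

    def test_single_nucleus_only_class_weights(self):
        arr = np.zeros((4, 8, 8), np.int32)
        arr[1:3, 2:6, 2:6] = 1
        w = make_weight_map(self._gt(arr))
        assert set(np.unique(w)) == {1.0, 3.0}
        assert np.all(w[arr > 0] == 3.0)

    def test_gap_voxel_between_two_nuclei(self):
        arr = np.zeros((1, 1, 5), np.int32)
        arr[0, 0, 0:2] = 1
        arr[0, 0, 3:5] = 2
        w = make_weight_map(self._gt(arr), w0=10.0, sigma=5.0)
        # the voxel at x=2 is adjacent to both nuclei: d1 = d2 = 1
        want = 1.0 + 10.0 * np.exp(-4.0 / 50.0)
        assert w[0, 0, 2] == pytest.approx(want, rel=1e-6)

    def test_far_field_weight_approaches_one(self):
        arr = np.zeros((1, 4, 64), np.int32)
        arr[0, :, 0] = 1
        arr[0, :, 1] = 2
        w = make_weight_map(self._gt(arr))
        assert w[0, 2, 63] == pytest.approx(1.0, abs=1e-6)


class TestTraining:
    def test_learning_rate_schedule_checkpoints(self):
        assert lr_at_epoch(1) == 1e-3
        assert lr_at_epoch(75) == 1e-3
        assert lr_at_epoch(76) == 2e-4
        assert lr_at_epoch(110) == 2e-4
        assert lr_at_epoch(111) == 1e-4
        assert lr_at_epoch(200) == 1e-4

    def test_training_loss_decreases_on_tiny_volumes(self):
        rng = np.random.default_rng(3)
        data = []
        for seed in (21, 22):
            vs, gt = generate_spheroid(SimConfig(
                n_nuclei=2, radius_range=(4.0, 5.0), volume_shape=(4, 32, 32),
                clumping=0.0, rng_seed=seed))
            vsx = expand_stack(vs, 3)
            target = make_m3d(interpolate_ground_truth(gt, 3))
            data.append((vsx, target.voxels.astype(np.float32)))
        cfg = TrainConfig(epochs=5, batch_size=2, rotation_fraction=0.0,
                          mirror_fraction=0.0, seed=0)
        _, hist = train_model("3D", data, data[0], cfg, patch_depth=12)
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_model("3D", [], None, TrainConfig(epochs=1))

    def test_shape_mismatch_rejected(self):
        vs = VolumeStack(np.zeros((12, 32, 32), np.float32), (1, 1, 1),
                         space="expanded", expansion_factor=1)
        with pytest.raises(ValueError, match="mismatch"):
            train_model("3D", [(vs, np.zeros((10, 32, 32), np.float32))],
                        (vs, np.zeros((12, 32, 32), np.float32)),
                        TrainConfig(epochs=1), patch_depth=12)


class _StubMasker:
    """Fixed-probability predictor standing in for a trained U-Net."""

    def __init__(self, prob, target_kind="M3D"):
        self._prob = np.asarray(prob, dtype=np.float32)
        self.target_kind = target_kind

    def predict_proba(self, vs):
        return self._prob


class TestPredictionThresholds:
    def _vs(self, shape=(2, 2, 2)):
        return VolumeStack(np.zeros(shape, np.float32), (1, 1, 1),
                           space="expanded", expansion_factor=1)

    def test_mask_threshold_ties_are_foreground(self):
        prob = np.full((2, 2, 2), 0.5, np.float32)
        mask, _ = predict_masks(self._vs(), _StubMasker(prob))
        assert mask.voxels.all()

    def test_seed_probability_is_multiplied_before_thresholding(self):
        mask_p = np.zeros((1, 2, 2), np.float32)
        seed_p = np.zeros((1, 2, 2), np.float32)
        mask_p[0, 0, 0], seed_p[0, 0, 0] = 0.0, 0.9   # 0.0 -> no seed
        mask_p[0, 0, 1], seed_p[0, 0, 1] = 0.6, 0.6   # 0.36 >= 0.3 -> seed
        mask_p[0, 1, 0], seed_p[0, 1, 0] = 0.6, 0.4   # 0.24 < 0.3 -> no seed
        mask, seeds = predict_masks(self._vs((1, 2, 2)), _StubMasker(mask_p),
                                    _StubMasker(seed_p, "seeds"))
        assert not seeds.voxels[0, 0, 0]
        assert seeds.voxels[0, 0, 1]
        assert not seeds.voxels[0, 1, 0]

    def test_seeds_are_subset_of_mask(self):
        rng = np.random.default_rng(4)
        mask_p = rng.random((2, 4, 4)).astype(np.float32)
        seed_p = rng.random((2, 4, 4)).astype(np.float32)
        mask, seeds = predict_masks(self._vs((2, 4, 4)), _StubMasker(mask_p),
                                    _StubMasker(seed_p, "seeds"))
        assert np.all(~seeds.voxels | mask.voxels)


class TestInference:
    @pytest.fixture(scope="class")
    def net_and_volume(self):
        rng = np.random.default_rng(5)
        net = build_network("2D", seed=9)
        vs = VolumeStack(rng.random((5, 32, 32)).astype(np.float32),
                         (1, 1, 1), space="expanded", expansion_factor=1)
        return net, vs

    def test_prediction_is_deterministic(self, net_and_volume):
        from nucleiws.unet.masking import predict_proba_volume
        net, vs = net_and_volume
        a = predict_proba_volume(net, vs, "2D")
        b = predict_proba_volume(net, vs, "2D")
        np.testing.assert_array_equal(a, b)

    def test_2d_variant_has_no_cross_slice_leakage(self, net_and_volume):
        from nucleiws.unet.masking import predict_proba_volume
        net, vs = net_and_volume
        full = predict_proba_volume(net, vs, "2D")
        for z in range(vs.shape[0]):
            single = VolumeStack(vs.voxels[z:z + 1], (1, 1, 1),
                                 space="expanded", expansion_factor=1)
            np.testing.assert_allclose(
                predict_proba_volume(net, single, "2D")[0], full[z],
                atol=1e-6)

    def test_model_round_trip_through_disk(self, tmp_path):
        rng = np.random.default_rng(6)
        m = UNetMasker(variant="2D", target_kind="M3DE", epochs=1)
        m.net_ = build_network("2D", seed=1)
        m.spec_ = build_unet("2D", "M3DE")
        save_model(m, tmp_path / "model")
        back = load_model(tmp_path / "model")
        vs = VolumeStack(rng.random((2, 32, 32)).astype(np.float32),
                         (1, 1, 1), space="expanded", expansion_factor=1)
        np.testing.assert_array_equal(back.predict_proba(vs),
                                      m.predict_proba(vs))
        assert back.target_kind == "M3DE"

    def test_sklearn_get_set_params(self):
        m = UNetMasker(variant="2D", epochs=7)
        params = m.get_params()
        assert params["epochs"] == 7
        m.set_params(epochs=9, target_kind="seeds")
        assert m.epochs == 9 and m.target_kind == "seeds"
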
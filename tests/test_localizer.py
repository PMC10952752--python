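"""Generalized Dice loss, network architecture, prediction and the
intensity-based segmenter."""

import numpy as np
import pytest

from fetaltrack import (
    BinaryMask,
    GridGeometry,
    LabelMap,
    NetworkSpec,
    ProbabilityMap,
    Trajectory,
    VolumeGrid,
    analytic_target_mask,
    build_localizer_network,
    generalized_dice_loss,
    load_checkpoint,
    make_fetal_world,
    make_sphere_world,
    predict_mask,
    save_checkpoint,
    segment_intensity,
)
from fetaltrack.localizer import (
    TrainConfig,
    class_weights,
    gdl_value_and_grad,
    softmax_channels,
    train_localizer,
)
from fetaltrack.phantom import AcquisitionConfig, acquire_repetition
from fetaltrack.synth import make_training_scenes

from conftest import brute_force_gdl




def _maps(probs, onehot, spacing=1.0):
    g = GridGeometry(probs.shape[1:], spacing)
    return ProbabilityMap(g, probs), LabelMap(g, onehot)


class TestGeneralizedDiceLoss:
    def test_perfect_prediction_is_zero(self):
        rng = np.random.default_rng(0)
        onehot_fg = (rng.random((4, 4, 4)) > 0.5).astype(np.float32)
        onehot = np.stack([1 - onehot_fg, onehot_fg])
        pred, target = _maps(onehot.copy(), onehot)
        assert generalized_dice_loss(pred, target) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_eight_voxel_case(self):
        # 2x2x2 grid, 2 foreground voxels, all-background prediction:
        # w_bg = 1/36, w_fg = 1/4, numerator 1/3, denominator 8/9 -> 0.625
        fg = np.zeros((2, 2, 2), np.float32)
        fg[0, 0, 0] = fg[1, 1, 1] = 1.0
        onehot = np.stack([1 - fg, fg])
        probs = np.stack([np.ones_like(fg), np.zeros_like(fg)])
        pred, target = _maps(probs, onehot)
        assert generalized_dice_loss(pred, target) == pytest.approx(0.625, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            shape = tuple(rng.integers(1, 7, size=3))
            fg = (rng.random(shape) > rng.random()).astype(np.float32)
            onehot = np.stack([1 - fg, fg])
            raw = rng.random((2,) + shape)
            probs = raw / raw.sum(axis=0, keepdims=True)
            pred, target = _maps(probs, onehot)
            # evaluate the oracle on the container's (float32-stored) values
            expected = brute_force_gdl(pred.probs.astype(np.float64),
                                       target.onehot.astype(np.float64))
            got = generalized_dice_loss(pred, target)
            assert got == pytest.approx(expected, abs=1e-10)
            assert 0.0 <= got <= 1.0

    def test_invariant_to_voxel_permutation(self):
        rng = np.random.default_rng(3)
        fg = (rng.random(27) > 0.6).astype(np.float32)
        raw = rng.random((2, 27))
        probs = raw / raw.sum(axis=0, keepdims=True)
        perm = rng.permutation(27)
        a = brute_force_gdl(probs.reshape(2, 3, 3, 3), np.stack([1 - fg, fg]).reshape(2, 3, 3, 3))
        b = brute_force_gdl(
            probs[:, perm].reshape(2, 3, 3, 3),
            np.stack([1 - fg, fg])[:, perm].reshape(2, 3, 3, 3),
        )
        assert a == pytest.approx(b, abs=1e-12)

    def test_absent_class_stays_finite(self):
        fg = np.zeros((2, 2, 2), np.float32)  # no foreground at all
        onehot = np.stack([1 - fg, fg])
        probs = np.stack([np.ones_like(fg), np.zeros_like(fg)])
        pred, target = _maps(probs, onehot)
        loss = generalized_dice_loss(pred, target)
        assert np.isfinite(loss) and 0.0 <= loss <= 1.0

    def test_geometry_mismatch_rejected(self):
        fg = np.zeros((2, 2, 2), np.float32)
        onehot = np.stack([1 - fg, fg])
        probs = np.stack([np.ones_like(fg), np.zeros_like(fg)])
        pred, _ = _maps(probs, onehot)
        g2 = GridGeometry((4, 4, 4), 1.0)
        target2 = LabelMap(g2, np.stack([np.ones((4, 4, 4), np.float32),
                                         np.zeros((4, 4, 4), np.float32)]))
        with pytest.raises(ValueError):
            generalized_dice_loss(pred, target2)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        fg = (rng.random((3, 3, 3)) > 0.5).astype(np.float64)
        onehot = np.stack([1 - fg, fg])
        raw = rng.random((2, 3, 3, 3))
        probs = raw / raw.sum(axis=0, keepdims=True)
        _, grad = gdl_value_and_grad(probs, onehot)
        eps = 1e-7
        for idx in [(0, 0, 0, 0), (1, 1, 2, 0), (0, 2, 2, 2)]:
            pp = probs.copy()
            pp[idx] += eps
            lp = brute_force_gdl(pp, onehot)
            pm = probs.copy()
            pm[idx] -= eps
            lm = brute_force_gdl(pm, onehot)
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)

    def test_class_weights_are_inverse_squared_volumes(self):
        fg = np.zeros((2, 2, 2), np.float32)
        fg[0, 0, 0] = fg[1, 1, 1] = 1.0
        w = class_weights(np.stack([1 - fg, fg]))
        assert w == pytest.approx([1.0 / 36.0, 1.0 / 4.0])


class TestNetworkArchitecture:
    def test_default_spec_matches_deployed_configuration(self):
        model = build_localizer_network(NetworkSpec())
        desc = model.describe()
        assert desc["levels"] == 5
        assert desc["channels"] == (32, 64, 128, 256, 512)
        assert desc["normalization"] == "instance"
        assert desc["activation"] == "leaky_relu"
        assert desc["pooling"] == ["avg", "avg", "max", "max"]
        assert desc["pool_size"] == (2, 2, 2)
        assert desc["conv_kernel"] == (3, 3, 3)
        assert desc["conv_stride"] == 1
        assert desc["convs_per_stage"] == 2
        assert desc["out_channels"] == 2

    def test_forward_preserves_spatial_shape(self):
        model = build_localizer_network(NetworkSpec.small(input_edge=32))
        x = np.zeros((1, 32, 32, 32), np.float32)
        out = model.forward(x)
        assert out.shape == (2, 32, 32, 32)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(channels=(32, 64, 128, 256))

    def test_non_divisible_edge_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(input_edge=100)
        model = build_localizer_network(NetworkSpec.small(input_edge=32))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 20, 20, 20), np.float32))

    def test_pooling_layer_types_follow_schedule(self):
        from fetaltrack.nn.layers import AvgPool3d, MaxPool3d

        model = build_localizer_network(NetworkSpec())
        assert [type(p) for p in model.pools] == [
            AvgPool3d, AvgPool3d, MaxPool3d, MaxPool3d
        ]


class TestPredictMask:
    def _vol(self, edge=32):
        g = GridGeometry((edge,) * 3, 3.0)
        return VolumeGrid(g, np.zeros((edge,) * 3, np.float32))

    def test_argmax_with_tie_to_background(self):
        from fetaltrack.localizer import softmax_channels

        logits = np.zeros((2, 2, 2, 2))
        probs = softmax_channels(logits)  # exact 0.5/0.5 tie everywhere
        assert np.all(probs[1] <= probs[0])

    def test_foreground_blob_extracted(self):
        g = GridGeometry((4, 4, 4), 1.0)
        probs = np.full((2, 4, 4, 4), 0.9, np.float32)
        probs[1] = 0.1
        probs[1, 1:3, 1:3, 1:3] = 0.9
        probs[0] = 1.0 - probs[1]
        mask = BinaryMask(g, probs[1] > probs[0])
        assert mask.voxel_count == 8

    def test_untrained_network_output_partitions_voxels(self):
        model = build_localizer_network(NetworkSpec.small(input_edge=32), seed=1)
        vol = self._vol(32)
        mask, pmap = predict_mask(model, vol)
        np.testing.assert_allclose(pmap.probs.sum(axis=0), 1.0, atol=1e-5)
        bg = pmap.probs[1] <= pmap.probs[0]
        assert np.all(mask.values ^ bg)  # fg and bg are complementary

    def test_geometry_mismatch_rejected(self):
        model = build_localizer_network(NetworkSpec.small(input_edge=32))
        with pytest.raises(ValueError):
            predict_mask(model, self._vol(20))


class TestSegmentIntensity:
    def test_noise_free_sphere_matches_analytic_mask(self, sphere_scene, geom64,
                                                     noise_free_acq):
        traj = Trajectory(np.zeros((1, 3)))
        vol = acquire_repetition(sphere_scene, traj, geom64, 0, 90.0, noise_free_acq)
        truth = analytic_target_mask(sphere_scene, traj, geom64, 0)
        got = segment_intensity(vol)
        np.testing.assert_array_equal(got.values, truth.values)

    def test_largest_component_suppresses_confounder(self, geom64, noise_free_acq):
        scene = make_fetal_world(
            head_radii_mm=(30.0, 30.0, 30.0), background_s0=0.0
        )
        traj = Trajectory(np.zeros((1, 3)))
        vol = acquire_repetition(scene, traj, geom64, 0, 90.0, noise_free_acq)
        truth = analytic_target_mask(scene, traj, geom64, 0)
        got = segment_intensity(vol)
        # only the (larger) head survives largest-component selection
        assert (got.values & ~truth.values).sum() == 0
        from fetaltrack.evaluation import dice

        assert dice(got, truth) > 0.99

    def test_scale_invariance_with_auto_threshold(self, sphere_scene, geom64):
        acq = AcquisitionConfig(noise_sigma=1.0, seed=3)
        traj = Trajectory(np.zeros((1, 3)))
        vol = acquire_repetition(sphere_scene, traj, geom64, 0, 90.0, acq)
        scaled = VolumeGrid(geom64, vol.values * 7.5)
        a = segment_intensity(vol)
        b = segment_intensity(scaled)
        np.testing.assert_array_equal(a.values, b.values)

    def test_all_zero_volume_gives_flagged_empty_mask(self, geom64):
        vol = VolumeGrid(geom64, np.zeros(geom64.shape, np.float32))
        mask = segment_intensity(vol)
        assert mask.empty


class TestTraining:
    def test_descent_and_determinism_on_tiny_problem(self):
        train = make_training_scenes(4, edge=32, seed=0)
        val = make_training_scenes(2, edge=32, seed=50)
        cfg = TrainConfig(epochs=2, learning_rate=1e-3, seed=0, patch_edge=16)
        spec = NetworkSpec.small(input_edge=32)
        _, hist1 = train_localizer(train, val, cfg, spec=spec)
        _, hist2 = train_localizer(train, val, cfg, spec=spec)
        assert hist1 == hist2  # bitwise-deterministic given the seed
        assert hist1[-1]["train_gdl"] < hist1[0]["train_gdl"]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_localizer([], [], TrainConfig())

    def test_checkpoint_roundtrip(self, tmp_path):
        spec = NetworkSpec.small(input_edge=32)
        model = build_localizer_network(spec, seed=7)
        p = tmp_path / "ckpt.npz"
        save_checkpoint(model, spec, p, seed=7)
        back, back_spec, seed = load_checkpoint(p)
        assert back_spec == spec and seed == 7
        x = np.random.default_rng(0).random((1, 32, 32, 32), dtype=np.float32)
        np.testing.assert_array_equal(model.forward(x), back.forward(x))
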
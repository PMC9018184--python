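"""Loss arithmetic, perceptual path, and the staged training schedule."""

import numpy as np
import pytest

from crowngen.discriminators import DiscriminatorSpec, DualDiscriminator
from crowngen.generator import Generator, GeneratorSpec
from crowngen.objectives import (
    LossError,
    LossWeights,
    PerceptualPath,
    TrainConfig,
    _perceptual_value_and_grad,
    l1_loss,
    masked_l1,
    mse_loss,
    perceptual_loss,
    total_loss,
    train_staged,
)

RNG = np.random.default_rng(21)


class TestPixelLosses:
    def test_identical_images_zero(self):
        img = RNG.random((8, 8))
        assert mse_loss(img, img) == 0.0
        assert l1_loss(img, img) == 0.0

    def test_ones_vs_zeros(self):
        a, b = np.ones((4, 4)), np.zeros((4, 4))
        assert mse_loss(a, b) == pytest.approx(1.0, abs=1e-9)
        assert l1_loss(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_single_pixel_differences(self):
        a = np.zeros((2, 2))
        b = a.copy()
        b[0, 0] = 0.5
        assert mse_loss(a, b) == pytest.approx(0.0625, abs=1e-9)  # 0.25 / 4
        assert l1_loss(a, b) == pytest.approx(0.125, abs=1e-9)    # 0.5 / 4

    def test_shape_mismatch(self):
        with pytest.raises(LossError):
            mse_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_masked_l1_restricts_to_mask(self):
        a = np.zeros((4, 4))
        b = np.ones((4, 4))
        m = np.zeros((4, 4))
        m[0, :2] = 1
        assert masked_l1(a, b, m) == pytest.approx(1.0)
        assert masked_l1(a, b, np.zeros((4, 4))) == 0.0


class TestPerceptualLoss:
    def test_identity_feature_net_reduces_to_l1(self):
        a, b = RNG.random((6, 6)), RNG.random((6, 6))
        net = lambda x: [x]
        assert perceptual_loss(a, b, net) == pytest.approx(l1_loss(a, b), abs=1e-12)

    def test_scales_linearly_through_linear_features(self):
        a, b = RNG.random((6, 6)), RNG.random((6, 6))
        net = lambda x: [x]
        base = perceptual_loss(a, b, net)
        assert perceptual_loss(3 * a, 3 * b, net) == pytest.approx(3 * base)

    def test_no_tagged_layers_is_configuration_error(self):
        with pytest.raises(LossError):
            perceptual_loss(np.zeros((4, 4)), np.zeros((4, 4)), lambda x: [])

    def test_trunk_gradient_matches_finite_differences(self):
        disc = DualDiscriminator(
            DiscriminatorSpec(base_filters=4, feature_dim=8,
                              image_size=16, local_size=8),
            seed=1,
        )
        # give batch norm meaningful running stats
        disc.global_branch.trunk.forward(
            RNG.random((4, 5, 16, 16), dtype=np.float32), train=True
        )
        path = PerceptualPath(disc.global_branch.trunk)
        a = RNG.random((1, 5, 16, 16)).astype(np.float64)
        b = RNG.random((1, 5, 16, 16)).astype(np.float64)
        val, grad = _perceptual_value_and_grad(path, a, b)
        assert val == pytest.approx(
            perceptual_loss(a, b, path), abs=1e-5
        )
        eps = 1e-3
        for (c, r, s) in [(4, 7, 7), (0, 3, 12), (2, 10, 2)]:
            ap = a.copy(); ap[0, c, r, s] += eps
            am = a.copy(); am[0, c, r, s] -= eps
            vp, _ = _perceptual_value_and_grad(path, ap, b)
            vm, _ = _perceptual_value_and_grad(path, am, b)
            assert grad[0, c, r, s] == pytest.approx(
                (vp - vm) / (2 * eps), abs=1e-4
            )


class TestTotalLoss:
    def test_zero_components(self):
        assert total_loss(0, 0, 0, 0) == 0.0

    def test_weighted_sum_at_default_weights(self):
        # 1 + 100*0.01 + 50*0.02 + 50*0.03 = 4.5
        assert total_loss(1.0, 0.01, 0.02, 0.03) == pytest.approx(4.5, abs=1e-9)

    def test_zero_weights_degenerate_to_adv(self):
        w = LossWeights(lambda_L1=0, lambda_mse=0, lambda_per=0)
        assert total_loss(0.7, 9, 9, 9, w) == pytest.approx(0.7)

    def test_nan_component_aborts_with_name(self):
        with pytest.raises(LossError, match="mse"):
            total_loss(0.0, 0.0, float("nan"), 0.0)

    def test_affine_in_each_component(self):
        w = LossWeights()
        base = total_loss(0.1, 0.2, 0.3, 0.4, w)
        assert total_loss(0.1 + 1, 0.2, 0.3, 0.4, w) - base == pytest.approx(1.0)
        assert total_loss(0.1, 0.2 + 1, 0.3, 0.4, w) - base == pytest.approx(
            w.lambda_L1
        )
        assert total_loss(0.1, 0.2, 0.3 + 1, 0.4, w) - base == pytest.approx(
            w.lambda_mse
        )
        assert total_loss(0.1, 0.2, 0.3, 0.4 + 1, w) - base == pytest.approx(
            w.lambda_per
        )


def _nets(seed=0, image_size=48, local_size=24):
    g = Generator(GeneratorSpec(base_filters=8), seed=seed + 1)
    d = DualDiscriminator(
        DiscriminatorSpec(
            base_filters=8, feature_dim=32,
            image_size=image_size, local_size=local_size,
        ),
        seed=seed + 2,
    )
    return g, d


class TestTrainStaged:
    def test_zero_epoch_schedule_is_a_noop(self, tiny_cases):
        g, d = _nets()
        before = {k: v.copy() for k, v in g.state().items()}
        res = train_staged(
            tiny_cases[:4], [], g, d, TrainConfig(stage_epochs=(0, 0, 0))
        )
        assert res.log == [] and res.val_log == []
        for k, v in g.state().items():
            assert np.array_equal(v, before[k])

    def test_same_seed_reproduces_final_losses(self, tiny_cases):
        logs = []
        for _ in range(2):
            g, d = _nets(seed=5)
            res = train_staged(
                tiny_cases[:6], tiny_cases[6:], g, d,
                TrainConfig(stage_epochs=(1, 1, 1), batch_size=3, seed=9),
            )
            logs.append(res.log[-1])
        assert logs[0] == logs[1]

    def test_stage1_validation_l1_decreases(self, tiny_cases):
        g, d = _nets(seed=2)
        res = train_staged(
            tiny_cases[:6], tiny_cases[6:], g, d,
            TrainConfig(stage_epochs=(3, 0, 0), batch_size=3, seed=4),
        )
        vals = [r["median_l1"] for r in res.val_log if r["stage"] == 1]
        assert vals[-1] < vals[0]

    def test_checkpoints_at_stage_boundaries(self, tiny_cases, tmp_path):
        g, d = _nets(seed=3)
        res = train_staged(
            tiny_cases[:4], [], g, d,
            TrainConfig(stage_epochs=(1, 1, 1), batch_size=2, seed=1),
            out_dir=tmp_path,
        )
        assert set(res.checkpoints) == {"stage1", "stage2", "stage3"}
        assert (tmp_path / "generator_stage1.npz").exists()
        # frozen-generator contract: stage-1 and stage-2 G states identical
        s1 = res.checkpoints["stage1"]["generator"]
        s2 = res.checkpoints["stage2"]["generator"]
        for k in s1:
            assert np.array_equal(s1[k], s2[k])
        # discriminator trained during stage II
        d1 = res.checkpoints["stage1"]["discriminator"]
        d2 = res.checkpoints["stage2"]["discriminator"]
        assert any(not np.array_equal(d1[k], d2[k]) for k in d1)

    def test_log_has_all_loss_columns(self, tiny_cases):
        g, d = _nets(seed=6)
        res = train_staged(
            tiny_cases[:4], [], g, d,
            TrainConfig(stage_epochs=(1, 1, 1), batch_size=2, seed=2),
        )
        stages = {r["stage"] for r in res.log}
        assert stages == {1, 2, 3}
        row = [r for r in res.log if r["stage"] == 3][-1]
        for key in ("loss_l1", "loss_mse", "loss_per", "loss_adv", "loss_d"):
            assert np.isfinite(row[key])
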
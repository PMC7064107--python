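"""Network stack: gradient correctness, architecture contract, SE gating,
normalization, the training loop and residual inference."""

import numpy as np
import pytest

from laxm.nn import (
    ArtifactUNet,
    SEBlock,
    TrainConfig,
    UNetConfig,
    learning_rate,
    load_checkpoint,
    normalize,
    predict_clean,
    save_checkpoint,
    train,
)
from laxm.nn.train import predict_artifact
from laxm.phantoms import SliceImage

TINY = UNetConfig(depth=2, base_channels=3, se_reduction=2)


def _float64(net):
    for l in net.layers():
        for k in l.params:
            l.params[k] = l.params[k].astype(np.float64)
    return net


class TestGradients:
    @pytest.mark.parametrize("upsample", ["bilinear", "transposed"])
    def test_parameter_gradients_match_finite_differences(self, rng, upsample):
        cfg = UNetConfig(depth=2, base_channels=3, se_reduction=2, upsample=upsample)
        net = _float64(ArtifactUNet(cfg, seed=0))
        x = rng.standard_normal((2, 1, 8, 8))
        y = rng.standard_normal((2, 1, 8, 8))

        def loss():
            pred = net.forward(x, training=True)
            return float(np.mean((pred - y) ** 2))

        pred = net.forward(x, training=True)
        net.backward((2.0 / pred.size) * (pred - y))
        for layer in net.layers():
            for k, p in layer.params.items():
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps, old = 1e-6, p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = layer.grads[k][idx]
                assert num == pytest.approx(ana, rel=1e-3, abs=1e-9), (
                    f"{type(layer).__name__}.{k}"
                )

    def test_input_gradient_directional_derivative(self, rng):
        net = _float64(ArtifactUNet(TINY, seed=0))
        x = rng.standard_normal((2, 1, 8, 8))
        y = rng.standard_normal((2, 1, 8, 8))
        d = rng.standard_normal(x.shape)
        d /= np.linalg.norm(d)
        pred = net.forward(x, training=True)
        dx = net.backward((2.0 / pred.size) * (pred - y))
        ana = float(np.sum(dx * d))
        eps = 1e-6
        lp = float(np.mean((net.forward(x + eps * d, training=True) - y) ** 2))
        lm = float(np.mean((net.forward(x - eps * d, training=True) - y) ** 2))
        assert (lp - lm) / (2 * eps) == pytest.approx(ana, rel=1e-5)


class TestArchitecture:
    def test_output_size_equals_input_size(self):
        net = ArtifactUNet(TINY, seed=0)
        for size in (8, 16, 32):
            out = net.forward(np.zeros((1, 1, size, size), np.float32))
            assert out.shape == (1, 1, size, size)

    def test_indivisible_size_rejected(self):
        net = ArtifactUNet(UNetConfig(depth=3, base_channels=2, se_reduction=2))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 12, 12), np.float32))

    def test_seeded_init_is_reproducible(self):
        a = ArtifactUNet(TINY, seed=5)
        b = ArtifactUNet(TINY, seed=5)
        c = ArtifactUNet(TINY, seed=6)
        sa, sb, sc = a.state_arrays(), b.state_arrays(), c.state_arrays()
        assert all(np.array_equal(sa[k], sb[k]) for k in sa)
        assert any(not np.array_equal(sa[k], sc[k]) for k in sa)

    def test_forward_finite_on_unit_range_input(self, rng):
        net = ArtifactUNet(TINY, seed=1)
        x = rng.uniform(-1, 1, (2, 1, 16, 16)).astype(np.float32)
        assert np.all(np.isfinite(net.forward(x, training=True)))
        assert np.all(np.isfinite(net.predict(x)))

    def test_parameter_count_deterministic(self):
        assert (
            ArtifactUNet(TINY, seed=0).n_parameters()
            == ArtifactUNet(TINY, seed=99).n_parameters()
        )

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net = ArtifactUNet(TINY, seed=3)
        x = rng.uniform(-1, 1, (1, 1, 16, 16)).astype(np.float32)
        net.forward(x, training=True)  # move BN running stats off init
        path = tmp_path / "model.npz"
        save_checkpoint(path, net, norm_constant=0.025)
        net2, nc = load_checkpoint(path)
        assert nc == 0.025
        assert np.allclose(net.predict(x), net2.predict(x))


class TestSEBlock:
    def test_identity_gate_mode(self, rng):
        se = SEBlock(4, reduction=2, rng=np.random.default_rng(0))
        se.force_identity = True
        x = rng.standard_normal((2, 4, 6, 6))
        assert np.array_equal(se.forward(x), x)

    def test_gates_lie_in_unit_interval(self, rng):
        se = SEBlock(4, reduction=2, rng=np.random.default_rng(0))
        x = rng.standard_normal((2, 4, 6, 6))
        se.forward(x)
        _, _, _, _, g = se._cache
        assert np.all((g > 0) & (g < 1))

    def test_uniform_channels_stay_uniform(self):
        se = SEBlock(3, reduction=3, rng=np.random.default_rng(0))
        x = np.ones((1, 3, 5, 5)) * np.array([1.0, -2.0, 0.5])[None, :, None, None]
        y = se.forward(x)
        assert np.allclose(y, y[:, :, :1, :1])


class TestNormalize:
    def test_constant_from_max_abs(self, rng):
        imgs = [rng.uniform(-0.02, 0.02, (8, 8)) for _ in range(4)]
        imgs[2][3, 3] = 0.02
        scaled, c = normalize(imgs)
        assert c == 0.02
        assert np.abs(scaled).max() == pytest.approx(1.0)

    def test_single_constant_image_scales_to_one(self):
        scaled, c = normalize([np.full((4, 4), 0.007)])
        assert c == pytest.approx(0.007)
        assert np.allclose(scaled, 1.0)

    def test_round_trip(self, rng):
        imgs = [rng.standard_normal((8, 8)) for _ in range(3)]
        scaled, c = normalize(imgs)
        assert np.allclose(scaled * c, np.stack(imgs), atol=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize([np.zeros((4, 4))])


class TestTraining:
    def test_lr_schedule_endpoints(self):
        cfg = TrainConfig(epochs=500, lr_plateau_epochs=100)
        assert learning_rate(1, cfg) == 1e-3
        assert learning_rate(100, cfg) == 1e-3
        assert learning_rate(500, cfg) == pytest.approx(1e-5)
        assert learning_rate(101, cfg) < 1e-3

    def test_descent_and_determinism_on_tiny_fixture(self, rng):
        """Loss falls on 8 pairs of 16x16 images, and identical seeds give
        identical loss curves."""
        x = rng.standard_normal((8, 16, 16)) * 0.01
        y = 0.5 * x  # a learnable linear artifact
        cfg = UNetConfig(depth=2, base_channels=4, se_reduction=2)
        tc = TrainConfig(epochs=15, lr_plateau_epochs=10, batch_size=4,
                         seed=0, val_fraction=0.0)
        net, _, log = train(x, y, cfg, tc)
        assert log[-1]["train_loss"] < log[0]["train_loss"]
        _, _, log2 = train(x, y, cfg, tc)
        assert [e["train_loss"] for e in log] == [e["train_loss"] for e in log2]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((0, 8, 8)), np.zeros((0, 8, 8)), TINY,
                  TrainConfig(epochs=1, lr_plateau_epochs=1))


class TestPredictClean:
    def test_zero_head_returns_input_unchanged(self, rng):
        net = ArtifactUNet(TINY, seed=0)
        net.head.params["W"][...] = 0.0
        net.head.params["b"][...] = 0.0
        img = SliceImage(pixels=rng.uniform(0, 0.02, (16, 16)))
        out = predict_clean(img, net, norm_constant=0.02)
        assert np.allclose(out.pixels, img.pixels)

    def test_inference_is_deterministic(self, rng):
        net = ArtifactUNet(TINY, seed=0)
        img = rng.uniform(0, 0.02, (16, 16))
        a = predict_artifact(img, net, 0.02)
        b = predict_artifact(img, net, 0.02)
        assert np.array_equal(a, b)

    def test_invalid_norm_constant_rejected(self, rng):
        net = ArtifactUNet(TINY, seed=0)
        with pytest.raises(ValueError):
            predict_clean(rng.uniform(0, 1, (16, 16)), net, norm_constant=0.0)


class TestCheckerboard:
    def test_bilinear_decoder_suppresses_two_pixel_periodicity(self, rng):
        """Trained identically, the transposed-convolution decoder leaves a
        stronger 2-pixel-period spectral peak than the bilinear decoder."""
        x = (0.01 * rng.standard_normal((12, 16, 16))).astype(np.float64)
        y = np.stack([0.5 * xi + 0.002 for xi in x])
        tc = TrainConfig(epochs=10, lr_plateau_epochs=10, batch_size=4,
                         seed=0, val_fraction=0.0)

        def nyquist_power(upsample):
            cfg = UNetConfig(depth=2, base_channels=4, se_reduction=2,
                             upsample=upsample)
            net, nc, _ = train(x, y, cfg, tc)
            peaks = []
            for xi in x:
                out = predict_artifact(xi, net, nc)
                spec = np.abs(np.fft.fft2(out))
                n = out.shape[0]
                peaks.append(spec[n // 2, :].mean() + spec[:, n // 2].mean())
            return np.mean(peaks)

        assert nyquist_power("bilinear") < nyquist_power("transposed")
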
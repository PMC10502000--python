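"""U-net topology, composite loss, training harness, prediction contracts."""

import numpy as np
import pytest

from gutgaze.model import predict
from gutgaze.nn import UNet, UNetConfig, build_unet, composite_loss, train
from gutgaze.nn.losses import composite_loss_and_grads
from gutgaze.nn.train import stack_samples
from gutgaze.preprocessing import TrainingSample
from gutgaze.reconstruction import VolumeGrid


def tiny_net(seed=0, shape=(16, 16)):
    return build_unet(
        UNetConfig(dims=2, input_shape=shape, base_channels=2, n_levels=2, dropout=0.0),
        seed=seed,
    )


def tiny_samples(n, rng, shape=(16, 16)):
    out = []
    for _ in range(n):
        labels = np.zeros(shape, np.uint8)
        labels[4:10, 4:10] = 2
        diam = np.where(labels > 0, 8.0, 0.0)
        img = np.clip(np.where(labels > 0, 0.5, -0.5) + rng.normal(0, 0.1, shape), -1, 1)
        out.append(TrainingSample(img, labels, diam, np.where(labels > 0, 10.0, 1.0)))
    return out


class TestTopology:
    @pytest.mark.parametrize(
        "dims,n_levels,blocks", [(2, 7, 14), (3, 5, 10), (2, 3, 6)]
    )
    def test_block_count_is_twice_levels(self, dims, n_levels, blocks):
        shape = (256,) * dims if dims == 2 else (128, 128, 64)
        cfg = UNetConfig(dims=dims, input_shape=shape, n_levels=n_levels)
        assert cfg.n_blocks == blocks

    def test_reference_defaults(self):
        cfg2 = UNetConfig(dims=2)
        assert (cfg2.base_channels, cfg2.n_levels) == (8, 7)
        cfg3 = UNetConfig(dims=3, input_shape=(128, 128, 64))
        assert (cfg3.base_channels, cfg3.n_levels) == (16, 5)

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(dims=2, input_shape=(100, 100), n_levels=3)

    def test_forward_shapes_and_output_contracts(self, rng):
        net = tiny_net()
        x = rng.normal(0, 1, (2, 1, 16, 16))
        probs, diam = net.predict_proba(x)
        assert probs.shape == (2, 4, 16, 16)
        assert diam.shape == (2, 1, 16, 16)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (diam >= 0).all()

    def test_parameter_count_grows_fourfold_per_level(self):
        p2 = build_unet(UNetConfig(dims=2, input_shape=(16, 16), base_channels=4,
                                   n_levels=2)).n_parameters
        p3 = build_unet(UNetConfig(dims=2, input_shape=(16, 16), base_channels=4,
                                   n_levels=3)).n_parameters
        assert 3.0 <= (p3 - p2 + p2) / p2 <= 6.0  # total roughly quadruples

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        net = tiny_net(seed=5)
        x = rng.normal(0, 1, (1, 1, 16, 16))
        p0, d0 = net.predict_proba(x)
        path = tmp_path / "model.npz"
        net.save(path)
        loaded = UNet.load(path)
        p1, d1 = loaded.predict_proba(x)
        assert np.allclose(p0, p1) and np.allclose(d0, d1)


class TestCompositeLoss:
    def test_perfect_prediction_is_zero(self):
        t = np.zeros((1, 4, 2, 2))
        t[:, 2] = 1.0
        p = np.clip(t, 1e-12, 1.0)
        d = np.full((1, 2, 2), 7.0)
        assert composite_loss(p, t, d, d) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_background_analytic_value(self):
        p = np.full((1, 4, 2, 2), 0.25)
        t = np.zeros((1, 4, 2, 2))
        t[:, 0] = 1.0
        d = np.zeros((1, 2, 2))
        assert composite_loss(p, t, d, d) == pytest.approx(2 * np.log(4), rel=1e-6)

    def test_diameter_term_scale(self):
        t = np.zeros((1, 4, 1, 1))
        t[:, 1] = 1.0
        p = np.clip(t, 1e-9, 1 - 1e-9)
        base = composite_loss(p, t, np.zeros((1, 1, 1)), np.full((1, 1, 1), 10.0), lam=0.01)
        assert base == pytest.approx(1.0, abs=1e-4)  # 0.01 * 10^2

    def test_negative_lambda_rejected(self):
        p = np.full((1, 4, 1, 1), 0.25)
        with pytest.raises(ValueError):
            composite_loss(p, p, np.zeros((1, 1, 1)), np.zeros((1, 1, 1)), lam=-1.0)

    def test_matches_independent_scalar_loop(self, rng):
        """Vectorized loss equals a per-voxel scalar reimplementation."""
        import math

        N, H, W = 2, 3, 4
        logits = rng.normal(0, 2, (N, 4, H, W))
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = rng.integers(0, 4, (N, H, W))
        t = np.moveaxis(np.eye(4)[labels], -1, 1)
        d_p = rng.uniform(0, 20, (N, H, W))
        d_t = rng.uniform(0, 20, (N, H, W))
        w = np.where(labels > 0, 10.0, 1.0)
        lam = 0.01
        total = 0.0
        for n in range(N):
            for i in range(H):
                for j in range(W):
                    ce = -math.log(p[n, labels[n, i, j], i, j])
                    t0 = 1.0 if labels[n, i, j] == 0 else 0.0
                    p0 = p[n, 0, i, j]
                    bce = -(t0 * math.log(p0) + (1 - t0) * math.log(1 - p0))
                    se = (d_t[n, i, j] - d_p[n, i, j]) ** 2
                    total += w[n, i, j] * (ce + bce + lam * se)
        expected = total / (N * H * W)
        assert composite_loss(p, t, d_p, d_t, w, lam) == pytest.approx(expected, rel=1e-5)

    def test_lambda_zero_decouples_diameter_head(self, rng):
        logits = rng.normal(0, 1, (1, 4, 4, 4))
        t = np.moveaxis(np.eye(4)[rng.integers(0, 4, (1, 4, 4))], -1, 1)
        d_p = rng.uniform(0, 10, (1, 4, 4))
        d_t = rng.uniform(0, 10, (1, 4, 4))
        _, _, ddiam = composite_loss_and_grads(logits, t, d_p, d_t, lam=0.0)
        assert (ddiam == 0).all()

    def test_gradients_match_finite_differences(self, rng):
        net = tiny_net(seed=3, shape=(8, 8))
        x = rng.normal(0, 1, (2, 1, 8, 8))
        labels = rng.integers(0, 4, (2, 8, 8))
        t = np.moveaxis(np.eye(4)[labels], -1, 1)
        d_t = rng.uniform(0, 15, (2, 8, 8))
        w = np.where(labels > 0, 10.0, 1.0)

        def value():
            logits, diam = net.forward(x, training=True)
            return composite_loss_and_grads(logits, t, diam[:, 0], d_t, w, 0.01)[0]

        net.zero_grad()
        logits, diam = net.forward(x, training=True)
        _, dlogits, ddiam = composite_loss_and_grads(logits, t, diam[:, 0], d_t, w, 0.01)
        net.backward(dlogits, ddiam[:, None])
        eps = 1e-6
        params = net.parameters()
        for pi in rng.choice(len(params), 5, replace=False):
            p = params[pi]
            flat = p.value.reshape(-1)
            k = int(rng.integers(flat.size))
            orig = flat[k]
            flat[k] = orig + eps
            up = value()
            flat[k] = orig - eps
            dn = value()
            flat[k] = orig
            num = (up - dn) / (2 * eps)
            ana = p.grad.reshape(-1)[k]
            assert num == pytest.approx(ana, abs=1e-6, rel=1e-4), p.name


class TestTraining:
    def test_loss_decreases_when_overfitting(self, rng):
        samples = tiny_samples(4, rng)
        net = tiny_net(seed=1)
        _, hist = train(net, samples, epochs=15, lr=0.01, val_fraction=0.0, seed=1,
                        batch_size=2)
        losses = hist.frame.train_loss.to_numpy()
        assert losses[-1] < losses[0] * 0.5

    def test_same_seed_identical_history(self, rng):
        samples = tiny_samples(4, rng)
        h = []
        for _ in range(2):
            net = tiny_net(seed=2)
            _, hist = train(net, samples, epochs=3, lr=1e-3, val_fraction=0.25,
                            seed=9, batch_size=2)
            h.append(hist.frame.val_loss.to_numpy())
        assert (h[0] == h[1]).all()

    def test_empty_split_rejected(self, rng):
        samples = tiny_samples(2, rng)
        with pytest.raises(ValueError):
            train(tiny_net(), samples, epochs=1, val_fraction=0.9)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            train(tiny_net(), tiny_samples(1, rng), epochs=1)


class TestPredict:
    def test_prediction_contracts_on_original_grid(self, rng):
        grid = VolumeGrid((24, 24, 5), (1.0, 1.0, 3.0))
        ct = rng.normal(0, 100, grid.shape)
        net = tiny_net()
        labels, diam = predict(net, ct, grid)
        assert labels.grid == grid and diam.grid == grid
        assert set(np.unique(labels.values)) <= {0, 1, 2, 3}
        assert (diam.values >= 0).all()
        assert diam.units == "voxels"

    def test_shape_mismatch_rejected(self, rng):
        grid = VolumeGrid((24, 24, 5), (1.0, 1.0, 3.0))
        with pytest.raises(ValueError):
            predict(tiny_net(), rng.normal(0, 1, (10, 10, 2)), grid)
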
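"""Network architectures, training schedule, tiled inference."""

import numpy as np
import pytest

from ezseg import networks, nn, patches, phantom
from ezseg.networks import (SWConfig, TrainConfig, TrainedModel, UNetConfig,
                            build_sw, build_unet, classify_pixels,
                            segment_bscan)


class _IntensityNet(nn.Layer):
    """Oracle 'network': scores by proximity to known region intensities.

    On a noise-free phantom whose regions have distinct mean
    reflectances this reproduces the true label map pixel-for-pixel,
    which makes it a ground-truth oracle for the tiling/stitching
    machinery.  It is pixel-wise, hence exactly mirror-symmetric.
    """

    def __init__(self, levels):
        self.levels = np.asarray(levels, dtype=np.float32)

    def params(self):
        return []

    def forward(self, x, train):
        return -np.abs(x - self.levels)


def intensity_oracle(spec) -> TrainedModel:
    return TrainedModel("unet", UNetConfig(), _IntensityNet(spec.layer_intensities),
                        trained=True)


class TestLearningRateSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (1, 0.01), (10, 0.01), (11, 0.001), (21, 1e-4), (25, 1e-4),
        (31, 1e-5), (41, 1e-6), (45, 1e-6)])
    def test_unet_schedule(self, epoch, expected):
        tc = TrainConfig(initial_lr=0.01)
        assert tc.learning_rate(epoch) == pytest.approx(expected, rel=1e-12)

    def test_sw_initial_rate(self):
        assert TrainConfig(initial_lr=0.05).learning_rate(5) == 0.05

    def test_epoch_must_be_positive(self):
        with pytest.raises(ValueError):
            TrainConfig().learning_rate(0)


class TestBuildUnet:
    def test_output_shape_has_5_classes(self):
        m = build_unet(seed=0)
        x = np.random.rand(2, 256, 32).astype(np.float32)
        out = networks._forward_batch(m, x, train=False)
        assert out.shape == (2, 256, 32, 5)

    def test_param_count_deterministic_and_monotone(self):
        a, b = build_unet(seed=0), build_unet(seed=99)
        assert a.n_params == b.n_params
        wider = build_unet(UNetConfig(initial_channels=16), seed=0)
        assert wider.n_params > a.n_params

    def test_identical_seed_identical_weights(self):
        a, b = build_unet(seed=7), build_unet(seed=7)
        for pa, pb in zip(a.net.params(), b.net.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_batchnorm_only_in_encoder(self):
        m = build_unet(seed=0)
        net = m.net
        enc_bns = [l for blk in net.enc for l in blk.layers
                   if isinstance(l, nn.BatchNorm)]
        dec_bns = [l for blk in net.dec for l in blk.layers
                   if isinstance(l, nn.BatchNorm)]
        assert len(enc_bns) == 8 and len(dec_bns) == 0


class TestBuildSw:
    def test_layer_inventory(self):
        m = build_sw(seed=0)
        layers = m.net.layers
        inventory = {
            nn.Conv2d: sum(isinstance(l, nn.Conv2d) for l in layers),
            nn.MaxPool2d: sum(isinstance(l, nn.MaxPool2d) for l in layers),
            nn.ReLU: sum(isinstance(l, nn.ReLU) for l in layers),
            nn.Linear: sum(isinstance(l, nn.Linear) for l in layers),
        }
        assert inventory == {nn.Conv2d: 3, nn.MaxPool2d: 3,
                             nn.ReLU: 4, nn.Linear: 2}

    def test_softmax_outputs_sum_to_one(self):
        m = build_sw(seed=0)
        x = np.random.rand(3, 33, 33).astype(np.float32)
        probs = nn.softmax(networks._forward_batch(m, x, train=False))
        assert probs.shape == (3, 6)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_seed_identical_weights(self):
        a, b = build_sw(seed=3), build_sw(seed=3)
        for pa, pb in zip(a.net.params(), b.net.params()):
            assert np.array_equal(pa.value, pb.value)


class TestGradients:
    def test_conv_gradients_match_numeric(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv2d(2, 3, 5, rng)
        x = rng.normal(size=(2, 6, 7, 2)).astype(np.float32)
        dy = rng.normal(size=(2, 6, 7, 3)).astype(np.float32)
        conv.forward(x, True)
        dx = conv.backward(dy)

        def f(xv):
            return float((conv.forward(xv, False) * dy).sum())

        eps, idx = 1e-3, (1, 3, 2, 1)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        assert (f(xp) - f(xm)) / (2 * eps) == pytest.approx(dx[idx], rel=2e-2)

    def test_tiny_net_loss_gradient(self):
        rng = np.random.default_rng(1)
        net = nn.Sequential([nn.Conv2d(1, 4, 3, rng), nn.BatchNorm(4), nn.ReLU(),
                             nn.Conv2d(4, 3, 1, rng)])
        x = rng.normal(size=(4, 8, 6, 1)).astype(np.float32)
        y = rng.integers(0, 3, size=(4, 8, 6))
        logits = net.forward(x, True)
        loss, d = nn.softmax_cross_entropy(logits, y)
        net.backward(d)
        w = net.layers[0].W
        eps, idx = 1e-2, (5, 0, 2)
        orig = w.value[idx]
        w.value[idx] = orig + eps
        lp, _ = nn.softmax_cross_entropy(net.forward(x, True), y)
        w.value[idx] = orig - eps
        lm, _ = nn.softmax_cross_entropy(net.forward(x, True), y)
        w.value[idx] = orig
        assert (lp - lm) / (2 * eps) == pytest.approx(w.grad[idx], rel=0.05, abs=1e-4)


class TestTrain:
    def _sw_sets(self, n=500):
        g = phantom.ScanGeometry(n_cols=128, n_rows=256, n_lines=5)
        spec = phantom.PhantomSpec.flat(g, rows=(60, 120, 150, 170, 182),
                                        noise_level=0.0, noise_floor=0.0)
        img, lines, _ = phantom.generate_bscan(spec, 2)
        ps = patches.extract_sw_patches(img, lines, bg_per_column=2, seed=0)
        keep = np.random.default_rng(0).choice(len(ps), size=min(n, len(ps)),
                                               replace=False)
        return patches.split_dataset(ps.subset(keep), 0.8, seed=0)

    def test_accuracy_improves_on_noiseless_phantom(self):
        tr, va = self._sw_sets()
        m = build_sw(seed=0)
        acc0 = networks.validation_accuracy(m, va)
        networks.train(m, tr, va, TrainConfig(initial_lr=0.05, epochs=3, seed=0))
        assert m.history[-1]["val_accuracy"] > acc0

    def test_history_and_schedule_honoured(self):
        tr, va = self._sw_sets(200)
        m = build_sw(seed=1)
        networks.train(m, tr, va, TrainConfig(initial_lr=0.05, epochs=2, seed=1))
        assert len(m.history) == 2
        assert m.history[0]["lr"] == 0.05
        assert m.trained

    def test_flavor_mismatch_and_empty_set(self):
        tr, va = self._sw_sets(100)
        u = build_unet(seed=0)
        with pytest.raises(ValueError):
            networks.train(u, tr, va, TrainConfig())
        empty = patches.PatchSet("sw", np.zeros((0, 33, 33), np.float32),
                                 np.zeros(0, np.int8))
        with pytest.raises(ValueError):
            networks.train(build_sw(seed=0), empty, va, TrainConfig())


@pytest.fixture(scope="module")
def phantom_scan():
    g = phantom.ScanGeometry(n_cols=160, n_rows=300, n_lines=5)
    spec = phantom.PhantomSpec.flat(g, rows=(60, 130, 165, 190, 205),
                                    ez_semi_axes_mm=(2.5, 3.0),
                                    noise_level=0.0, noise_floor=0.0)
    img, lines, labels = phantom.generate_bscan(spec, 2)
    return spec, img, labels


class TestSegmentBscan:
    def test_oracle_stitching_reproduces_ground_truth(self, phantom_scan):
        spec, img, labels = phantom_scan
        m = intensity_oracle(spec)
        out = segment_bscan(m, img)
        assert out.shape == img.shape
        assert np.array_equal(out, labels)

    def test_mirror_equivariance(self, phantom_scan):
        spec, img, labels = phantom_scan
        m = intensity_oracle(spec)
        assert np.array_equal(segment_bscan(m, img[:, ::-1]),
                              segment_bscan(m, img)[:, ::-1])

    def test_untrained_model_rejected(self):
        m = build_unet(seed=0)
        with pytest.raises(RuntimeError):
            segment_bscan(m, np.zeros((256, 64), np.float32))

    def test_tie_break_toward_lower_class(self):
        levels = (0.5, 0.5, 0.1, 0.2, 0.3)   # classes 0 and 1 tie at 0.5
        m = TrainedModel("unet", UNetConfig(), _IntensityNet(levels), trained=True)
        img = np.full((256, 32), 0.5, np.float32)
        assert (segment_bscan(m, img) == 0).all()


@pytest.fixture(scope="module")
def sw_model():
    m = build_sw(seed=0)
    m.allow_untrained = True
    return m


class TestClassifyPixels:
    def test_empty_coords(self, sw_model):
        cls, probs = classify_pixels(sw_model, np.zeros((64, 64), np.float32), [])
        assert len(cls) == 0 and probs.shape == (0, 6)

    def test_probabilities_sum_to_one_and_border_ok(self, sw_model):
        img = np.random.default_rng(0).random((64, 64)).astype(np.float32)
        cls, probs = classify_pixels(sw_model, img, [(0, 0), (31, 40), (63, 63)])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert len(cls) == 3

    def test_out_of_range_coordinate(self, sw_model):
        with pytest.raises(IndexError):
            classify_pixels(sw_model, np.zeros((32, 32), np.float32), [(40, 0)])


class TestModelSerialization:
    def test_save_load_roundtrip_preserves_outputs(self, tmp_path):
        from ezseg.cli import load_model, save_model

        g = phantom.ScanGeometry(n_cols=96, n_rows=256, n_lines=5)
        spec = phantom.PhantomSpec.flat(g, rows=(60, 120, 150, 170, 182),
                                        noise_level=0.0, noise_floor=0.0)
        img, lines, _ = phantom.generate_bscan(spec, 2)
        ps = patches.extract_sw_patches(img, lines, bg_per_column=1, seed=0)
        tr, va = patches.split_dataset(ps, 0.8, seed=0)
        m = build_sw(seed=0)
        networks.train(m, tr, va, TrainConfig(initial_lr=0.05, epochs=1, seed=0))
        save_model(m, tmp_path / "sw")
        back = load_model(tmp_path / "sw")
        assert back.trained
        x = np.random.default_rng(1).random((4, 33, 33)).astype(np.float32)
        a = networks._forward_batch(m, x, train=False)
        b = networks._forward_batch(back, x, train=False)
        assert np.allclose(a, b, atol=1e-6)
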
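"""SR harness: architectures, losses, training loop, inference, baselines."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import pclesr as P
from pclesr.data import PatchSet
from pclesr.errors import InvalidArgumentError, TrainingDivergedError
from pclesr.sr import _ssim_value_and_grad


def patchset(x, y=None, size=32):
    x = np.asarray(x)
    y = x.copy() if y is None else np.asarray(y)
    n = x.shape[0]
    return PatchSet(lr_patches=x, hr_patches=y, positions=np.zeros((n, 2), int),
                    pair_ids=["p"] * n, patch_size=size)


class TestBuildModel:
    def test_fsrcnn_parameter_count_closed_form(self):
        model = P.build_model(P.ModelSpec("fsrcnn_like"), seed=0)
        d, s, m = 56, 12, 4
        expected = (25 * d + d) + (d * s + s) + m * (9 * s * s + s) + (s * d + d) + (81 * d + 1)
        assert model.parameter_count == expected

    @pytest.mark.parametrize("shape", [(64, 64), (97, 123)])
    def test_edsr_fully_convolutional_shapes(self, shape):
        model = P.build_model(P.ModelSpec("edsr_like", width=16, depth=2), seed=0)
        x = np.random.default_rng(0).uniform(0, 1, (1, *shape))
        assert model.forward(x).shape == (1, *shape)

    def test_seed_determinism(self):
        a = P.build_model(P.ModelSpec("edsr_like", width=8, depth=1), seed=5)
        b = P.build_model(P.ModelSpec("edsr_like", width=8, depth=1), seed=5)
        assert all(np.array_equal(p, q) for p, q in zip(a.params(), b.params()))

    def test_unknown_family(self):
        with pytest.raises(InvalidArgumentError):
            P.ModelSpec("srgan_like")

    def test_scale_must_be_one(self):
        with pytest.raises(InvalidArgumentError):
            P.ModelSpec("edsr_like", scale=2)


class TestLosses:
    def test_zero_at_equality(self):
        x = np.random.default_rng(0).uniform(0, 1, (2, 32, 32))
        assert P.loss_l1(x, x)[0] == 0.0
        assert P.loss_ssim_l1(x, x, alpha=0.5, data_range=1.0)[0] == pytest.approx(0.0, abs=1e-9)

    def test_alpha_zero_is_l1(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, (2, 3, 24, 24))
        v0, g0 = P.loss_ssim_l1(a, b, alpha=0.0)
        v1, g1 = P.loss_l1(a, b)
        assert v0 == v1 and np.array_equal(g0, g1)

    def test_alpha_one_is_one_minus_ssim(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0, 1, (2, 40, 40))
        v, _ = P.loss_ssim_l1(a[None], b[None], alpha=1.0, data_range=1.0)
        assert v == pytest.approx(1.0 - P.ssim(a, b), abs=1e-9)

    def test_constant_offset_l1(self):
        x = np.random.default_rng(3).uniform(0, 1, (2, 16, 16))
        v, _ = P.loss_l1(x + 0.25, x)
        assert v == pytest.approx(0.25, abs=1e-12)

    def test_ssim_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, (2, 24, 24))
        y = rng.uniform(0, 1, (2, 24, 24))
        _, g = _ssim_value_and_grad(x, y, 1.0)
        for _ in range(6):
            i = tuple(rng.integers(0, s) for s in x.shape)
            e = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i] += e
            xm[i] -= e
            fd = (_ssim_value_and_grad(xp, y, 1.0)[0] - _ssim_value_and_grad(xm, y, 1.0)[0]) / (2 * e)
            assert g[i] == pytest.approx(fd, abs=1e-7)

    def test_shape_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            P.loss_l1(np.zeros((1, 8, 8)), np.zeros((1, 9, 9)))


class TestTrain:
    def test_descent_on_learnable_identity(self):
        rng = np.random.default_rng(5)
        ps = patchset(rng.uniform(0, 1, (24, 32, 32)))
        model = P.build_model(
            P.ModelSpec("fsrcnn_like", width=8, shrink=4, depth=1), seed=1
        )
        cfg = P.TrainConfig(minibatch=4, max_steps=200, learning_rate=1e-3,
                            loss="l1", seed=0, val_every=50)
        model, hist = P.train(model, ps, ps, cfg)
        assert hist.val_loss.dropna().iloc[-1] < hist.train_loss.iloc[0]

    def test_history_reproducible(self):
        rng = np.random.default_rng(6)
        ps = patchset(rng.uniform(0, 1, (10, 32, 32)))
        runs = []
        for _ in range(2):
            model = P.build_model(P.ModelSpec("edsr_like", width=8, depth=1), seed=2)
            cfg = P.TrainConfig(minibatch=4, max_steps=20, learning_rate=1e-3,
                                loss="l1", seed=3, val_every=10)
            _, hist = P.train(model, ps, ps, cfg)
            runs.append(hist.train_loss.to_numpy())
        assert np.allclose(runs[0], runs[1], rtol=1e-6)

    def test_default_minibatch_matches_protocol(self):
        assert P.TrainConfig().minibatch == 54

    def test_empty_patches_rejected(self):
        empty = PatchSet(np.empty((0, 32, 32)), np.empty((0, 32, 32)),
                         np.empty((0, 2), int), [], 32)
        model = P.build_model(P.ModelSpec("edsr_like", width=8, depth=1), seed=0)
        with pytest.raises(InvalidArgumentError):
            P.train(model, empty, empty, P.TrainConfig(minibatch=4, max_steps=5))

    def test_nan_loss_diverged(self):
        x = np.random.default_rng(7).uniform(0, 1, (4, 32, 32))
        bad = x.copy()
        bad[0, 0, 0] = np.nan
        ps = patchset(x, bad)
        model = P.build_model(P.ModelSpec("edsr_like", width=8, depth=1), seed=0)
        with pytest.raises(TrainingDivergedError):
            P.train(model, ps, ps, P.TrainConfig(minibatch=4, max_steps=5, loss="l1"))


class TestInfer:
    def mask_image(self, shape, seed=0):
        rng = np.random.default_rng(seed)
        return P.CartesianImage(rng.uniform(0, 1, shape), np.ones(shape, bool))

    def test_zero_init_edsr_is_identity(self):
        model = P.build_model(P.ModelSpec("edsr_like", width=16, depth=2), seed=0)
        img = self.mask_image((80, 80))
        out = P.infer(model, img)
        assert np.allclose(out.pixels, img.pixels, atol=1e-6)

    @pytest.mark.parametrize("shape", [(128, 128), (125, 121)])
    def test_output_shape(self, shape):
        model = P.build_model(P.ModelSpec("edsr_like", width=8, depth=1), seed=0)
        assert P.infer(model, self.mask_image(shape)).grid_shape == shape

    def test_too_small_input(self):
        model = P.build_model(P.ModelSpec("fsrcnn_like"), seed=0)
        with pytest.raises(InvalidArgumentError):
            P.infer(model, self.mask_image((8, 8)))

    def test_crop_commutes_away_from_borders(self):
        """Fully-convolutional contract: interior pixels do not depend on
        context beyond the receptive field."""
        model = P.build_model(P.ModelSpec("fsrcnn_like", width=8, shrink=4, depth=1), seed=3)
        big = self.mask_image((96, 96), seed=1)
        r = model.receptive_field
        inner = P.CartesianImage(big.pixels[16:80, 16:80], np.ones((64, 64), bool))
        out_big = P.infer(model, big).pixels[16 + r : 80 - r, 16 + r : 80 - r]
        out_inner = P.infer(model, inner).pixels[r : 64 - r, r : 64 - r]
        assert np.abs(out_big - out_inner).max() < 1e-5

    def test_fov_mask_propagated(self, phantom_pair):
        model = P.build_model(P.ModelSpec("edsr_like", width=8, depth=1), seed=0)
        out = P.infer(model, phantom_pair.lr)
        assert np.array_equal(out.fov_mask, phantom_pair.lr.fov_mask)
        assert np.all(out.pixels[~out.fov_mask] == 0.0)


class TestBaselines:
    def test_sharpen_amount_zero_identity(self, phantom_pair):
        img = P.rescale_unit(phantom_pair.lr)
        out = P.baseline_sharpen(img, amount=0.0)
        assert np.allclose(out.pixels[out.fov_mask], img.pixels[img.fov_mask])

    def test_sharpen_constant_unchanged(self):
        img = P.CartesianImage(np.full((32, 32), 0.5), np.ones((32, 32), bool))
        out = P.baseline_sharpen(img, amount=1.0, radius=2.0)
        assert np.allclose(out.pixels, 0.5)

    def test_sharpen_raises_contrast(self, phantom_pair):
        img = P.rescale_unit(phantom_pair.hr)
        out = P.baseline_sharpen(img, amount=1.0, radius=2.0)
        assert P.gcf(out) > P.gcf(img)

    def test_wiener_defaults(self):
        import inspect

        sig = inspect.signature(P.baseline_wiener)
        assert sig.parameters["psf_sigma"].default == 2.0

    def test_wiener_large_nsr_kills_signal(self, phantom_pair):
        img = P.rescale_unit(phantom_pair.hr)
        out = P.baseline_wiener(img, psf_sigma=2.0, nsr=1e9)
        assert np.abs(out.pixels).max() < 1e-3

    def test_wiener_restores_gaussian_blur(self):
        # periodic blur matches the filter's circular-convolution model
        rng = np.random.default_rng(8)
        x = gaussian_filter(rng.uniform(0, 1, (64, 64)), 1.0, mode="wrap")
        x = (x - x.min()) / np.ptp(x)
        blurred = gaussian_filter(x, 2.0, mode="wrap")
        img = P.CartesianImage(blurred, np.ones((64, 64), bool))
        restored = P.baseline_wiener(img, psf_sigma=2.0, nsr=1e-4)
        assert np.abs(restored.pixels - x).mean() < np.abs(blurred - x).mean()


def test_checkpoint_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    ps = patchset(rng.uniform(0, 1, (6, 32, 32)))
    model = P.build_model(P.ModelSpec("edsr_like", width=8, depth=1), seed=4)
    cfg = P.TrainConfig(minibatch=4, max_steps=10, loss="l1", seed=0, val_every=5)
    model, hist = P.train(model, ps, ps, cfg)
    P.save_checkpoint(tmp_path / "ckpt", model, cfg, hist)
    back, cfg2 = P.load_checkpoint(tmp_path / "ckpt")
    assert cfg2 == cfg
    assert all(np.array_equal(p, q) for p, q in zip(model.params(), back.params()))
    x = rng.uniform(0, 1, (1, 48, 48))
    assert np.array_equal(model.forward(x), back.forward(x))
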
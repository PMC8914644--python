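import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from trapcount import (
    GeneratorConfig,
    ModelConfig,
    augment_image,
    bank_from_config,
    build_count_regressor,
    build_dataset,
    load_regressor,
    make_backgrounds,
    preprocess_image,
    render_split,
    save_regressor,
    train_regressor,
)

TINY = ModelConfig(input_size=(32, 32, 1), channels=(4, 8), batch_size=16, max_epochs=5, patience=5, seed=0)


class TestPreprocess:
    def test_rgb_resized_to_grayscale_unit_range(self):
        rgb = np.random.default_rng(0).integers(0, 256, (480, 640, 3), dtype=np.uint8)
        out = preprocess_image(rgb, (240, 240, 1))
        assert out.shape == (240, 240, 1)
        assert out.dtype == np.float32
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_constant_gray_preserved(self):
        gray = np.full((100, 300), 0.37, dtype=np.float32)
        out = preprocess_image(gray, (64, 64, 1))
        assert np.allclose(out, 0.37, atol=1e-6)

    def test_conforming_input_is_fixed_point(self):
        x = np.random.default_rng(1).random((240, 240)).astype(np.float32)
        out = preprocess_image(x, (240, 240, 1))
        assert np.array_equal(out[..., 0], x)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty image"):
            preprocess_image(np.zeros((0, 0)), (64, 64, 1))


class TestAugment:
    def test_zero_probabilities_are_identity(self):
        cfg = dataclasses.replace(TINY, aug_flip_h=0, aug_flip_v=0, aug_rotation=0, aug_zoom=0)
        x = np.random.default_rng(0).random((32, 32, 1)).astype(np.float32)
        assert np.array_equal(augment_image(x, np.random.default_rng(1), cfg), x)

    def test_flip_is_an_involution(self):
        cfg = dataclasses.replace(TINY, aug_flip_h=1.0, aug_flip_v=0, aug_rotation=0, aug_zoom=0)
        x = np.random.default_rng(0).random((32, 32, 1)).astype(np.float32)
        once = augment_image(x, np.random.default_rng(1), cfg)
        twice = augment_image(once, np.random.default_rng(1), cfg)
        assert np.array_equal(twice, x)

    def test_seeded_determinism(self):
        x = np.random.default_rng(0).random((32, 32, 1)).astype(np.float32)
        a = augment_image(x, np.random.default_rng(42), TINY)
        b = augment_image(x, np.random.default_rng(42), TINY)
        assert np.array_equal(a, b)

    def test_rotation_and_flips_preserve_insect_count(self, desk_config, desk_bank, desk_backgrounds):
        """Augmented scenes keep their connected-component count: rotation
        expands the canvas before resizing back, so nothing leaves the frame."""
        from trapcount import compose_scene

        cfg = dataclasses.replace(desk_config, jitter_enabled=False)
        mcfg = dataclasses.replace(ModelConfig.desk_scale(), aug_zoom=0)
        rng = np.random.default_rng(3)
        checked = 0
        for i in range(100):
            count = int(rng.integers(1, 7))
            rec = compose_scene(desk_backgrounds, desk_bank, count, int(rng.integers(2**31)), config=cfg)
            x = preprocess_image(rec.image, mcfg.input_size)
            aug = augment_image(x, rng, mcfg)[..., 0]
            comps = ndimage.label(aug < 0.62, structure=np.ones((3, 3), int))[1]
            checked += int(comps == count)
        assert checked >= 95  # bilinear resampling may rarely merge close neighbours


class TestRegressor:
    def test_scalar_output_shape(self):
        model = build_count_regressor(TINY)
        x = np.random.default_rng(0).random((4, 32, 32, 1)).astype(np.float32)
        y, _ = model.forward(x)
        assert y.shape == (4,) and np.isfinite(y).all()

    def test_default_model_fits_8bit_budget(self):
        model = build_count_regressor(ModelConfig())
        est_bytes = model.n_params + 3 * sum(l["b"].size for l in model.conv_weights) + 4096
        assert est_bytes <= 0.55 * 1024 * 1024

    def test_seeded_init_identical(self):
        a = build_count_regressor(TINY)
        b = build_count_regressor(TINY)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_backward_matches_numeric_gradient(self):
        """Central-difference check of the analytic gradients on a tiny net."""
        cfg = ModelConfig(input_size=(8, 8, 1), channels=(2, 3), seed=1)
        model = build_count_regressor(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((3, 8, 8, 1), dtype=np.float32)
        y = np.array([1.0, 2.0, 0.0], dtype=np.float32)

        def loss():
            pred, _ = model.forward(x)
            return float(np.mean((pred - y) ** 2))

        pred, cache = model.forward(x, want_cache=True)
        grads = model.backward((2.0 / 3) * (pred - y).astype(np.float32), cache)
        params = model.parameters()
        eps = 1e-3
        rng2 = np.random.default_rng(5)
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                num = (up - down) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(num, abs=2e-3)

    def test_prediction_finite_and_batch_consistent(self):
        model = build_count_regressor(TINY)
        imgs = np.random.default_rng(0).integers(0, 256, (5, 32, 32), dtype=np.uint8)
        with pytest.warns(UserWarning, match="not trained"):
            batch = model.predict(imgs)
        with pytest.warns(UserWarning):
            singles = np.array([model.predict(im) for im in imgs])
        assert np.isfinite(batch).all()
        assert np.allclose(batch, singles, atol=1e-5)

    def test_save_load_roundtrip(self, tmp_path):
        model = build_count_regressor(TINY)
        model.trained = True
        save_regressor(model, tmp_path / "m.tcf")
        clone = load_regressor(tmp_path / "m.tcf")
        x = np.random.default_rng(0).integers(0, 256, (3, 32, 32), dtype=np.uint8)
        assert np.allclose(model.predict(x), clone.predict(x))


@pytest.fixture(scope="module")
def easy_data():
    cfg = GeneratorConfig.desk_scale(seed=5, image_size=32, train_pool_per_class=20, test_per_class=4)
    bank = bank_from_config(cfg)
    man = build_dataset(cfg)
    xtr, ytr = render_split(man, "train", bank=bank)
    xval, yval = render_split(man, "val", bank=bank)
    return xtr, ytr, xval, yval


class TestTraining:

    def test_loss_decreases_early(self, easy_data):
        cfg = dataclasses.replace(TINY, max_epochs=6)
        model = build_count_regressor(cfg)
        train_regressor(model, easy_data, cfg)
        losses = [h["train_loss"] for h in model.history[:6]]
        drops = sum(b <= a for a, b in zip(losses, losses[1:]))
        assert drops >= 4  # at least 4 of the first 5 transitions non-increasing

    def test_single_class_collapse(self, easy_data):
        """Trained only on empty scenes, the regressor predicts ~0 on held-out
        empty scenes."""
        xtr, ytr, xval, yval = easy_data
        zt = ytr == 0
        zv = yval == 0
        cfg = dataclasses.replace(TINY, max_epochs=8, seed=2)
        model = build_count_regressor(cfg)
        train_regressor(model, (xtr[zt], ytr[zt], xval[zv], yval[zv]), cfg)
        preds = model.predict(xval[zv])
        assert np.all(preds < 0.5)

    def test_missing_split_rejected(self, easy_data):
        xtr, ytr, _, _ = easy_data
        model = build_count_regressor(TINY)
        with pytest.raises(ValueError, match="missing split"):
            train_regressor(model, (xtr, ytr, xtr[:0], ytr[:0]), TINY)

    def test_history_and_early_stop_bookkeeping(self, easy_data):
        model = build_count_regressor(TINY)
        train_regressor(model, easy_data, TINY)
        assert model.trained
        assert 0 < len(model.history) <= TINY.max_epochs
        assert model.stopped_epoch == len(model.history) - 1
        assert all(np.isfinite(h["train_loss"]) for h in model.history)
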
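import numpy as np
import pytest

from trapcount import (
    GeneratorConfig,
    ModelConfig,
    bank_from_config,
    build_count_regressor,
    build_dataset,
    evaluate_counts,
    make_backgrounds,
    quantize_model,
    render_split,
    train_regressor,
)


@pytest.fixture(scope="session")
def desk_config():
    return GeneratorConfig.desk_scale(seed=0)


@pytest.fixture(scope="session")
def desk_bank(desk_config):
    return bank_from_config(desk_config)


@pytest.fixture(scope="session")
def desk_backgrounds(desk_config):
    return make_backgrounds(desk_config)


@pytest.fixture(scope="session")
def mini_manifest():
    """A small dataset (20/class pool, 5/class test) for fast structural tests."""
    cfg = GeneratorConfig.desk_scale(seed=3, train_pool_per_class=20, test_per_class=5)
    return build_dataset(cfg)


@pytest.fixture(scope="session")
def scaled_run():
    """The full reduced-scale study: generate scenes, train the regressor,
    quantize it, and evaluate both models on the held-out test split.

    Session-scoped because training takes a few minutes; every test that
    needs a trained model shares this one run (seed pinned to 0).
    """
    seed = 0
    gcfg = GeneratorConfig.desk_scale(seed=seed)
    bank = bank_from_config(gcfg)
    manifest = build_dataset(gcfg)
    xtr, ytr = render_split(manifest, "train", bank=bank)
    xval, yval = render_split(manifest, "val", bank=bank)
    xte, yte = render_split(manifest, "test", bank=bank)
    mcfg = ModelConfig.desk_scale(seed=seed)
    model = build_count_regressor(mcfg)
    train_regressor(model, (xtr, ytr, xval, yval), mcfg)
    # Calibration sample spans all count classes (a seeded uniform draw).
    sel = np.random.default_rng(seed).choice(len(xtr), 128, replace=False)
    quant = quantize_model(model, xtr[sel], 128)
    return {
        "gcfg": gcfg,
        "mcfg": mcfg,
        "bank": bank,
        "manifest": manifest,
        "model": model,
        "quant": quant,
        "train": (xtr, ytr),
        "test": (xte, yte),
        "report_float": evaluate_counts(yte, model.predict(xte)),
        "report_quant": evaluate_counts(yte, quant.predict(xte)),
    }
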
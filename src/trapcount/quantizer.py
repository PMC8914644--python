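"""Post-training 8-bit quantization of the counting regressor.

To fit a microcontroller's memory, the trained float32 network is converted to
8-bit integer weights with activation ranges calibrated on a representative
sample of training images (full-integer post-training quantization, with
float32 kept at the input/output interface).  Weights are quantized
per-tensor, symmetric int8; activations per-tensor, asymmetric uint8; biases
int32 at the product scale ``s_weight * s_input`` — the standard fixed-point
scheme for integer-only inference engines.

Inference through the quantized model evaluates the network on the exact
dequantized grid values, so its predictions are what an integer engine with a
float I/O fallback would produce, and its serialized artifact (int8/int32
tensors plus scale metadata) is what such an engine would load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .count_model import (
    CountRegressor,
    ModelConfig,
    _conv_forward,
    _pool_forward,
    _read_container,
    _write_container,
    preprocess_image,
    save_regressor,
)
from .evaluator import evaluate_counts

__all__ = [
    "QuantizedRegressor",
    "quantize_model",
    "load_quantized",
    "compare_models",
]

_QUANT_MAGIC = b"TCQ1"


def _act_qparams(lo: float, hi: float) -> tuple[float, int]:
    """Asymmetric uint8 scale/zero-point covering [lo, hi] (0 always exact)."""
    lo, hi = min(lo, 0.0), max(hi, 0.0)
    scale = (hi - lo) / 255.0
    if scale == 0.0:
        return 1.0, 0
    zp = int(round(-lo / scale))
    return float(scale), int(np.clip(zp, 0, 255))


def _fake_quant(x: np.ndarray, scale: float, zp: int) -> np.ndarray:
    q = np.clip(np.round(x / scale) + zp, 0, 255)
    return ((q - zp) * scale).astype(np.float32)


@dataclass
class QuantizedRegressor:
    """The 8-bit counterpart of a :class:`CountRegressor`."""

    config: ModelConfig
    conv_layers: list[dict]  # {"Wq" int8, "bq" int32, "w_scale", "b_scale"}
    head: dict
    act_scales: list[tuple[float, int]]  # per activation tensor: (scale, zero_point)
    calibration_spec: dict = field(default_factory=dict)
    size_bytes: int = 0
    model_id: str = "count_regressor_int8"

    def _forward(self, x: np.ndarray) -> np.ndarray:
        s, zp = self.act_scales[0]
        # the input centering shift folds into the input zero-point on-device
        a = _fake_quant(x, s, zp) - self.config.input_shift
        for i, l in enumerate(self.conv_layers):
            w = l["Wq"].astype(np.float32) * l["w_scale"]
            b = l["bq"].astype(np.float32) * l["b_scale"]
            z, _ = _conv_forward(a, w, b)
            r = np.maximum(z, 0.0)
            p, _ = _pool_forward(r)
            s, zp = self.act_scales[i + 1]
            a = _fake_quant(p, s, zp)
        g = a.sum(axis=(1, 2))
        w = self.head["Wq"].astype(np.float32) * self.head["w_scale"]
        b = self.head["bq"].astype(np.float32) * self.head["b_scale"]
        return (g @ w + b)[:, 0]

    def predict(self, images, batch_size: int = 64) -> np.ndarray:
        arr = np.asarray(images)
        single = arr.ndim == 2 or (arr.ndim == 3 and arr.shape[-1] in (1, 3))
        batch = [arr] if single else list(arr)
        x = np.stack([preprocess_image(im, self.config.input_size) for im in batch])
        outs = [self._forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
        preds = np.concatenate(outs)
        return float(preds[0]) if single else preds

    def save(self, path: str | Path) -> int:
        header = {
            "config": self.config.to_dict(),
            "act_scales": [[float(s), int(z)] for s, z in self.act_scales],
            "w_scales": [float(l["w_scale"]) for l in self.conv_layers] + [float(self.head["w_scale"])],
            "b_scales": [float(l["b_scale"]) for l in self.conv_layers] + [float(self.head["b_scale"])],
            "calibration_spec": self.calibration_spec,
        }
        arrays = []
        for l in self.conv_layers:
            arrays += [l["Wq"], l["bq"]]
        arrays += [self.head["Wq"], self.head["bq"]]
        self.size_bytes = _write_container(path, _QUANT_MAGIC, header, arrays)
        return self.size_bytes


def load_quantized(path: str | Path) -> QuantizedRegressor:
    header, arrays = _read_container(path, _QUANT_MAGIC)
    config = ModelConfig.from_dict(header["config"])
    pairs = [(arrays[i], arrays[i + 1]) for i in range(0, len(arrays), 2)]
    conv_layers = [
        {"Wq": w, "bq": b, "w_scale": ws, "b_scale": bs}
        for (w, b), ws, bs in zip(pairs[:-1], header["w_scales"][:-1], header["b_scales"][:-1])
    ]
    head = {
        "Wq": pairs[-1][0],
        "bq": pairs[-1][1],
        "w_scale": header["w_scales"][-1],
        "b_scale": header["b_scales"][-1],
    }
    return QuantizedRegressor(
        config=config,
        conv_layers=conv_layers,
        head=head,
        act_scales=[(float(s), int(z)) for s, z in header["act_scales"]],
        calibration_spec=header.get("calibration_spec", {}),
        size_bytes=Path(path).stat().st_size,
    )


def quantize_model(
    model: CountRegressor,
    calibration_images,
    n_cal: int = 128,
    path: str | Path | None = None,
) -> QuantizedRegressor:
    """Quantize a trained regressor to 8 bits.

    ``calibration_images`` is a stack (or list) of representative images from
    the training split; the first ``n_cal`` are run through the float network
    to record per-tensor activation ranges.  Writing to ``path`` records the
    serialized size; otherwise the artifact can be saved later.
    """
    cal = list(calibration_images)[:n_cal] if not isinstance(calibration_images, np.ndarray) else calibration_images[:n_cal]
    if len(cal) == 0:
        raise ValueError("calibration set required")
    if n_cal < 16:
        raise ValueError("calibration set required: need at least 16 representative images")

    lo = None
    hi = None
    for i in range(0, len(cal), 32):
        x = np.stack([preprocess_image(im, model.config.input_size) for im in cal[i:i + 32]])
        ranges: list[tuple[float, float]] = []
        model.forward(x, ranges=ranges)
        if lo is None:
            lo = [r[0] for r in ranges]
            hi = [r[1] for r in ranges]
        else:
            lo = [min(a, r[0]) for a, r in zip(lo, ranges)]
            hi = [max(a, r[1]) for a, r in zip(hi, ranges)]
    act_scales = [_act_qparams(a, b) for a, b in zip(lo, hi)]

    conv_layers = []
    for i, l in enumerate(model.conv_weights):
        w_scale = float(np.abs(l["W"]).max() / 127.0) or 1.0
        in_scale = act_scales[i][0]
        b_scale = w_scale * in_scale
        conv_layers.append(
            {
                "Wq": np.clip(np.round(l["W"] / w_scale), -127, 127).astype(np.int8),
                "bq": np.round(l["b"] / b_scale).astype(np.int32),
                "w_scale": w_scale,
                "b_scale": b_scale,
            }
        )
    w_scale = float(np.abs(model.head["W"]).max() / 127.0) or 1.0
    b_scale = w_scale * act_scales[-1][0]
    head = {
        "Wq": np.clip(np.round(model.head["W"] / w_scale), -127, 127).astype(np.int8),
        "bq": np.round(model.head["b"] / b_scale).astype(np.int32),
        "w_scale": w_scale,
        "b_scale": b_scale,
    }
    quant = QuantizedRegressor(
        config=model.config,
        conv_layers=conv_layers,
        head=head,
        act_scales=act_scales,
        calibration_spec={"n_cal": int(len(cal)), "source": "training split"},
    )
    if path is not None:
        quant.save(path)
    return quant


def compare_models(
    float_model: CountRegressor,
    quant_model: QuantizedRegressor,
    test_data,
    workdir: str | Path | None = None,
) -> dict:
    """Accuracy/size comparison of the float model and its 8-bit counterpart.

    ``test_data`` is a ``(images, counts)`` pair or a dataset manifest whose
    test split is rendered.  Serialized sizes are the actual on-disk byte
    counts of both artifacts (written into ``workdir`` if not saved yet).
    """
    if tuple(float_model.config.input_size) != tuple(quant_model.config.input_size):
        raise ValueError("incompatible models: input sizes differ")
    if isinstance(test_data, tuple):
        images, counts = test_data
    else:
        from .scene_composer import render_split

        images, counts = render_split(test_data, "test")
    rep_f = evaluate_counts(counts, float_model.predict(images), model_id=float_model.model_id)
    rep_q = evaluate_counts(counts, quant_model.predict(images), model_id=quant_model.model_id)

    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir is not None else Path(tmp)
        base.mkdir(parents=True, exist_ok=True)
        if hasattr(float_model, "save"):  # also accepts two int8 models
            float_size = float_model.save(base / "model_count_a.tcq")
        else:
            float_size = save_regressor(float_model, base / "model_count_float.tcf")
        quant_size = quant_model.save(base / "model_count_quant.tcq")
    return {
        "alpha_float": rep_f.mean_alpha,
        "alpha_quant": rep_q.mean_alpha,
        "alpha_delta_abs": abs(rep_f.mean_alpha - rep_q.mean_alpha),
        "float_size_bytes": float_size,
        "quant_size_bytes": quant_size,
        "per_class_alpha_float": rep_f.per_class_alpha,
        "per_class_alpha_quant": rep_q.per_class_alpha,
    }
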
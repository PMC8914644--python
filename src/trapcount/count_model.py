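"""The counting-by-regression CNN and its training recipe.

Counting insects in a trap image is posed as scalar regression: the network
maps a grayscale image straight to a real-valued count, skipping localization,
segmentation and species recognition entirely.  Regression heads are compact —
the whole model must fit a microcontroller's memory after 8-bit quantization —
and are reported to be more robust to partially overlapping insects than
detect-then-count pipelines.

The architecture is a stack of 3x3 conv + ReLU + 2x2 max-pool blocks, a global
sum pool, and a single linear output unit.  Sum (not average) pooling is the
natural head for counting: the count is an extensive quantity, the spatial
integral of a learned insect-density map, so the target scale is reachable
without inflating the head weights.  The head is linear
(unbounded); negative raw outputs are handled at rounding time so the MSE
gradient stays unconstrained.  Training follows the standard recipe for this
model family: MSE loss, Adam(lr 0.001, beta1 0.9, beta2 0.999), batch size 32,
augmentation by random flips (p 0.5 each), rotation (p 0.5) and zoom (p 0.2),
with early stopping regulated by validation counting accuracy.

Everything here — forward, backward, Adam — is plain NumPy, sized for a model
of well under a million parameters where framework overhead would dwarf the
arithmetic.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .evaluator import evaluate_counts

__all__ = [
    "ModelConfig",
    "CountRegressor",
    "preprocess_image",
    "augment_image",
    "build_count_regressor",
    "train_regressor",
    "save_regressor",
    "load_regressor",
]

_LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float64)  # ITU-R 601


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``channels`` lists the conv-block widths; each block halves the spatial
    resolution, so ``input_size`` must be divisible by ``2 ** len(channels)``.
    The default four-block stack has ~98k parameters, i.e. ~0.1 MB at 8 bits —
    comfortably inside a 0.55 MB microcontroller budget.
    """

    input_size: tuple[int, int, int] = (240, 240, 1)
    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3
    learning_rate: float = 1e-3
    beta_1: float = 0.9
    beta_2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 32
    max_epochs: int = 240
    patience: int = 20
    aug_flip_h: float = 0.5
    aug_flip_v: float = 0.5
    aug_rotation: float = 0.5
    aug_zoom: float = 0.2
    rotation_range_deg: float = 20.0
    zoom_range: tuple[float, float] = (0.8, 1.2)
    input_shift: float = 0.5  # fixed centering subtracted from [0,1] inputs
    head_bias_init: float = 3.0  # midpoint of the 0-6 count range
    seed: int = 0

    def __post_init__(self) -> None:
        h, w, c = self.input_size
        if c != 1:
            raise ValueError("invalid head: model is single-channel grayscale")
        div = 2 ** len(self.channels)
        if h % div or w % div:
            raise ValueError(f"input size must be divisible by {div}")

    @classmethod
    def desk_scale(cls, seed: int = 0, max_epochs: int = 30) -> "ModelConfig":
        """Single-CPU end-to-end configuration: 64x64 input, a three-block
        (16, 32, 64) stack and a 30-epoch cap.  At this scene size the
        four-block stack's extra capacity only overfits the per-sprite
        appearance of the 70 training insects."""
        return cls(
            input_size=(64, 64, 1),
            channels=(16, 32, 64),
            max_epochs=max_epochs,
            patience=8,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("input_size", "channels", "zoom_range"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Image preprocessing and augmentation
# ---------------------------------------------------------------------------

def _resize_bilinear(x: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a float32 (H, W) array to (rows, cols)."""
    if x.shape == size:
        return x
    im = Image.fromarray(np.ascontiguousarray(x, dtype=np.float32), mode="F")
    return np.asarray(im.resize((size[1], size[0]), Image.BILINEAR), dtype=np.float32)


def preprocess_image(raster: np.ndarray, input_size: tuple[int, int, int] = (240, 240, 1)) -> np.ndarray:
    """Convert any raster to the model's input tensor.

    Color images are reduced to luminance (ITU-R 601), the result is resized
    bilinearly to the configured square resolution and scaled to [0, 1].
    Already-conforming inputs pass through unchanged.
    """
    a = np.asarray(raster)
    if a.size == 0:
        raise ValueError("empty image")
    if a.dtype == np.uint8:
        a = a.astype(np.float32) / 255.0
    if a.ndim == 3 and a.shape[-1] == 1:
        a = a[..., 0]
    if a.ndim == 3:
        a = a[..., :3] @ _LUMA
    a = np.asarray(a, dtype=np.float32)
    a = _resize_bilinear(a, (input_size[0], input_size[1]))
    return a[..., None]


def augment_image(tensor: np.ndarray, rng: np.random.Generator, config: ModelConfig) -> np.ndarray:
    """Label-preserving augmentation of one model input.

    Flips, rotation and zoom are applied independently with their configured
    probabilities.  Rotation expands the canvas first and resizes back so no
    insect is ever rotated out of frame (the count label survives exactly);
    blank corners are filled with the median border luminance.
    """
    x = tensor[..., 0] if tensor.ndim == 3 else tensor
    h, w = x.shape
    if config.aug_flip_h and rng.random() < config.aug_flip_h:
        x = x[:, ::-1]
    if config.aug_flip_v and rng.random() < config.aug_flip_v:
        x = x[::-1, :]
    fill = float(np.median(np.concatenate([x[0], x[-1], x[:, 0], x[:, -1]])))
    if config.aug_rotation and rng.random() < config.aug_rotation:
        angle = float(rng.uniform(-config.rotation_range_deg, config.rotation_range_deg))
        x = ndimage.rotate(x, angle, reshape=True, order=1, cval=fill)
        x = _resize_bilinear(np.clip(x, 0.0, 1.0), (h, w))
    if config.aug_zoom and rng.random() < config.aug_zoom:
        z = float(rng.uniform(*config.zoom_range))
        nh, nw = max(8, round(h * z)), max(8, round(w * z))
        scaled = _resize_bilinear(x, (nh, nw))
        if z < 1.0:  # shrink and pad: everything stays in frame
            out = np.full((h, w), fill, dtype=np.float32)
            r0, c0 = (h - nh) // 2, (w - nw) // 2
            out[r0:r0 + nh, c0:c0 + nw] = scaled
            x = out
        else:  # magnify and center-crop
            r0, c0 = (nh - h) // 2, (nw - w) // 2
            x = scaled[r0:r0 + h, c0:c0 + w]
    x = np.ascontiguousarray(np.clip(x, 0.0, 1.0), dtype=np.float32)
    return x[..., None] if tensor.ndim == 3 else x


# ---------------------------------------------------------------------------
# Layer primitives (NCHW is avoided: all tensors are N, H, W, C float32)
# ---------------------------------------------------------------------------

def _conv_forward(x, W, b):
    """'Same' 3x3 convolution as k*k shifted (Cin, Cout) matmuls.

    Shifted matmuls keep every product inside BLAS without materializing
    im2col patch matrices, which dominates runtime for these small channel
    counts.
    """
    n, h, w, cin = x.shape
    k = W.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    z = np.empty((n, h, w, W.shape[-1]), dtype=np.float32)
    z[:] = b
    for i in range(k):
        for j in range(k):
            z += xp[:, i:i + h, j:j + w, :] @ W[i, j]
    return z, xp


def _conv_backward(dout, xp, x_shape, W):
    n, h, w, cin = x_shape
    k = W.shape[0]
    p = k // 2
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            patch = xp[:, i:i + h, j:j + w, :]
            dW[i, j] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i:i + h, j:j + w, :] += dout @ W[i, j].T
    db = dout.sum(axis=(0, 1, 2))
    return dxp[:, p:p + h, p:p + w, :], dW, db


def _pool_forward(x):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx


def _pool_backward(dout, idx, x_shape):
    n, h, w, c = x_shape
    dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=np.float32)
    np.put_along_axis(dxr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    return dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)


# ---------------------------------------------------------------------------
# The regressor
# ---------------------------------------------------------------------------

@dataclass
class CountRegressor:
    """Float32 counting network: weights, config, and training history."""

    config: ModelConfig
    conv_weights: list[dict] = field(default_factory=list)  # {"W","b"} per block
    head: dict = field(default_factory=dict)  # {"W": (C,1), "b": (1,)}
    history: list[dict] = field(default_factory=list)
    stopped_epoch: int = -1
    trained: bool = False
    model_id: str = "count_regressor_float"

    @property
    def n_params(self) -> int:
        n = sum(l["W"].size + l["b"].size for l in self.conv_weights)
        return n + self.head["W"].size + self.head["b"].size

    def parameters(self) -> list[np.ndarray]:
        out = []
        for l in self.conv_weights:
            out += [l["W"], l["b"]]
        out += [self.head["W"], self.head["b"]]
        return out

    def forward(self, x: np.ndarray, want_cache: bool = False, ranges: list | None = None):
        """Run a (N, H, W, 1) batch; optionally keep the backward cache or
        record per-layer activation min/max (for quantization calibration)."""
        cache = {"x": x, "convs": []} if want_cache else None
        if ranges is not None:
            ranges.append((float(x.min()), float(x.max())))
        a = x - self.config.input_shift
        for l in self.conv_weights:
            z, xp = _conv_forward(a, l["W"], l["b"])
            r = np.maximum(z, 0.0)
            p, idx = _pool_forward(r)
            if want_cache:
                cache["convs"].append({"a_shape": a.shape, "xp": xp, "z": z, "idx": idx, "r_shape": r.shape})
            if ranges is not None:
                ranges.append((float(p.min()), float(p.max())))
            a = p
        g = a.sum(axis=(1, 2))
        y = (g @ self.head["W"] + self.head["b"])[:, 0]
        if want_cache:
            cache["g"] = g
            cache["a_final_shape"] = a.shape
        return y, cache

    def backward(self, dloss_dy: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Gradients in the same order as :meth:`parameters`."""
        g = cache["g"]
        dy = dloss_dy[:, None]  # (N,1)
        dWd = g.T @ dy
        dbd = dy.sum(axis=0)
        dg = dy @ self.head["W"].T  # (N,C)
        n, hf, wf, cf = cache["a_final_shape"]
        da = np.broadcast_to(dg[:, None, None, :], (n, hf, wf, cf)).astype(np.float32)
        grads_rev = [dbd.astype(np.float32), dWd.astype(np.float32)]
        for l, cc in zip(reversed(self.conv_weights), reversed(cache["convs"])):
            dr = _pool_backward(da, cc["idx"], cc["r_shape"])
            dz = dr * (cc["z"] > 0)
            da, dW, db = _conv_backward(dz, cc["xp"], cc["a_shape"], l["W"])
            grads_rev += [db.astype(np.float32), dW.astype(np.float32)]
        return list(reversed(grads_rev))

    def predict(self, images, batch_size: int = 64) -> np.ndarray:
        """Raw scalar count predictions for one image or a stack of images.

        Accepts uint8 or float rasters of any size; each is preprocessed to
        the model's input resolution.  Rounding to integers is the
        evaluator's job.
        """
        if not self.trained:
            warnings.warn("model not trained; predictions are from initial weights", stacklevel=2)
        arr = np.asarray(images)
        # (H, W) and (H, W, 1|3) are single images; anything else is a stack.
        single = arr.ndim == 2 or (arr.ndim == 3 and arr.shape[-1] in (1, 3))
        batch = [arr] if single else list(arr)
        x = np.stack([preprocess_image(im, self.config.input_size) for im in batch])
        outs = []
        for i in range(0, len(x), batch_size):
            y, _ = self.forward(x[i:i + batch_size])
            outs.append(y)
        preds = np.concatenate(outs)
        return float(preds[0]) if single else preds


def build_count_regressor(config: ModelConfig | None = None) -> CountRegressor:
    """Initialize the network (Glorot-uniform, seeded) without training it."""
    config = config or ModelConfig()
    rng = np.random.default_rng(config.seed)
    conv_weights = []
    cin = 1
    k = config.kernel
    for cout in config.channels:
        limit = np.sqrt(6.0 / (k * k * cin + k * k * cout))
        conv_weights.append(
            {
                "W": rng.uniform(-limit, limit, size=(k, k, cin, cout)).astype(np.float32),
                "b": np.zeros(cout, dtype=np.float32),
            }
        )
        cin = cout
    limit = np.sqrt(6.0 / (cin + 1))
    head = {
        "W": rng.uniform(-limit, limit, size=(cin, 1)).astype(np.float32),
        "b": np.full(1, config.head_bias_init, dtype=np.float32),
    }
    return CountRegressor(config=config, conv_weights=conv_weights, head=head)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, b1: float, b2: float, eps: float):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _as_input_batch(images: np.ndarray, input_size) -> np.ndarray:
    return np.stack([preprocess_image(im, input_size) for im in images])


def train_regressor(
    model: CountRegressor,
    data,
    config: ModelConfig | None = None,
    bank=None,
    verbose: bool = False,
) -> CountRegressor:
    """Train with MSE + Adam, monitoring validation counting accuracy.

    ``data`` is either a :class:`~trapcount.scene_composer.DatasetManifest`
    (its train/val splits are rendered) or a ready-made tuple
    ``(train_images, train_counts, val_images, val_counts)``.  Augmentation is
    applied to training inputs only.  Training stops at ``max_epochs`` or when
    validation mean α has not improved for ``patience`` epochs; the best-val
    weights are restored.
    """
    config = config or model.config
    if isinstance(data, tuple):
        xtr_raw, ytr, xval_raw, yval = data
    else:
        from .scene_composer import render_split

        xtr_raw, ytr = render_split(data, "train", bank=bank)
        xval_raw, yval = render_split(data, "val", bank=bank)
    if len(xtr_raw) == 0 or len(xval_raw) == 0:
        raise ValueError("missing split: train and val must both be non-empty")
    ytr = np.asarray(ytr, dtype=np.float32)
    xval = _as_input_batch(xval_raw, config.input_size)
    yval = np.asarray(yval)

    root = np.random.SeedSequence([config.seed, 20201])
    best_alpha = -np.inf
    best_weights = None
    best_epoch = -1
    adam = _Adam(model.parameters(), config.learning_rate, config.beta_1, config.beta_2, config.epsilon)
    model.history = []

    n = len(xtr_raw)
    for epoch in range(config.max_epochs):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20201, epoch]))
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            xb = np.stack(
                [
                    augment_image(preprocess_image(xtr_raw[i], config.input_size), rng, config)
                    for i in sel
                ]
            )
            yb = ytr[sel]
            pred, cache = model.forward(xb, want_cache=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            losses.append(loss)
            grads = model.backward((2.0 / len(sel)) * err.astype(np.float32), cache)
            adam.step(model.parameters(), grads)

        val_pred = []
        for i in range(0, len(xval), 64):
            y, _ = model.forward(xval[i:i + 64])
            val_pred.append(y)
        report = evaluate_counts(yval, np.concatenate(val_pred))
        model.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_alpha": report.mean_alpha}
        )
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  val_alpha {report.mean_alpha:.4f}")
        if report.mean_alpha > best_alpha:
            best_alpha = report.mean_alpha
            best_weights = (copy.deepcopy(model.conv_weights), copy.deepcopy(model.head))
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break

    if best_weights is not None:
        model.conv_weights, model.head = best_weights
    model.stopped_epoch = len(model.history) - 1
    model.trained = True
    return model


# ---------------------------------------------------------------------------
# Portable serialization: magic + JSON header + raw little-endian arrays
# ---------------------------------------------------------------------------

def _write_container(path: str | Path, magic: bytes, header: dict, arrays: list[np.ndarray]) -> int:
    header = dict(header)
    header["arrays"] = [{"shape": list(a.shape), "dtype": str(a.dtype)} for a in arrays]
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(magic)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        for a in arrays:
            fh.write(np.ascontiguousarray(a).tobytes())
    return Path(path).stat().st_size


def _read_container(path: str | Path, magic: bytes) -> tuple[dict, list[np.ndarray]]:
    raw = Path(path).read_bytes()
    if raw[:4] != magic:
        raise ValueError(f"not a {magic!r} file: {path}")
    (hlen,) = struct.unpack("<I", raw[4:8])
    header = json.loads(raw[8:8 + hlen].decode())
    arrays = []
    off = 8 + hlen
    for spec in header["arrays"]:
        a = np.frombuffer(raw, dtype=np.dtype(spec["dtype"]), count=int(np.prod(spec["shape"])), offset=off)
        arrays.append(a.reshape(spec["shape"]).copy())
        off += a.nbytes
    return header, arrays


_FLOAT_MAGIC = b"TCF1"


def save_regressor(model: CountRegressor, path: str | Path) -> int:
    """Write the float32 portable graph; returns its size in bytes."""
    header = {
        "config": model.config.to_dict(),
        "trained": model.trained,
        "stopped_epoch": model.stopped_epoch,
    }
    return _write_container(path, _FLOAT_MAGIC, header, model.parameters())


def load_regressor(path: str | Path) -> CountRegressor:
    header, arrays = _read_container(path, _FLOAT_MAGIC)
    config = ModelConfig.from_dict(header["config"])
    model = build_count_regressor(config)
    it = iter(arrays)
    for l in model.conv_weights:
        l["W"], l["b"] = next(it), next(it)
    model.head["W"], model.head["b"] = next(it), next(it)
    model.trained = bool(header.get("trained", False))
    model.stopped_epoch = int(header.get("stopped_epoch", -1))
    return model
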
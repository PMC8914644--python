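"""Composition of labeled trap scenes and construction of the reference dataset.

Each scene is a light "trap floor" background with 0-6 insect sprites pasted
onto it at random rotations and non-overlapping positions, so the true insect
count is known exactly by construction — no manual tagging.  The default
dataset mirrors a balanced reference database: a 14,000-image training pool
(2,000 per count class 0-6) split 70/30 into train/validation at the image
level, plus 1,400 test images (200 per class) composed exclusively from
sprites held out of training.

Scenes are deterministic functions of (config, seed): the manifest stores only
per-scene metadata and seeds, and :func:`render_record` regenerates any scene
bit-for-bit on demand.  PNGs are written only when materializing a dataset to
disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .sprite_bank import (
    MorphologyParams,
    SpriteBank,
    load_sprite_images,
    partition_sprites,
    synthesize_procedural_sprite,
)

__all__ = [
    "GeneratorConfig",
    "Placement",
    "SceneRecord",
    "DatasetManifest",
    "SceneOvercrowdedError",
    "bank_from_config",
    "make_backgrounds",
    "compose_scene",
    "render_record",
    "render_split",
    "build_dataset",
    "write_manifest",
    "read_manifest",
]

_BG_SALT = 7919  # fixed salt separating the background stream from scene streams


class SceneOvercrowdedError(RuntimeError):
    """Raised when a sprite cannot be placed without overlap within max_attempts."""


@dataclass
class GeneratorConfig:
    """Full parameter snapshot for dataset generation.

    ``image_size`` is the square scene resolution in pixels.  Background
    defaults model a light sticky-trap floor: a base gray with low-amplitude
    smooth texture, plus optional per-image brightness jitter (±5%) and faint
    smooth noise emulating backgrounds "that differ slightly".
    """

    image_size: int = 240
    max_count: int = 6
    train_pool_per_class: int = 2000
    test_per_class: int = 200
    train_fraction: float = 0.7  # image-level train/val split of the pool
    n_backgrounds: int = 1
    base_gray: float = 0.82
    background_noise_amp: float = 0.04
    background_noise_scale: float = 12.0
    brightness_jitter: float = 0.05
    jitter_noise_amp: float = 0.01
    jitter_enabled: bool = True
    separation_px: int = 1  # dilation radius used in the overlap test
    max_attempts: int = 200
    seed: int = 0
    sprite_source: dict = field(
        default_factory=lambda: {
            "kind": "procedural",
            "n": 100,
            "seed": 0,
            "train_fraction": 0.7,
            "morphology": None,
        }
    )

    @classmethod
    def desk_scale(cls, seed: int = 0, image_size: int = 64,
                   train_pool_per_class: int = 300, test_per_class: int = 50) -> "GeneratorConfig":
        """A reduced configuration for end-to-end runs on a single CPU."""
        return cls(
            image_size=image_size,
            train_pool_per_class=train_pool_per_class,
            test_per_class=test_per_class,
            seed=seed,
            sprite_source={
                "kind": "procedural",
                "n": 100,
                "seed": seed,
                "train_fraction": 0.7,
                "morphology": None,
            },
        )

    def morphology(self) -> MorphologyParams:
        m = self.sprite_source.get("morphology")
        if m is not None:
            return MorphologyParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in m.items()})
        return MorphologyParams().scaled(self.image_size / 240.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


@dataclass(frozen=True)
class Placement:
    """One sprite placed in a scene: which sprite, how rotated, and where.

    ``anchor`` is the (row, col) of the rotated sprite's top-left corner in
    0-based, row-major background coordinates.
    """

    sprite_index: int
    rotation_deg: float
    anchor: tuple[int, int]


@dataclass
class SceneRecord:
    """One composed trap image with its exact ground-truth count."""

    scene_id: int
    split: str  # train | val | test
    count: int
    background_id: int
    seed: int
    filename: str
    placements: list[Placement] | None = None
    image: np.ndarray | None = None  # uint8 (H, W), populated by render

    def meta_tuple(self) -> tuple:
        return (self.scene_id, self.split, self.count, self.background_id, self.seed, self.filename)


@dataclass
class DatasetManifest:
    """All records of a generated dataset plus the parameters that made it."""

    records: list[SceneRecord]
    per_class_counts: dict[int, int]
    seed: int
    config: GeneratorConfig

    def __post_init__(self) -> None:
        counts: dict[int, int] = {}
        for r in self.records:
            counts[r.count] = counts.get(r.count, 0) + 1
        declared = {int(k): int(v) for k, v in self.per_class_counts.items() if int(v) > 0}
        if counts != declared:
            raise ValueError("per_class_counts disagree with the records")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatasetManifest):
            return NotImplemented
        return (
            self.seed == other.seed
            and self.config.to_dict() == other.config.to_dict()
            and {int(k): v for k, v in self.per_class_counts.items()}
            == {int(k): v for k, v in other.per_class_counts.items()}
            and [r.meta_tuple() for r in self.records] == [r.meta_tuple() for r in other.records]
        )

    def split_records(self, split: str) -> list[SceneRecord]:
        return [r for r in self.records if r.split == split]


# ---------------------------------------------------------------------------
# Sprite bank and backgrounds from a config
# ---------------------------------------------------------------------------

def bank_from_config(config: GeneratorConfig) -> SpriteBank:
    """Build and partition the sprite bank the config describes."""
    src = config.sprite_source
    if src["kind"] == "procedural":
        params = config.morphology()
        seeds = [
            int(np.random.SeedSequence([src["seed"], i]).generate_state(1)[0] % (2**31))
            for i in range(src["n"])
        ]
        bank = SpriteBank(sprites=[synthesize_procedural_sprite(s, params) for s in seeds])
    elif src["kind"] == "directory":
        bank = load_sprite_images(src["path"])
    else:
        raise ValueError(f"unknown sprite source kind: {src['kind']}")
    return partition_sprites(bank, src.get("train_fraction", 0.7), src["seed"])


def _smooth_noise(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    g = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=scale)
    peak = float(np.abs(g).max())
    return (g / peak).astype(np.float32) if peak > 0 else g.astype(np.float32)


def make_backgrounds(config: GeneratorConfig) -> list[np.ndarray]:
    """The bank of base trap-floor textures (uint8), deterministic in the seed."""
    out = []
    for b in range(config.n_backgrounds):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _BG_SALT, b]))
        tex = config.base_gray + config.background_noise_amp * _smooth_noise(
            rng, config.image_size, config.background_noise_scale
        )
        out.append(np.clip(np.round(tex * 255), 0, 255).astype(np.uint8))
    return out


# ---------------------------------------------------------------------------
# Scene composition
# ---------------------------------------------------------------------------

def _rotate_sprite(sprite, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate pixels+mask with canvas expansion; re-binarize alpha at 0.5.

    Bilinear resampling can shave sub-pixel fragments off thin legs; only the
    largest connected component is kept so one sprite stays one blob.
    """
    if angle == 0.0:
        return sprite.pixels, sprite.mask
    pix = ndimage.rotate(sprite.pixels, angle, reshape=True, order=1, cval=0.0)
    alp = ndimage.rotate(sprite.alpha, angle, reshape=True, order=1, cval=0.0)
    mask = alp > 0.5
    if not mask.any():
        return sprite.pixels, sprite.mask
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (int(np.argmax(sizes)) + 1)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return np.clip(pix[sl], 0.0, 1.0), mask[sl]


def compose_scene(
    backgrounds: list[np.ndarray],
    bank: SpriteBank,
    count: int,
    rng_seed: int,
    *,
    sprite_pool: list[int] | None = None,
    config: GeneratorConfig | None = None,
    split: str = "train",
    scene_id: int = 0,
    placement_salt: int = 0,
) -> SceneRecord:
    """Compose one labeled scene deterministically from ``rng_seed``.

    The background index and illumination jitter depend only on ``rng_seed``;
    sprite choice, rotations and anchors additionally depend on
    ``placement_salt`` so a caller can retry an overcrowded scene without
    changing its background.  Raises :class:`SceneOvercrowdedError` when a
    sprite cannot be placed disjointly within ``max_attempts`` anchors.
    """
    config = config or GeneratorConfig(image_size=backgrounds[0].shape[0])
    if not 0 <= count <= config.max_count:
        raise ValueError("invalid class range: count outside [0, max_count]")
    bg_id = int(rng_seed) % len(backgrounds)
    bg = backgrounds[bg_id]
    h_img, w_img = bg.shape

    img = bg.astype(np.float32) / 255.0
    if config.jitter_enabled:
        jit_rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0]))
        factor = 1.0 + jit_rng.uniform(-config.brightness_jitter, config.brightness_jitter)
        img = img * factor
        if config.jitter_noise_amp > 0:
            img = img + config.jitter_noise_amp * _smooth_noise(
                jit_rng, h_img, config.background_noise_scale / 2
            )
        img = np.clip(img, 0.0, 1.0)

    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 1 + placement_salt]))
    pool = sprite_pool if sprite_pool is not None else list(range(len(bank.sprites)))
    if count > 0 and len(pool) < count:
        raise ValueError("sprite pool smaller than requested count")

    placements: list[Placement] = []
    occupancy = np.zeros((h_img, w_img), dtype=bool)
    chosen = rng.choice(len(pool), size=count, replace=False) if count else []
    struct = np.ones((3, 3), dtype=bool)
    for k in chosen:
        sprite = bank.sprites[pool[int(k)]]
        angle = float(rng.uniform(0.0, 360.0))
        pix, mask = _rotate_sprite(sprite, angle)
        h, w = mask.shape
        if h >= h_img or w >= w_img:
            raise SceneOvercrowdedError("scene overcrowded: sprite larger than background")
        dil = ndimage.binary_dilation(
            np.pad(mask, config.separation_px), structure=struct, iterations=config.separation_px
        )
        placed = False
        for _ in range(config.max_attempts):
            r = int(rng.integers(0, h_img - h + 1))
            c = int(rng.integers(0, w_img - w + 1))
            m = config.separation_px
            r0, c0 = max(r - m, 0), max(c - m, 0)
            r1, c1 = min(r + h + m, h_img), min(c + w + m, w_img)
            sub = dil[m + (r0 - r): m + (r1 - r), m + (c0 - c): m + (c1 - c)]
            if not (occupancy[r0:r1, c0:c1] & sub).any():
                region = img[r:r + h, c:c + w]
                region[mask] = pix[mask]
                occupancy[r:r + h, c:c + w] |= mask
                placements.append(Placement(pool[int(k)], angle, (r, c)))
                placed = True
                break
        if not placed:
            raise SceneOvercrowdedError("scene overcrowded: no disjoint anchor found")

    return SceneRecord(
        scene_id=scene_id,
        split=split,
        count=count,
        background_id=bg_id,
        seed=int(rng_seed),
        filename=f"{split}_{scene_id:06d}_count{count}.png",
        placements=placements,
        image=np.clip(np.round(img * 255), 0, 255).astype(np.uint8),
    )


def render_record(
    config: GeneratorConfig,
    bank: SpriteBank,
    backgrounds: list[np.ndarray],
    record: SceneRecord,
    max_retries: int = 20,
) -> SceneRecord:
    """Regenerate a manifest record's scene, retrying overcrowded layouts.

    Retries redraw sprite choices and anchors deterministically (salted seed)
    while keeping the background and, crucially, the count label unchanged.
    """
    pool = bank.indices_for("test" if record.split == "test" else "train")
    for retry in range(max_retries):
        try:
            return compose_scene(
                backgrounds,
                bank,
                record.count,
                record.seed,
                sprite_pool=pool,
                config=config,
                split=record.split,
                scene_id=record.scene_id,
                placement_salt=retry,
            )
        except SceneOvercrowdedError:
            continue
    raise SceneOvercrowdedError(
        f"scene overcrowded: record {record.scene_id} failed after {max_retries} re-seeds"
    )


def render_split(
    manifest: DatasetManifest,
    split: str,
    bank: SpriteBank | None = None,
    backgrounds: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render every scene of a split to a (N, H, W) uint8 stack plus counts."""
    bank = bank or bank_from_config(manifest.config)
    backgrounds = backgrounds or make_backgrounds(manifest.config)
    recs = manifest.split_records(split)
    if not recs:
        raise ValueError(f"missing split: {split}")
    n = len(recs)
    s = manifest.config.image_size
    images = np.empty((n, s, s), dtype=np.uint8)
    counts = np.empty(n, dtype=np.int64)
    for i, rec in enumerate(recs):
        images[i] = render_record(manifest.config, bank, backgrounds, rec).image
        counts[i] = rec.count
    return images, counts


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

def _scene_seed(dataset_seed: int, scene_id: int) -> int:
    return int(np.random.SeedSequence([dataset_seed, scene_id]).generate_state(1)[0] % (2**31))


def build_dataset(config: GeneratorConfig) -> DatasetManifest:
    """Plan the full balanced dataset as deterministic per-scene metadata.

    The training pool (``train_pool_per_class`` scenes per class 0..max_count)
    is split 70/30 into train/val per class at the image level; test scenes
    (``test_per_class`` per class) will be rendered with held-out sprites only.
    Images themselves are regenerated on demand from the stored seeds.
    """
    if config.max_count < 0:
        raise ValueError("invalid class range")
    records: list[SceneRecord] = []
    scene_id = 0
    split_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    for cls in range(config.max_count + 1):
        n_pool = config.train_pool_per_class
        n_train = int(np.floor(n_pool * config.train_fraction + 0.5))
        labels = np.array(["train"] * n_train + ["val"] * (n_pool - n_train))
        split_rng.shuffle(labels)
        for lab in labels:
            records.append(
                SceneRecord(scene_id, str(lab), cls, 0, _scene_seed(config.seed, scene_id), "")
            )
            scene_id += 1
    for cls in range(config.max_count + 1):
        for _ in range(config.test_per_class):
            records.append(SceneRecord(scene_id, "test", cls, 0, _scene_seed(config.seed, scene_id), ""))
            scene_id += 1
    for r in records:
        r.background_id = r.seed % config.n_backgrounds
        r.filename = f"{r.split}_{r.scene_id:06d}_count{r.count}.png"
    per_class = {c: config.train_pool_per_class + config.test_per_class for c in range(config.max_count + 1)}
    return DatasetManifest(records=records, per_class_counts=per_class, seed=config.seed, config=config)


# ---------------------------------------------------------------------------
# Manifest I/O: CSV of records + JSON sidecar with the generator config
# ---------------------------------------------------------------------------

def write_manifest(manifest: DatasetManifest, out_dir: str | Path, write_images: bool = False,
                   bank: SpriteBank | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "scene_id": r.scene_id,
                "filename": r.filename,
                "split": r.split,
                "count": r.count,
                "background_id": r.background_id,
                "seed": r.seed,
            }
            for r in manifest.records
        ],
        columns=["scene_id", "filename", "split", "count", "background_id", "seed"],
    )
    df.to_csv(out / "manifest.csv", index=False)
    sidecar = {
        "seed": manifest.seed,
        "per_class_counts": {str(k): int(v) for k, v in manifest.per_class_counts.items()},
        "generator_config": manifest.config.to_dict(),
        "images_written": bool(write_images),
    }
    (out / "manifest.json").write_text(json.dumps(sidecar, indent=1))
    if write_images:
        bank = bank or bank_from_config(manifest.config)
        backgrounds = make_backgrounds(manifest.config)
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for rec in manifest.records:
            full = render_record(manifest.config, bank, backgrounds, rec)
            Image.fromarray(full.image, mode="L").save(img_dir / rec.filename)
    return out


def read_manifest(in_dir: str | Path) -> DatasetManifest:
    src = Path(in_dir)
    sidecar = json.loads((src / "manifest.json").read_text())
    df = pd.read_csv(src / "manifest.csv")
    records = [
        SceneRecord(
            scene_id=int(row["scene_id"]),
            split=str(row["split"]),
            count=int(row["count"]),
            background_id=int(row["background_id"]),
            seed=int(row["seed"]),
            filename=str(row["filename"]),
        )
        for row in df.to_dict("records")
    ]
    per_class = {int(k): int(v) for k, v in sidecar["per_class_counts"].items()}
    config = GeneratorConfig.from_dict(sidecar["generator_config"])
    manifest = DatasetManifest(records=records, per_class_counts=per_class,
                               seed=int(sidecar["seed"]), config=config)
    if sidecar.get("images_written"):
        for rec in records:
            f = src / "images" / rec.filename
            if not f.exists():
                raise FileNotFoundError(f"missing image file: {f}")
    return manifest
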
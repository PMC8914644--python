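"""Insect sprites: loading cutouts, procedural synthesis, and train/test partitioning.

A *sprite* is a single insect cutout — a luminance raster plus a transparency
mask — used as the unit of composition when synthesizing labeled trap images.
Sprites come from real photographs (an insect photographed inside the trap and
extracted from its background) or from the built-in procedural synthesizer,
which emulates the diversity of insect body forms (elongated elliptical body,
thin articulated legs and antennae, optional wing lobes) so the full pipeline
can run without any photographic input.

The bank of sprites is partitioned into disjoint train and test sets so that
no insect used to train the counting model ever appears in a test scene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw
from skimage import filters as skfilters

__all__ = [
    "Sprite",
    "SpriteBank",
    "MorphologyParams",
    "load_sprite_images",
    "synthesize_procedural_sprite",
    "partition_sprites",
    "extract_cutout",
]

_LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float64)  # ITU-R 601

# Masks are handled as hard (binary) alpha so overlap tests during scene
# composition are exact set operations.
ALPHA_THRESHOLD = 0.5


@dataclass(frozen=True)
class Sprite:
    """A single insect cutout, trimmed to the tight bounding box of its mask."""

    pixels: np.ndarray  # float32 luminance in [0, 1], shape (H, W)
    alpha: np.ndarray  # float32 binary mask, same shape
    species_tag: str = ""
    origin: str = "procedural"  # or "real_cutout"

    def __post_init__(self) -> None:
        if self.pixels.shape != self.alpha.shape:
            raise ValueError("pixels and alpha must have identical shapes")
        mask = self.alpha > ALPHA_THRESHOLD
        if not mask.any():
            raise ValueError("sprite alpha mask is empty")
        rows = mask.any(axis=1)
        cols = mask.any(axis=0)
        if not (rows[0] and rows[-1] and cols[0] and cols[-1]):
            raise ValueError("sprite is not trimmed to the tight bounding box")

    @property
    def mask(self) -> np.ndarray:
        """Binary boolean mask."""
        return self.alpha > ALPHA_THRESHOLD

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save(self, path: str | Path) -> None:
        """Write the sprite as an RGBA PNG (luminance replicated to RGB)."""
        g = np.clip(np.round(self.pixels * 255), 0, 255).astype(np.uint8)
        a = np.where(self.mask, 255, 0).astype(np.uint8)
        rgba = np.stack([g, g, g, a], axis=-1)
        Image.fromarray(rgba, mode="RGBA").save(path)


@dataclass
class SpriteBank:
    """An ordered collection of sprites with an optional train/test partition."""

    sprites: list[Sprite]
    partition: dict[int, str] | None = None  # sprite index -> "train" | "test"
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.sprites)

    def indices_for(self, split: str) -> list[int]:
        """Sprite indices assigned to ``split`` ("train" or "test").

        An unpartitioned bank exposes every sprite under either name.
        """
        if self.partition is None:
            return list(range(len(self.sprites)))
        return [i for i in range(len(self.sprites)) if self.partition[i] == split]


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr)
    if a.dtype == np.uint8:
        a = a.astype(np.float32) / 255.0
    else:
        a = a.astype(np.float32)
    if a.ndim == 3:
        a = (a[..., :3] @ _LUMA).astype(np.float32)
    return a


def _trim(pixels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return pixels[sl], mask[sl]


def _make_sprite(pixels: np.ndarray, mask: np.ndarray, tag: str, origin: str) -> Sprite:
    pixels, mask = _trim(pixels, mask)
    return Sprite(
        pixels=np.where(mask, pixels, 0.0).astype(np.float32),
        alpha=mask.astype(np.float32),
        species_tag=tag,
        origin=origin,
    )


def load_sprite_images(directory_path: str | Path, species_from_filename: bool = True) -> SpriteBank:
    """Load every raster image in a directory as one sprite per file.

    Files are read in lexicographic filename order so repeated loads produce an
    identical bank.  PNGs with an alpha channel use it (binarized) as the mask;
    images without alpha get a mask from Otsu thresholding of the luminance
    (dark insect on light background), keeping the largest connected component.
    """
    directory = Path(directory_path)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not paths:
        raise ValueError(f"no sprites found in {directory}")
    sprites: list[Sprite] = []
    for p in paths:
        try:
            with Image.open(p) as im:
                arr = np.asarray(im)
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise ValueError(f"unreadable sprite file: {p.name}: {exc}") from exc
        gray = _to_gray01(arr)
        if arr.ndim == 3 and arr.shape[-1] == 4:
            mask = (arr[..., 3].astype(np.float32) / 255.0) > ALPHA_THRESHOLD
        else:
            thresh = skfilters.threshold_otsu(gray)
            mask = gray < thresh
            lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
            if n > 1:
                sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
                mask = lab == (int(np.argmax(sizes)) + 1)
        if not mask.any():
            raise ValueError(f"unreadable sprite file: {p.name}: empty mask")
        tag = p.stem if species_from_filename else ""
        sprites.append(_make_sprite(gray, mask, tag, "real_cutout"))
    return SpriteBank(sprites=sprites)


@dataclass(frozen=True)
class MorphologyParams:
    """Ranges driving the procedural insect synthesizer.

    Lengths are in pixels of the target scene resolution.  Defaults emulate
    medium-sized insects on a 240 px trap-floor image; :meth:`scaled` shrinks
    them proportionally for lower-resolution scenes.
    """

    body_length: tuple[float, float] = (12.0, 60.0)
    aspect_ratio: tuple[float, float] = (2.0, 5.0)
    n_appendages: tuple[int, int] = (0, 8)
    appendage_length: tuple[float, float] = (0.3, 0.9)  # fraction of body length
    darkness: tuple[float, float] = (0.05, 0.40)  # body luminance
    wing_prob: float = 0.5

    def validate(self) -> None:
        if self.body_length[0] < 3 or self.body_length[1] < self.body_length[0]:
            raise ValueError("invalid morphology parameters: body_length")
        if self.aspect_ratio[0] < 1 or self.aspect_ratio[1] < self.aspect_ratio[0]:
            raise ValueError("invalid morphology parameters: aspect_ratio")
        if self.n_appendages[0] < 0 or self.n_appendages[1] > 8:
            raise ValueError("invalid morphology parameters: n_appendages")
        if not (0 <= self.darkness[0] <= self.darkness[1] <= 0.6):
            raise ValueError("invalid morphology parameters: darkness")

    def scaled(self, factor: float) -> "MorphologyParams":
        """Morphology ranges scaled for a scene ``factor`` times the 240 px default."""
        lo = max(3.0, self.body_length[0] * factor)
        hi = max(lo + 1.0, self.body_length[1] * factor)
        return replace(self, body_length=(lo, hi))


def synthesize_procedural_sprite(seed: int, params: MorphologyParams | None = None) -> Sprite:
    """Generate one articulated insect-like sprite deterministically from a seed.

    The mask is an elliptical body, an optional pair of lighter wing lobes, and
    0-8 thin polyline appendages (legs/antennae) rooted inside the body, so the
    whole mask is a single connected component.  Luminance is well below trap
    backgrounds (dark insect on a light sticky floor).
    """
    params = params or MorphologyParams()
    params.validate()
    rng = np.random.default_rng(seed)

    body_len = rng.uniform(*params.body_length)
    aspect = rng.uniform(*params.aspect_ratio)
    body_w = max(body_len / aspect, 2.0)
    app_frac = rng.uniform(*params.appendage_length)
    reach = app_frac * body_len
    side = int(np.ceil(body_len + 2 * reach)) + 6
    cy = cx = side / 2.0

    mask = np.zeros((side, side), dtype=bool)
    rr, cc = skdraw.ellipse(cy, cx, body_w / 2.0, body_len / 2.0, shape=mask.shape)
    mask[rr, cc] = True
    body_mask = mask.copy()

    pix = np.zeros((side, side), dtype=np.float32)
    dark = rng.uniform(*params.darkness)
    texture = rng.normal(0.0, 0.03, size=(side, side)).astype(np.float32)
    pix[body_mask] = np.clip(dark + texture[body_mask], 0.0, 0.55)

    if rng.random() < params.wing_prob:
        for sign in (-1, 1):
            wr, wc = skdraw.ellipse(
                cy + sign * body_w * 0.45,
                cx + rng.uniform(-0.15, 0.15) * body_len,
                body_w * 0.45,
                body_len * 0.35,
                shape=mask.shape,
            )
            new = np.zeros_like(mask)
            new[wr, wc] = True
            wing_only = new & ~mask
            pix[wing_only] = np.clip(dark + 0.15 + texture[wing_only], 0.0, 0.6)
            mask |= new

    n_legs = int(rng.integers(params.n_appendages[0], params.n_appendages[1] + 1))
    for _ in range(n_legs):
        # Root strictly inside the body so the polyline stays connected to it.
        theta = rng.uniform(0, 2 * np.pi)
        r0 = cy + 0.7 * (body_w / 2.0) * np.sin(theta)
        c0 = cx + 0.7 * (body_len / 2.0) * np.cos(theta)
        length = rng.uniform(0.5, 1.0) * reach
        phi = rng.uniform(0, 2 * np.pi)
        # Elbowed limb: two segments with a bend, like a femur/tibia pair.
        mid_r = r0 + 0.6 * length * np.sin(phi)
        mid_c = c0 + 0.6 * length * np.cos(phi)
        phi2 = phi + rng.uniform(-0.9, 0.9)
        end_r = mid_r + 0.4 * length * np.sin(phi2)
        end_c = mid_c + 0.4 * length * np.cos(phi2)
        pts = [(r0, c0), (mid_r, mid_c), (end_r, end_c)]
        for (ar, ac), (br, bc) in zip(pts[:-1], pts[1:]):
            lr, lc = skdraw.line(
                int(round(np.clip(ar, 0, side - 1))),
                int(round(np.clip(ac, 0, side - 1))),
                int(round(np.clip(br, 0, side - 1))),
                int(round(np.clip(bc, 0, side - 1))),
            )
            mask[lr, lc] = True
            pix[lr, lc] = np.clip(dark, 0.0, 0.55)

    # Legs clipped at the canvas edge could in principle detach; keep the
    # component containing the body.
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        mask = lab == lab[int(cy), int(cx)]

    return _make_sprite(pix, mask, f"procedural_{seed}", "procedural")


def partition_sprites(bank: SpriteBank, train_fraction: float, seed: int) -> SpriteBank:
    """Randomly assign sprites to disjoint train/test sets.

    ``round(n * train_fraction)`` sprites go to train (ties toward train),
    the rest to test; the assignment is a seeded permutation.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(bank.sprites)
    if n == 0:
        raise ValueError("cannot partition an empty bank")
    n_train = int(np.floor(n * train_fraction + 0.5))  # round half up = ties to train
    if n_train == 0 or n_train == n:
        raise ValueError("degenerate partition: one side would be empty")
    order = np.random.default_rng(seed).permutation(n)
    partition = {int(i): ("train" if k < n_train else "test") for k, i in enumerate(order)}
    return SpriteBank(sprites=list(bank.sprites), partition=partition, seed=seed)


def extract_cutout(
    photo: np.ndarray,
    background: np.ndarray,
    threshold: float = 0.08,
    closing_size: int = 3,
    border_warn_fraction: float = 0.05,
    species_tag: str = "",
) -> Sprite:
    """Extract the single insect in ``photo`` by background subtraction.

    The mask is the largest connected component of ``|photo - background| >
    threshold`` after binary closing (3x3 by default); smaller blobs are
    treated as debris.  A mask hugging the image border suggests a clipped
    insect and raises a warning.
    """
    p = _to_gray01(photo)
    b = _to_gray01(background)
    if p.shape != b.shape:
        raise ValueError("photo and background must have the same dimensions")
    raw = np.abs(p - b) > threshold
    if not raw.any():
        raise ValueError("no foreground detected")
    fg = ndimage.binary_closing(raw, structure=np.ones((closing_size, closing_size), dtype=bool))
    fg |= raw  # closing zeroes border pixels (outside counts as background)
    lab, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("no foreground detected")
    sizes = ndimage.sum_labels(fg, lab, index=np.arange(1, n + 1))
    mask = lab == (int(np.argmax(sizes)) + 1)
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = int((mask & border).sum())
    perimeter = int((mask & ~ndimage.binary_erosion(mask)).sum())
    if perimeter and touching / perimeter > border_warn_fraction:
        warnings.warn("foreground touches the image border; insect may be clipped", stacklevel=2)
    return _make_sprite(p, mask, species_tag, "real_cutout")
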
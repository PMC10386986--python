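"""Whole-slide preparation: tissue/background masking, patch extraction,
training-time augmentation.

Conventions: 0-based (row, col) pixel coordinates; patch windows are
half-open ``[r, r + patch)``. Grayscale for thresholding is the Rec. 601
luma of RGB, since H&E tissue is darker than the glass background the mask
is 1 on the *darker* side of the Otsu threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

from .tissues import TissueClass

LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class TissueMask:
    """Binary tissue mask aligned to a source image (1 = tissue)."""

    mask: np.ndarray
    threshold: float
    microns_per_pixel: float = 0.25

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0/1")


@dataclass
class Tile:
    """A square RGB patch cut from a slide.

    ``pixels`` is H×W×3 uint8; ``origin`` is the (row, col) of the patch's
    top-left corner in the source image.
    """

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)
    true_class: Optional[TissueClass] = None
    patient_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("tile pixels must be H×W×3")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("tiles must be square")
        if min(self.origin) < 0:
            raise ValueError("origin must be nonnegative")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB (H,W,3) or grayscale (H,W) array → float grayscale in [0,255]."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image @ LUMA
    return image


def otsu_mask(image: np.ndarray, microns_per_pixel: float = 0.25) -> TissueMask:
    """Threshold a slide into tissue vs background by Otsu's method.

    The threshold maximizes between-class variance over the 256-bin
    histogram; stained tissue absorbs light, so pixels at or below the
    threshold are flagged as tissue.
    """
    gray = to_grayscale(image)
    if np.ptp(gray) == 0:
        raise ValueError("constant image: Otsu threshold undefined")
    thr = float(threshold_otsu(gray, nbins=256))
    mask = (gray <= thr).astype(np.uint8)
    return TissueMask(mask=mask, threshold=thr, microns_per_pixel=microns_per_pixel)


def extract_patches(
    image: np.ndarray,
    mask: TissueMask,
    patch_size: int = 512,
    stride: int | None = None,
    min_tissue_frac: float = 0.5,
    patient_id: str = "",
) -> list[Tile]:
    """Cut tissue patches from a slide in row-major scan order.

    A window is kept iff the mean of the tissue mask over it is at least
    ``min_tissue_frac``. Origins are multiples of ``stride`` (default:
    non-overlapping, stride = patch_size).
    """
    image = np.asarray(image)
    if stride is None:
        stride = patch_size
    h, w = image.shape[:2]
    if patch_size > min(h, w):
        raise ValueError(f"patch_size {patch_size} exceeds image dims {h}×{w}")
    if not 0 < min_tissue_frac <= 1:
        raise ValueError("min_tissue_frac must be in (0, 1]")
    if mask.mask.shape != (h, w):
        raise ValueError("mask and image shapes differ")
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)

    tiles = []
    for r in range(0, h - patch_size + 1, stride):
        for c in range(0, w - patch_size + 1, stride):
            window = mask.mask[r : r + patch_size, c : c + patch_size]
            if window.mean() >= min_tissue_frac:
                tiles.append(
                    Tile(
                        pixels=image[r : r + patch_size, c : c + patch_size],
                        origin=(r, c),
                        patient_id=patient_id,
                    )
                )
    return tiles


@dataclass
class AugmentSpec:
    """Settings for random tile augmentation.

    Rotations are restricted to right angles and translations are filled by
    reflection padding, so pixel values never leave [0, 255] and no
    interpolation is involved.
    """

    flip_horizontal: bool = True
    flip_vertical: bool = True
    rotate_quarters: tuple[int, ...] = (0, 1, 2, 3)
    max_translate_px: int = 0
    contrast_range: tuple[float, float] = (0.8, 1.2)


def _adjust_contrast(pixels: np.ndarray, factor: float) -> np.ndarray:
    mean = pixels.mean(axis=(0, 1), keepdims=True)
    out = (pixels.astype(float) - mean) * factor + mean
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment(tile: Tile, spec: AugmentSpec | None = None, seed: int = 0) -> Tile:
    """Randomly flip/rotate/translate/contrast-jitter a tile (label kept)."""
    spec = spec or AugmentSpec()
    rng = np.random.default_rng(seed)
    px = tile.pixels

    if spec.flip_horizontal and rng.random() < 0.5:
        px = px[:, ::-1]
    if spec.flip_vertical and rng.random() < 0.5:
        px = px[::-1]
    k = int(rng.choice(spec.rotate_quarters))
    px = np.rot90(px, k)
    if spec.max_translate_px > 0:
        dy, dx = rng.integers(-spec.max_translate_px, spec.max_translate_px + 1, 2)
        pad = spec.max_translate_px
        padded = np.pad(px, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
        n = px.shape[0]
        px = padded[pad + dy : pad + dy + n, pad + dx : pad + dx + n]
    lo, hi = spec.contrast_range
    factor = float(rng.uniform(lo, hi))
    px = _adjust_contrast(px, factor)
    return Tile(
        pixels=px,
        origin=tile.origin,
        true_class=tile.true_class,
        patient_id=tile.patient_id,
    )


def rotate90(tile: Tile, quarters: int = 1) -> Tile:
    """Deterministic right-angle rotation (used by tests and augmentation)."""
    return Tile(
        pixels=np.rot90(tile.pixels, quarters).copy(),
        origin=tile.origin,
        true_class=tile.true_class,
        patient_id=tile.patient_id,
    )
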
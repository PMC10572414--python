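"""Mask-consistent application of transformations to image/mask pairs.

Geometric operations (shears, translations, rotation, flips) transform the
image and its binary mask with identical parameters — bilinear resampling
for the image, nearest-neighbour for the mask, which is then re-binarized —
so the annotation follows the anatomy.  Photometric operations act on the
image only.  Every operation fires with its discrete probability φ drawn
from the caller's seeded random generator, so whole pipelines are
reproducible.

Vacated regions are filled with intensity 0 (OCT background is dark) and
mask background.  Translation magnitudes are calibrated in pixels at the
native 512-px scan width and scale proportionally for resized images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageEnhance, ImageOps

from .ops import get_op_spec
from .strategy import OpInstance, Strategy, SubStrategy

__all__ = ["ImageMaskPair", "apply_op", "apply_substrategy", "apply_strategy",
           "NATIVE_SIZE"]

NATIVE_SIZE = 512  # reference width/height for translation magnitudes, px


@dataclass(frozen=True)
class ImageMaskPair:
    """A grayscale scan (uint8, 0..255) with its binary cavity mask (0/1)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        image = np.asarray(self.image)
        mask = np.asarray(self.mask)
        if image.ndim != 2 or mask.ndim != 2:
            raise ValueError("image and mask must be 2-D arrays")
        if image.shape != mask.shape:
            raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
        if image.min() < 0 or image.max() > 255:
            raise ValueError("image intensities must lie in [0, 255]")
        mvals = np.unique(mask)
        if not np.isin(mvals, (0, 1)).all():
            raise ValueError("mask must be strictly binary {0, 1}")
        object.__setattr__(self, "image", image.astype(np.uint8))
        object.__setattr__(self, "mask", mask.astype(np.uint8))


def _to_pil(arr: np.ndarray) -> Image.Image:
    return Image.fromarray(arr, mode="L")


def _affine_pair(pair: ImageMaskPair, coeffs) -> ImageMaskPair:
    img = _to_pil(pair.image).transform(
        (pair.image.shape[1], pair.image.shape[0]), Image.AFFINE, coeffs,
        resample=Image.BILINEAR, fillcolor=0)
    msk = _to_pil(pair.mask * 255).transform(
        (pair.mask.shape[1], pair.mask.shape[0]), Image.AFFINE, coeffs,
        resample=Image.NEAREST, fillcolor=0)
    return ImageMaskPair(np.asarray(img), (np.asarray(msk) > 127).astype(np.uint8))


def _rotate_pair(pair: ImageMaskPair, degrees: float) -> ImageMaskPair:
    img = _to_pil(pair.image).rotate(degrees, resample=Image.BILINEAR, fillcolor=0)
    msk = _to_pil(pair.mask * 255).rotate(degrees, resample=Image.NEAREST, fillcolor=0)
    return ImageMaskPair(np.asarray(img), (np.asarray(msk) > 127).astype(np.uint8))


def _enhance(img: Image.Image, enhancer_cls, magnitude: float, rng) -> Image.Image:
    # PIL enhancement factor 1.0 is identity; the unsigned printed magnitude
    # perturbs it in a random direction, per the PIL auto-augmentation lineage.
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return enhancer_cls(img).enhance(1.0 + sign * magnitude)


def _apply_transform(pair: ImageMaskPair, op: OpInstance, rng) -> ImageMaskPair:
    spec = get_op_spec(op.op)
    name = spec.name
    m = op.magnitude
    h, w = pair.image.shape

    if name == "ShearX":
        return _affine_pair(pair, (1, m, 0, 0, 1, 0))
    if name == "ShearY":
        return _affine_pair(pair, (1, 0, 0, m, 1, 0))
    if name == "TranslateX":
        return _affine_pair(pair, (1, 0, -m * w / NATIVE_SIZE, 0, 1, 0))
    if name == "TranslateY":
        return _affine_pair(pair, (1, 0, 0, 0, 1, -m * h / NATIVE_SIZE))
    if name == "Rotate":
        return _rotate_pair(pair, m)
    if name == "HorizontalFlip":
        return ImageMaskPair(pair.image[:, ::-1].copy(), pair.mask[:, ::-1].copy())
    if name == "VerticalFlip":
        return ImageMaskPair(pair.image[::-1, :].copy(), pair.mask[::-1, :].copy())

    img = _to_pil(pair.image)
    if name == "Color":
        # saturation blend is the identity on a single grayscale channel;
        # kept in the search space for the full 16-operation vocabulary
        out = img
    elif name == "Contrast":
        out = _enhance(img, ImageEnhance.Contrast, m, rng)
    elif name == "Sharpness":
        out = _enhance(img, ImageEnhance.Sharpness, m, rng)
    elif name == "Brightness":
        out = _enhance(img, ImageEnhance.Brightness, m, rng)
    elif name == "Posterize":
        out = ImageOps.posterize(img, int(m))
    elif name == "Solarize":
        out = ImageOps.solarize(img, int(round(m)))
    elif name == "AutoContrast":
        out = ImageOps.autocontrast(img)
    elif name == "Equalize":
        out = ImageOps.equalize(img)
    elif name == "Invert":
        out = ImageOps.invert(img)
    else:  # pragma: no cover - registry and dispatch kept in sync
        raise ValueError(f"unhandled operation {name}")
    return ImageMaskPair(np.asarray(out), pair.mask)


def apply_op(pair: ImageMaskPair, op_instance: OpInstance, rng: np.random.Generator
             ) -> ImageMaskPair:
    """Apply one transformation with its probability φ; otherwise return the
    input bit-exact."""
    if not isinstance(pair, ImageMaskPair):
        pair = ImageMaskPair(*pair)
    if rng.random() < op_instance.probability:
        return _apply_transform(pair, op_instance, rng)
    return pair


def apply_substrategy(pair: ImageMaskPair, sub: SubStrategy,
                      rng: np.random.Generator) -> ImageMaskPair:
    """Apply the two operations of a sub-strategy in order."""
    return apply_op(apply_op(pair, sub.first, rng), sub.second, rng)


def apply_strategy(pair: ImageMaskPair, strategy: Strategy,
                   rng: np.random.Generator) -> ImageMaskPair:
    """Pick one sub-strategy uniformly at random and apply it."""
    if len(strategy) == 0:
        raise ValueError("cannot apply an empty strategy")
    idx = int(rng.integers(0, len(strategy)))
    return apply_substrategy(pair, strategy.substrategies[idx], rng)
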
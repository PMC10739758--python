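"""Paired image/mask augmentation.

Geometric transforms (flips, rotation, shear, zoom) are applied with
identical geometry to the image and the label mask; the mask is always
resampled nearest-neighbour so labels stay in the {0..3} alphabet, and
regions exposed by the warp are filled with background (label 0, black
pixels). Photometric and noise transforms (brightness, blur, salt &
pepper, speckle) never touch the mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .scenes import HALF_RIPE

OP_NAMES = ("brightness", "blur", "hflip", "vflip", "rotation",
            "shear_h", "shear_v", "salt_pepper", "speckle", "zoom")

GEOMETRIC_OPS = frozenset({"hflip", "vflip", "rotation", "shear_h", "shear_v", "zoom"})

#: Default magnitude ranges used when a spec's params are left unset.
DEFAULT_RANGES = {
    "brightness": {"factor": (-0.25, 0.25)},
    "blur": {"sigma": (0.5, 1.0)},
    "hflip": {},
    "vflip": {},
    "rotation": {"angle": (-30.0, 30.0)},
    "shear_h": {"angle": (-15.0, 15.0)},
    "shear_v": {"angle": (-15.0, 15.0)},
    "salt_pepper": {"rate": (0.0, 0.02)},
    "speckle": {"variance": (0.0, 0.05)},
    "zoom": {"factor": (0.8, 1.2)},
}


class AugmentationError(ValueError):
    """Unknown op or invalid parameters."""


@dataclasses.dataclass(frozen=True)
class AugmentationSpec:
    """One augmentation op with concrete parameters.

    ``params=None`` means "sample the parameters from DEFAULT_RANGES with
    ``seed``"; the sampled values make the application deterministic.
    """

    op_name: str
    params: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.op_name not in OP_NAMES:
            raise AugmentationError(f"unknown augmentation op: {self.op_name!r}")

    def resolved_params(self) -> dict:
        if self.params is not None:
            return dict(self.params)
        rng = np.random.default_rng(self.seed)
        return {k: float(rng.uniform(*rng_range))
                for k, rng_range in DEFAULT_RANGES[self.op_name].items()}


def _affine_pair(image, mask, matrix):
    """Apply a 2x2 affine (about the image center) to image and mask."""
    rows, cols = mask.shape
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    offset = center - matrix @ center
    out_img = np.stack([
        ndimage.affine_transform(image[..., ch], matrix, offset=offset,
                                 order=1, mode="constant", cval=0.0)
        for ch in range(image.shape[2])], axis=-1)
    out_mask = ndimage.affine_transform(mask, matrix, offset=offset,
                                        order=0, mode="constant", cval=0,
                                        output=mask.dtype)
    return np.clip(out_img, 0.0, 1.0), out_mask


def apply_augmentation(image: np.ndarray, mask: np.ndarray,
                       spec: AugmentationSpec):
    """Apply one augmentation; returns a new (image, mask) pair."""
    if image.shape[:2] != mask.shape:
        raise AugmentationError(
            f"image {image.shape[:2]} and mask {mask.shape} shapes differ")
    p = spec.resolved_params()
    op = spec.op_name

    if op == "hflip":
        return image[:, ::-1].copy(), mask[:, ::-1].copy()
    if op == "vflip":
        return image[::-1].copy(), mask[::-1].copy()
    if op == "brightness":
        return np.clip(image * (1.0 + p["factor"]), 0.0, 1.0), mask.copy()
    if op == "blur":
        if p["sigma"] == 0:
            return image.copy(), mask.copy()
        out = ndimage.gaussian_filter(image, sigma=(p["sigma"], p["sigma"], 0))
        return np.clip(out, 0.0, 1.0), mask.copy()
    if op == "rotation":
        if p["angle"] % 360 == 0:
            return image.copy(), mask.copy()
        a = np.deg2rad(p["angle"])
        matrix = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return _affine_pair(image, mask, matrix)
    if op in ("shear_h", "shear_v"):
        if p["angle"] == 0:
            return image.copy(), mask.copy()
        s = np.tan(np.deg2rad(p["angle"]))
        matrix = (np.array([[1.0, s], [0.0, 1.0]]) if op == "shear_h"
                  else np.array([[1.0, 0.0], [s, 1.0]]))
        return _affine_pair(image, mask, matrix)
    if op == "zoom":
        factor = p["factor"]
        if factor <= 0:
            raise AugmentationError(f"zoom factor must be positive, got {factor}")
        if factor == 1:
            return image.copy(), mask.copy()
        matrix = np.eye(2) / factor
        return _affine_pair(image, mask, matrix)
    if op == "salt_pepper":
        rate = p["rate"]
        if not 0.0 <= rate <= 1.0:
            raise AugmentationError("salt_pepper rate must lie in [0, 1]")
        rng = np.random.default_rng(spec.seed)
        out = image.copy()
        hit = rng.random(mask.shape) < rate
        salt = rng.random(mask.shape) < 0.5
        out[hit & salt] = 1.0
        out[hit & ~salt] = 0.0
        return out, mask.copy()
    if op == "speckle":
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, np.sqrt(p["variance"]), image.shape)
        return np.clip(image + image * noise, 0.0, 1.0), mask.copy()
    raise AugmentationError(f"unknown augmentation op: {op!r}")  # pragma: no cover


def augment_dataset(dataset, spec_list, multiplier: int, seed: int = 0,
                    minority_boost: int = 1):
    """Emit ``multiplier`` augmented variants of each (image, mask) pair.

    Each variant applies every spec in ``spec_list`` in order; specs whose
    params are unset get per-variant sampled parameters (recorded in the
    returned spec lists, so any variant regenerates exactly). Inputs whose
    masks contain the minority half-ripe class are repeated
    ``minority_boost`` times before augmentation.

    Returns a list of ``(image, mask, applied_specs)`` triples.
    """
    if multiplier < 1:
        raise AugmentationError("multiplier must be >= 1")
    if not spec_list:
        raise AugmentationError("spec_list must not be empty")
    out = []
    counter = 0
    for image, mask in dataset:
        repeats = minority_boost if (mask == HALF_RIPE).any() else 1
        for _ in range(repeats):
            for _v in range(multiplier):
                img_v, mask_v = image, mask
                applied = []
                for spec in spec_list:
                    var_seed = (seed * 2_654_435_761 + spec.seed + counter) % (2 ** 31)
                    concrete = AugmentationSpec(
                        spec.op_name,
                        spec.params if spec.params is not None
                        else AugmentationSpec(spec.op_name, None, var_seed).resolved_params(),
                        var_seed)
                    img_v, mask_v = apply_augmentation(img_v, mask_v, concrete)
                    applied.append(concrete)
                    counter += 1
                out.append((img_v, mask_v, applied))
    return out
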
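"""Synthetic greenhouse scenes with pixel-accurate ripeness masks.

The real imagery this package is aimed at (greenhouse tomato crops graded
into un-ripened / half-ripened / fully-ripened by the red fraction of the
fruit surface) is not redistributable, so training, testing and the worked
examples all run on a parametric emulation: red/green discs on a foliage
backdrop, occluded by leaf strokes, under variable lighting, with the
heavy class imbalance observed in greenhouse crops (roughly 79% unripe,
4% half-ripe, 16% fully ripe instances).

Every scene is a pure function of its config seed, so datasets regenerate
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image

BACKGROUND, UNRIPE, HALF_RIPE, FULLY_RIPE = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", UNRIPE: "unripe",
               HALF_RIPE: "half_ripe", FULLY_RIPE: "fully_ripe"}
N_CLASSES = 4

#: Instance-count mix of the three ripeness classes (unripe, half, fully
#: ripe) matching the 3557:196:724 imbalance of a real greenhouse crop.
DEFAULT_CLASS_MIX = (3557 / 4477, 196 / 4477, 724 / 4477)

_MASK_PALETTE = [0, 0, 0, 60, 180, 75, 255, 225, 25, 230, 25, 75]


class SceneConfigError(ValueError):
    """Invalid scene-generation configuration."""


class DatasetError(IOError):
    """Manifest or dataset file problem."""


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic greenhouse scene.

    ``class_mix`` is the sampling probability of (unripe, half-ripe,
    fully-ripe) per tomato instance; ``occlusion_density`` is the fraction
    of the canvas covered by foliage strokes drawn over the fruit;
    ``lighting_gain_range`` is a multiplicative brightness interval
    emulating variable greenhouse lighting.
    """

    image_rows: int = 64
    image_cols: int = 64
    n_tomatoes_range: tuple[int, int] = (3, 8)
    radius_range: tuple[int, int] = (4, 9)
    class_mix: tuple[float, float, float] = DEFAULT_CLASS_MIX
    occlusion_density: float = 0.1
    lighting_gain_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise SceneConfigError("class_mix must sum to 1")
        if self.radius_range[0] < 2:
            raise SceneConfigError("minimum tomato radius is 2 px")
        for name in ("n_tomatoes_range", "radius_range", "lighting_gain_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SceneConfigError(f"{name} is empty: {lo} > {hi}")
        if not 0.0 <= self.occlusion_density <= 1.0:
            raise SceneConfigError("occlusion_density must lie in [0, 1]")
        if self.image_rows < 2 * self.radius_range[1] + 2 or \
           self.image_cols < 2 * self.radius_range[1] + 2:
            raise SceneConfigError(
                f"canvas {self.image_rows}x{self.image_cols} too small for "
                f"maximum radius {self.radius_range[1]}")


@dataclasses.dataclass
class InstanceRecord:
    """Ground truth for one rendered tomato."""

    class_label: int
    center: tuple[int, int]
    radius: int
    red_fraction: float
    visible_pixel_count: int = 0


def ripeness_class_from_red_fraction(red_fraction: float) -> int:
    """Map the red-covered surface fraction of a tomato to its ripeness class.

    Fully ripened fruit shows red on at least 90% of its surface, half
    ripened on 30-89%, and un-ripened on less than 30%.
    """
    if not 0.0 <= red_fraction <= 1.0:
        raise ValueError(f"red fraction must lie in [0, 1], got {red_fraction}")
    if red_fraction >= 0.90:
        return FULLY_RIPE
    if red_fraction >= 0.30:
        return HALF_RIPE
    return UNRIPE


_RED = np.array([0.80, 0.12, 0.10])
_GREEN_FRUIT = np.array([0.35, 0.62, 0.20])
_FOLIAGE = np.array([0.18, 0.42, 0.15])


def _disc_pixels(center, radius, rows, cols):
    r0, c0 = center
    rr, cc = np.ogrid[:rows, :cols]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2


def generate_scene(config: SceneConfig):
    """Render one scene.

    Returns ``(image, mask, records)`` where ``image`` is R x C x 3 float in
    [0, 1], ``mask`` is an R x C int label map over {0..3}, and ``records``
    lists each tomato with its class, geometry and post-occlusion visible
    pixel count. Tomatoes are placed without mutual contact so each one is
    exactly one connected mask component before occlusion.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_rows, config.image_cols

    # mottled foliage backdrop
    image = _FOLIAGE[None, None, :] * (0.75 + 0.5 * rng.random((rows, cols, 1)))
    mask = np.zeros((rows, cols), dtype=np.int64)

    n_target = int(rng.integers(config.n_tomatoes_range[0],
                                config.n_tomatoes_range[1] + 1))
    records: list[InstanceRecord] = []
    placed: list[tuple[int, int, int]] = []
    attempts = 0
    while len(records) < n_target and attempts < 200 * max(n_target, 1):
        attempts += 1
        radius = int(rng.integers(config.radius_range[0], config.radius_range[1] + 1))
        r0 = int(rng.integers(radius, rows - radius))
        c0 = int(rng.integers(radius, cols - radius))
        # >= 2 px gap so instances never touch, even diagonally
        if any((r0 - r) ** 2 + (c0 - c) ** 2 < (radius + rad + 2) ** 2
               for r, c, rad in placed):
            continue
        cls = UNRIPE + int(rng.choice(3, p=np.asarray(config.class_mix)))
        if cls == FULLY_RIPE:
            red_fraction = float(rng.uniform(0.90, 1.0))
        elif cls == HALF_RIPE:
            red_fraction = float(rng.uniform(0.30, 0.90))
        else:
            red_fraction = float(rng.uniform(0.0, 0.30))

        disc = _disc_pixels((r0, c0), radius, rows, cols)
        drr, dcc = np.nonzero(disc)
        n_pix = drr.size
        # ripening proceeds from the bottom of the fruit upward: the lowest
        # ``red_fraction`` of disc pixels are red, the rest green
        order = np.argsort(-drr, kind="stable")
        n_red = int(round(red_fraction * n_pix))
        red_sel = order[:n_red]
        colors = np.tile(_GREEN_FRUIT, (n_pix, 1))
        colors[red_sel] = _RED
        # radial shading for a hint of 3-D shape
        shade = 1.0 - 0.35 * (((drr - r0) ** 2 + (dcc - c0) ** 2) / radius ** 2)
        image[drr, dcc] = colors * shade[:, None]
        mask[disc] = cls
        placed.append((r0, c0, radius))
        records.append(InstanceRecord(cls, (r0, c0), radius, red_fraction))

    # foliage strokes drawn last genuinely occlude fruit
    if config.occlusion_density > 0:
        target = config.occlusion_density * rows * cols
        covered = np.zeros((rows, cols), dtype=bool)
        while covered.sum() < target:
            er = int(rng.integers(0, rows))
            ec = int(rng.integers(0, cols))
            a = float(rng.uniform(2, max(3, rows // 8)))
            b = float(rng.uniform(1, max(2, rows // 16)))
            theta = float(rng.uniform(0, np.pi))
            rr, cc = np.ogrid[:rows, :cols]
            dr, dc = rr - er, cc - ec
            u = dr * np.cos(theta) + dc * np.sin(theta)
            v = -dr * np.sin(theta) + dc * np.cos(theta)
            stroke = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            covered |= stroke
            image[stroke] = _FOLIAGE * float(rng.uniform(0.6, 1.2))
            mask[stroke] = BACKGROUND

    gain = float(rng.uniform(*config.lighting_gain_range))
    image = np.clip(image * gain, 0.0, 1.0)

    for rec, (r0, c0, radius) in zip(records, placed):
        disc = _disc_pixels((r0, c0), radius, rows, cols)
        rec.visible_pixel_count = int((mask[disc] == rec.class_label).sum())

    return image, mask, records


def generate_dataset(config: SceneConfig, n_images: int, out_dir) -> dict:
    """Write ``n_images`` scenes (8-bit PNGs) plus a JSON manifest.

    Returns the manifest dict, which also reports per-class instance
    counts over the whole dataset.
    """
    if n_images < 1:
        raise SceneConfigError("n_images must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DatasetError(f"cannot create output directory {out_dir}: {exc}") from exc

    entries = []
    counts = {CLASS_NAMES[c]: 0 for c in (UNRIPE, HALF_RIPE, FULLY_RIPE)}
    for i in range(n_images):
        seed_i = (config.seed * 1_000_003 + i) % (2 ** 31)
        cfg_i = dataclasses.replace(config, seed=seed_i)
        image, mask, records = generate_scene(cfg_i)
        img_name, mask_name = f"scene_{i:05d}.png", f"mask_{i:05d}.png"
        save_image(image, out_dir / img_name)
        save_mask(mask, out_dir / mask_name)
        for rec in records:
            counts[CLASS_NAMES[rec.class_label]] += 1
        entries.append({
            "image": img_name,
            "mask": mask_name,
            "seed": seed_i,
            "instances": [dataclasses.asdict(r) for r in records],
        })
    manifest = {"entries": entries, "class_counts": counts,
                "config": dataclasses.asdict(config)}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_dataset(manifest_path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Load (image, mask) pairs listed in a manifest.

    Masks round-trip exactly; images are 8-bit quantized.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DatasetError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    pairs = []
    for entry in manifest.get("entries", []):
        img_path, mask_path = base / entry["image"], base / entry["mask"]
        for p in (img_path, mask_path):
            if not p.exists():
                raise DatasetError(f"missing file for entry {entry['image']}: {p}")
        image = load_image(img_path)
        mask = load_mask(mask_path)
        if image.shape[:2] != mask.shape:
            raise DatasetError(
                f"entry {entry['image']}: image {image.shape[:2]} vs "
                f"mask {mask.shape} shape mismatch")
        pairs.append((image, mask))
    return pairs


# -- PNG I/O ------------------------------------------------------------------

def save_image(image: np.ndarray, path):
    Image.fromarray((np.clip(image, 0, 1) * 255).round().astype(np.uint8),
                    mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0


def save_mask(mask: np.ndarray, path):
    if mask.min() < 0 or mask.max() >= N_CLASSES:
        raise ValueError("mask labels outside {0..3}")
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    im.putpalette(_MASK_PALETTE + [0] * (768 - len(_MASK_PALETTE)))
    im.save(path)


def load_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.int64)
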
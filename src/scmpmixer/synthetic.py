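"""Deterministic generator of labeled white-blood-cell-like images.

Each class is a morphology recipe: nucleus lobe count, nucleus/cell area
ratio, cytoplasm and nucleus stain hues, and a size jitter. An image is an
elliptical cytoplasm on a noisy light background with ``lobe_count``
overlapping nucleus blobs whose union area is driven to the target
nucleus/cell ratio by bisection on the blob radius. This is a synthetic
fixture: it reproduces the class-conditioned features a classifier can use
(hue, nucleus fraction, lobedness) but makes no claim of stain or texture
realism.
"""

from __future__ import annotations

import colorsys
import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class ClassMorphology:
    name: str
    lobe_count: int           # 1-5 nucleus blobs
    area_ratio: float         # nucleus/cell pixel-area ratio in (0, 1)
    cell_hue: float           # cytoplasm hue, degrees
    nucleus_hue: float        # nucleus hue, degrees
    size_jitter: float = 0.10  # fractional jitter of the cell radius


@dataclass
class SyntheticSpec:
    classes: list
    images_per_class: int = 50
    image_size: int = 64
    noise_sigma: float = 0.03
    background: tuple = (0.93, 0.91, 0.96)
    seed: int = 0

    @property
    def num_classes(self) -> int:
        return len(self.classes)

    def validate(self):
        if not 2 <= self.num_classes <= 8:
            raise ValueError("need between 2 and 8 classes")
        seen = set()
        for m in self.classes:
            if not 0.0 < m.area_ratio < 1.0:
                raise ValueError(
                    f"area_ratio of {m.name} must be in (0,1), got {m.area_ratio}")
            if not 1 <= m.lobe_count <= 5:
                raise ValueError(f"lobe_count of {m.name} must be in 1..5")
            key = (m.lobe_count, round(m.area_ratio, 6), round(m.cell_hue, 3),
                   round(m.nucleus_hue, 3))
            if key in seen:
                raise ValueError(f"class {m.name} duplicates another morphology")
            seen.add(key)


@dataclass
class SyntheticDataset:
    images: np.ndarray      # (N, S, S, 3) float32 in [0, 1]
    labels: np.ndarray      # (N,) int64
    class_names: list


def _hsv(h_deg: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v),
                    dtype=np.float32)


def render_cell(params: ClassMorphology, rng: np.random.Generator,
                image_size: int = 64, noise_sigma: float = 0.03,
                background=(0.93, 0.91, 0.96), return_masks: bool = False):
    """Render one cell image; fully determined by the generator state.

    Returns the image, or ``(image, cell_mask, nucleus_mask)`` when
    ``return_masks`` is set (the masks feed the area-ratio checks).
    """
    s = image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = s / 2 + rng.uniform(-0.05, 0.05) * s
    cx = s / 2 + rng.uniform(-0.05, 0.05) * s
    r0 = 0.34 * s * (1.0 + params.size_jitter * rng.uniform(-1, 1))
    a = r0 * (1.0 + 0.15 * rng.uniform(-1, 1))
    b = r0 * r0 / a
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    cell_mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    cell_area = int(cell_mask.sum())

    nucleus_mask = np.zeros_like(cell_mask)
    if cell_area > 0 and params.area_ratio > 0.02:
        n = params.lobe_count
        r_eq = np.sqrt(a * b)
        phase = rng.uniform(0, 2 * np.pi)
        spread = 0.0 if n == 1 else 0.38 * r_eq
        centers = []
        for i in range(n):
            ang = phase + 2 * np.pi * i / n
            centers.append((cy + spread * np.sin(ang) + rng.uniform(-1, 1),
                            cx + spread * np.cos(ang) + rng.uniform(-1, 1)))

        def union_fraction(radius: float) -> float:
            m = np.zeros_like(cell_mask)
            for (ny, nx) in centers:
                m |= (yy - ny) ** 2 + (xx - nx) ** 2 <= radius ** 2
            m &= cell_mask
            return m.sum() / cell_area, m

        lo, hi = 0.0, 1.6 * r_eq
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            frac, m = union_fraction(mid)
            if frac < params.area_ratio:
                lo = mid
            else:
                hi = mid
        _, nucleus_mask = union_fraction(0.5 * (lo + hi))

    cyto = _hsv(params.cell_hue + rng.uniform(-6, 6),
                0.38 + rng.uniform(-0.04, 0.04),
                0.82 + rng.uniform(-0.04, 0.04))
    nucl = _hsv(params.nucleus_hue + rng.uniform(-6, 6),
                0.68 + rng.uniform(-0.04, 0.04),
                0.45 + rng.uniform(-0.04, 0.04))
    img = np.empty((s, s, 3), dtype=np.float32)
    img[...] = np.asarray(background, dtype=np.float32)
    img[cell_mask] = cyto
    img[nucleus_mask] = nucl
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    if return_masks:
        return img, cell_mask, nucleus_mask
    return img


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Exactly num_classes * images_per_class images, class-balanced and
    byte-reproducible from the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for label, morph in enumerate(spec.classes):
        for _ in range(spec.images_per_class):
            images.append(render_cell(morph, rng, spec.image_size,
                                      spec.noise_sigma, spec.background))
            labels.append(label)
    return SyntheticDataset(
        images=np.stack(images), labels=np.array(labels, dtype=np.int64),
        class_names=[m.name for m in spec.classes])


def write_dataset(dataset: SyntheticDataset, root_path) -> Path:
    """Class-per-directory PNG layout plus a manifest CSV.

    root/<class_name>/img_00001.png ..., zero-padded and stably sorted.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    counters = {name: 0 for name in dataset.class_names}
    manifest = []
    for img, label in zip(dataset.images, dataset.labels):
        name = dataset.class_names[int(label)]
        counters[name] += 1
        cls_dir = root / name
        cls_dir.mkdir(exist_ok=True)
        fname = f"img_{counters[name]:05d}.png"
        arr = (np.clip(img, 0, 1) * 255.0).round().astype(np.uint8)
        Image.fromarray(arr).save(cls_dir / fname)
        manifest.append((f"{name}/{fname}", name))
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "class"])
        writer.writerows(sorted(manifest))
    return root


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_PRESETS = {
    # 4 BCCD-like classes: eosinophil, lymphocyte, monocyte, neutrophil
    "wbc4": [
        ClassMorphology("EO", 2, 0.45, 18, 300),
        ClassMorphology("L", 1, 0.80, 200, 260),
        ClassMorphology("M", 1, 0.55, 222, 275),
        ClassMorphology("N", 3, 0.50, 330, 285),
    ],
    # 5 Raabin-like classes (adds basophil)
    "wbc5": [
        ClassMorphology("B", 2, 0.75, 268, 290),
        ClassMorphology("EO", 2, 0.45, 18, 300),
        ClassMorphology("L", 1, 0.80, 200, 260),
        ClassMorphology("M", 1, 0.55, 222, 275),
        ClassMorphology("N", 3, 0.50, 330, 285),
    ],
    # 8 PBC-like classes (adds erythroblast, immature granulocyte, platelet)
    "wbc8": [
        ClassMorphology("B", 2, 0.75, 268, 290),
        ClassMorphology("EO", 2, 0.45, 18, 300),
        ClassMorphology("ER", 1, 0.65, 355, 250),
        ClassMorphology("IG", 2, 0.60, 40, 280),
        ClassMorphology("L", 1, 0.80, 200, 260),
        ClassMorphology("M", 1, 0.55, 222, 275),
        ClassMorphology("N", 3, 0.50, 330, 285),
        ClassMorphology("P", 1, 0.30, 90, 310, size_jitter=0.2),
    ],
    # deliberately well-separated 3-class set for learning-capability checks
    "easy3": [
        ClassMorphology("alpha", 1, 0.25, 0, 40),
        ClassMorphology("beta", 2, 0.50, 120, 160),
        ClassMorphology("gamma", 3, 0.75, 240, 280),
    ],
}


def preset_names() -> list:
    return sorted(_PRESETS)


def preset_spec(name: str, images_per_class: int = 50, image_size: int = 64,
                seed: int = 0, noise_sigma: float = 0.03) -> SyntheticSpec:
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; valid: {preset_names()}")
    classes = [replace(m) for m in _PRESETS[name]]
    return SyntheticSpec(classes=classes, images_per_class=images_per_class,
                         image_size=image_size, seed=seed,
                         noise_sigma=noise_sigma)
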
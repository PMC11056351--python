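"""Dataset reading and stratified splitting.

Images live in a class-per-directory layout (the convention of the public
blood-cell collections): ``root/<class_name>/*.png|jpg``. Class order is
the lexicographic order of the directory names, so label assignment is
stable across re-reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class ImageSet:
    images: np.ndarray   # (N, S, S, 3) float32 in [0, 1]
    labels: np.ndarray   # (N,) int64
    class_names: list

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices) -> "ImageSet":
        idx = np.asarray(indices, dtype=np.int64)
        return ImageSet(self.images[idx], self.labels[idx],
                        list(self.class_names))


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the full-scale recipe
    (Adam, lr 1e-4, batch 16, 100 epochs, 70/15/15 fractional split)."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0
    split_mode: str = "fractional"            # or "presplit"
    split_fractions: tuple = (0.70, 0.15, 0.15)
    validation_fraction_of_train: float = 0.15  # presplit mode
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7
    checkpoint_policy: str = "best_val_acc"

    def validate(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions {self.split_fractions} must sum to 1")
        if self.split_mode not in ("fractional", "presplit"):
            raise ValueError(f"unknown split mode {self.split_mode!r}")


def desk_train_config(seed: int = 0) -> TrainConfig:
    """Desk-scale recipe: 30 epochs at lr 1e-3 (a standard Adam rate for
    short schedules on small synthetic sets), batch 16."""
    return TrainConfig(learning_rate=1e-3, epochs=30, seed=seed)


def read_image_folder(root, input_size: int = 224) -> ImageSet:
    """Decode a class-per-directory tree into an in-memory image set.

    Images are converted to RGB (grayscale broadcasts to 3 channels),
    resized to ``input_size`` with bilinear interpolation, and scaled to
    [0, 1]. Undecodable files are skipped with a logged warning; an empty
    class directory is an error.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(
            f"{root} must contain >= 2 class subdirectories, "
            f"found {len(class_dirs)}")
    images, labels = [], []
    class_names = [d.name for d in class_dirs]
    skipped = 0
    for label, cls_dir in enumerate(class_dirs):
        files = sorted(p for p in cls_dir.iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        decoded = 0
        for path in files:
            try:
                with Image.open(path) as im:
                    im = im.convert("RGB").resize(
                        (input_size, input_size), Image.BILINEAR)
                    arr = np.asarray(im, dtype=np.float32) / 255.0
            except (UnidentifiedImageError, OSError) as exc:
                skipped += 1
                logger.warning("skipping undecodable image %s (%s)", path, exc)
                continue
            images.append(arr)
            labels.append(label)
            decoded += 1
        if decoded == 0:
            raise ValueError(f"class directory {cls_dir} has no decodable images")
    if skipped:
        logger.warning("skipped %d undecodable file(s) under %s", skipped, root)
    return ImageSet(np.stack(images), np.array(labels, dtype=np.int64),
                    class_names)


def split_dataset(dataset: ImageSet, cfg: TrainConfig):
    """Seeded, stratified, disjoint and exhaustive train/val/test split.

    Per class the 70/15/15 targets are hit within one sample (rounding);
    a class too small to put at least one sample in each subset is an
    error naming that class.
    """
    cfg.validate()
    f_train, f_val, f_test = cfg.split_fractions
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx, test_idx = [], [], []
    for label in range(len(dataset.class_names)):
        idx = np.flatnonzero(dataset.labels == label)
        n = len(idx)
        n_val = int(round(f_val * n))
        n_test = int(round(f_test * n))
        n_train = n - n_val - n_test
        if min(n_train, n_val, n_test) < 1:
            raise ValueError(
                f"class {dataset.class_names[label]!r} has only {n} samples; "
                f"cannot place >= 1 in each of train/val/test")
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        val_idx.extend(perm[n_train:n_train + n_val])
        test_idx.extend(perm[n_train + n_val:])
    return (dataset.subset(train_idx), dataset.subset(val_idx),
            dataset.subset(test_idx))


def carve_validation(train_set: ImageSet, fraction: float, seed: int):
    """Presplit mode: set aside ``fraction`` of a provided training set for
    validation (stratified, seeded); the test directory stays untouched."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for label in range(len(train_set.class_names)):
        idx = np.flatnonzero(train_set.labels == label)
        n_val = max(1, int(round(fraction * len(idx))))
        if n_val >= len(idx):
            raise ValueError(
                f"class {train_set.class_names[label]!r} too small to carve "
                f"{fraction:.0%} validation")
        perm = rng.permutation(idx)
        val_idx.extend(perm[:n_val])
        train_idx.extend(perm[n_val:])
    return train_set.subset(train_idx), train_set.subset(val_idx)


def to_onehot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), num_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out
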
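"""Synthetic labelled image sets and planted feature tables.

The image generator emulates K-class histology archives at desk scale: a
stain-like background with Poisson-placed dark disks ("nuclei") whose rate,
radius and hue vary by class, plus clipped Gaussian pixel noise.  Classes are
therefore separable by cheap texture statistics (mean channel intensities and
a blob count), which is what the downstream feature/selection stages need —
no claim of realistic H&E morphology is made.

The feature-table generator plants a known subset of class-informative
columns (equally spaced Gaussian class means, unit noise) so selector
recovery can be scored against ground truth.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "LabeledImageSet",
    "PlantedFeatureTable",
    "make_synthetic_histology",
    "make_feature_table",
    "summary_features",
    "write_image_set",
    "read_image_set",
]


@dataclass
class LabeledImageSet:
    """RGB images with integer class labels."""

    images: list  # H x W x 3 uint8 arrays, all the same shape
    labels: np.ndarray  # class index 0..K-1 per image
    class_names: list
    seed: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.images) != len(self.labels):
            raise ValueError("one label per image required")
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1 or next(iter(shapes))[2] != 3:
            raise ValueError("all images must share one HxWx3 shape")
        k = len(self.class_names)
        if self.labels.min() < 0 or self.labels.max() >= k:
            raise ValueError("labels must index class_names")
        if len(np.unique(self.labels)) != k:
            raise ValueError("every class needs at least one image")

    def __len__(self):
        return len(self.images)


@dataclass
class PlantedFeatureTable:
    """n x d feature matrix with a known informative column subset."""

    matrix: np.ndarray
    labels: np.ndarray
    informative_indices: frozenset
    effect_size: float
    seed: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature table must be finite")
        d = self.matrix.shape[1]
        self.informative_indices = frozenset(int(i) for i in self.informative_indices)
        if any(i < 0 or i >= d for i in self.informative_indices):
            raise ValueError("informative indices out of range")

    def to_csv(self, path) -> None:
        d = self.matrix.shape[1]
        df = pd.DataFrame(self.matrix, columns=[f"f{j}" for j in range(d)])
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @staticmethod
    def read_features_csv(path):
        """Read a feature csv (header row, trailing label column)."""
        df = pd.read_csv(path)
        y = df.pop("label").to_numpy()
        return df.to_numpy(dtype=float), y, list(df.columns)


# ---------------------------------------------------------------------------
# image generator

_BACKGROUND = np.array([231.0, 205.0, 224.0])  # eosin-like pale pink


def _class_style(k: int, K: int, side: int):
    """Blob rate, radius and nucleus colour for class ``k`` of ``K``."""
    area_scale = (side / 64.0) ** 2
    rate = area_scale * (10.0 + 8.0 * k)
    radius = 2.0 + 0.8 * k
    hue = (0.62 + 0.11 * k) % 1.0  # purple-ish band, rotated per class
    rgb = colorsys.hsv_to_rgb(hue, 0.55, 0.45)
    return rate, radius, np.array(rgb) * 255.0


def make_synthetic_histology(n_per_class: int, K: int, side: int,
                             seed: int = 0) -> LabeledImageSet:
    """Generate ``K * n_per_class`` stain-like images, deterministic per seed.

    Class k controls the Poisson blob rate, blob radius and nucleus hue, so a
    nearest-neighbour classifier on mean-channel + blob-count statistics
    separates the classes well above chance.
    """
    if K < 2 or side < 32 or n_per_class < 1:
        raise ValueError("need K >= 2, side >= 32, n_per_class >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side]
    images, labels = [], []
    for k in range(K):
        rate, radius, colour = _class_style(k, K, side)
        for _ in range(n_per_class):
            img = np.tile(_BACKGROUND, (side, side, 1)).astype(float)
            n_blobs = rng.poisson(rate)
            cx = rng.uniform(0, side, n_blobs)
            cy = rng.uniform(0, side, n_blobs)
            rr = rng.uniform(0.7, 1.3, n_blobs) * radius
            for x0, y0, r in zip(cx, cy, rr):
                mask = (xx - x0) ** 2 + (yy - y0) ** 2 <= r ** 2
                img[mask] = colour
            img += rng.normal(0.0, 8.0, img.shape)
            images.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(k)
    return LabeledImageSet(images=images, labels=np.array(labels),
                           class_names=[f"class_{k}" for k in range(K)],
                           seed=seed)


def summary_features(image_set: LabeledImageSet) -> np.ndarray:
    """Per-image mean channel intensities plus a dark-blob count."""
    feats = []
    for img in image_set.images:
        gray = img.mean(axis=2)
        _, n_blobs = ndimage.label(gray < 150)
        feats.append([*img.reshape(-1, 3).mean(axis=0), n_blobs])
    return np.asarray(feats, dtype=float)


# ---------------------------------------------------------------------------
# planted feature tables


def make_feature_table(n: int, d: int, k_informative: int, effect_size: float,
                       K: int, seed: int = 0) -> PlantedFeatureTable:
    """Gaussian table with ``k_informative`` planted class-signal columns.

    Planted columns get equally spaced class-conditional means separated by
    ``effect_size`` noise standard deviations; the rest are pure N(0, 1)
    noise.  Deterministic per seed.
    """
    if not 0 < k_informative <= d:
        raise ValueError("need 0 < k_informative <= d")
    if K < 2:
        raise ValueError("need K >= 2")
    if n < 2 * K:
        raise ValueError("need n >= 2K")
    rng = np.random.default_rng(seed)
    labels = rng.permutation(np.arange(n) % K)
    informative = rng.choice(d, size=k_informative, replace=False)
    matrix = rng.standard_normal((n, d))
    offsets = effect_size * (labels - (K - 1) / 2.0)
    matrix[:, informative] += offsets[:, None]
    return PlantedFeatureTable(matrix=matrix, labels=labels,
                               informative_indices=frozenset(informative.tolist()),
                               effect_size=float(effect_size), seed=seed)


# ---------------------------------------------------------------------------
# disk IO (one PNG subdirectory per class; csv with header + label column)


def write_image_set(image_set: LabeledImageSet, root) -> None:
    root = Path(root)
    counters = {}
    for img, lab in zip(image_set.images, image_set.labels):
        name = image_set.class_names[int(lab)]
        sub = root / name
        sub.mkdir(parents=True, exist_ok=True)
        i = counters.get(name, 0)
        counters[name] = i + 1
        Image.fromarray(img).save(sub / f"{name}_{i:04d}.png")


def read_image_set(root) -> LabeledImageSet:
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels = [], []
    for k, sub in enumerate(class_dirs):
        files = sorted(p for p in sub.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        for f in files:
            images.append(np.asarray(Image.open(f).convert("RGB")))
            labels.append(k)
    return LabeledImageSet(images=images, labels=np.array(labels),
                           class_names=[p.name for p in class_dirs])
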
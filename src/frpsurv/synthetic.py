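"""Seeded synthetic data for a two-class IHC survival cohort.

Two generators make every pipeline stage testable without any download:

* ``generate_images`` — stained-tissue-like RGB textures: brown (DAB-like)
  blobs on a bluish (hematoxylin-like) background, where the two survival
  classes differ in blob density and granularity.  This exercises image
  I/O, preprocessing, CNN feature extraction and the GLCM baseline.
* ``generate_features`` — class-structured flattened feature vectors with
  a configurable mean shift on a random coordinate subset and
  equicorrelated within-sample noise.  This is the primary end-to-end
  vehicle: it stands in for the deep features of a real cohort (default
  length 2048, the ResNet-101 contract) with a controllable effect size.

The default cohort shape is 29 negative (<5-year) and 51
positive (>5-year) samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SyntheticImageConfig",
    "SyntheticFeatureConfig",
    "generate_images",
    "generate_features",
    "write_image_dataset",
    "load_image_dataset",
]

# DAB chromogen renders brown, hematoxylin counterstain blue-purple
_DAB_BROWN = (130, 80, 30)
_HEMATOXYLIN_BLUE = (150, 150, 200)


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Two-class stained-texture image generator settings.

    ``blob_density`` gives the expected number of stained blobs per image
    for (class 0, class 1); the density (and the smaller radii of class-1
    blobs) is the class signal, detectable by both texture and deep
    features.  Default densities 20 vs 60 give roughly the 1:3 stained-area
    ratio used throughout development.
    """

    n_per_class: tuple[int, int] = (29, 51)
    image_size: tuple[int, int] = (128, 128)
    blob_density: tuple[float, float] = (20.0, 60.0)
    blob_radius: tuple[float, float] = (3.0, 9.0)
    stain_rgb: tuple[int, int, int] = _DAB_BROWN
    background_rgb: tuple[int, int, int] = _HEMATOXYLIN_BLUE
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 1:
            raise ValueError("n_per_class entries must be >= 1")
        if min(self.image_size) < 8:
            raise ValueError("image_size too small")
        if min(self.blob_density) <= 0 or min(self.blob_radius) <= 0:
            raise ValueError("densities and radii must be positive")
        if self.blob_density[0] == self.blob_density[1]:
            raise ValueError("blob densities must differ between classes "
                             "(they carry the class signal)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticFeatureConfig:
    """Class-structured feature-vector generator settings.

    Class 1 vectors are shifted by ``class_mean_shift`` (in within-class
    standard deviations, i.e. Cohen's d per affected coordinate) on a
    seeded random subset of ``shift_fraction`` of the N coordinates.
    ``within_correlation`` is the equicorrelation of the noise across
    coordinates of one sample (a shared latent factor).

    The downstream FRP representation is invariant to shifting or scaling
    a whole feature vector, so the class signal must change the *shape* of
    the per-sample value distribution: the shifted subset makes class-1
    vectors bimodal.  ``baseline_sd`` (the spread of the class-independent
    coordinate pattern) is therefore kept small relative to the unit noise,
    so that the effect size governs how pronounced that bimodality is.
    """

    n_per_class: tuple[int, int] = (29, 51)
    N: int = 2048
    class_mean_shift: float = 2.0
    within_correlation: float = 0.3
    shift_fraction: float = 0.5
    baseline_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 1:
            raise ValueError("n_per_class entries must be >= 1")
        if self.N < 13:
            raise ValueError("N must be >= 13 (compressible to n=13)")
        if self.class_mean_shift < 0:
            raise ValueError("class_mean_shift must be >= 0")
        if not 0.0 <= self.within_correlation < 1.0:
            raise ValueError("within_correlation must be in [0, 1)")
        if not 0.0 < self.shift_fraction <= 1.0:
            raise ValueError("shift_fraction must be in (0, 1]")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")


def _render_image(rng: np.random.Generator, cfg: SyntheticImageConfig,
                  label: int) -> np.ndarray:
    h, w = cfg.image_size
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(cfg.background_rgb, dtype=float)

    n_blobs = rng.poisson(cfg.blob_density[label])
    r_lo, r_hi = cfg.blob_radius
    if label == 1:
        # the high-density class also has finer granularity
        r_hi = max(r_lo + 0.5, 0.6 * r_hi)
    yy, xx = np.mgrid[0:h, 0:w]
    stain = np.asarray(cfg.stain_rgb, dtype=float)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(r_lo, r_hi)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        # soft-edged disk: full stain inside, smooth falloff at the rim
        alpha = np.clip(1.0 - (np.sqrt(d2) - r) / max(r * 0.3, 1.0), 0.0, 1.0)
        strength = rng.uniform(0.6, 1.0)
        img += (alpha * strength)[:, :, None] * (stain - img)
    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_images(config: SyntheticImageConfig = SyntheticImageConfig()):
    """Generate the labeled two-class image set.

    Returns ``(images, labels, ids)``: a list of (H, W, 3) uint8 arrays,
    an int array of class labels (1 = the denser, >5-year-like class), and
    string image ids.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    images, labels, ids = [], [], []
    for label in (0, 1):
        for j in range(config.n_per_class[label]):
            images.append(_render_image(rng, config, label))
            labels.append(label)
            ids.append(f"class{label}_{j:03d}")
    return images, np.asarray(labels, dtype=int), ids


def write_image_dataset(out_dir: str | Path, images, labels, ids) -> Path:
    """Write PNGs plus ``labels.csv`` (image_id, class, split_hint)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, label, image_id in zip(images, labels, ids):
        fname = f"{image_id}.png"
        Image.fromarray(img, mode="RGB").save(out_dir / fname)
        rows.append((fname, int(label), "cv"))
    csv_path = out_dir / "labels.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "class", "split_hint"])
        writer.writerows(rows)
    return csv_path


def load_image_dataset(labels_csv: str | Path):
    """Read a ``labels.csv`` + image folder back into (paths, labels, ids)."""
    labels_csv = Path(labels_csv)
    folder = labels_csv.parent
    paths, labels, ids = [], [], []
    with open(labels_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            paths.append(folder / row["image_id"])
            labels.append(int(row["class"]))
            ids.append(row["image_id"])
    return paths, np.asarray(labels, dtype=int), ids


def generate_features(config: SyntheticFeatureConfig = SyntheticFeatureConfig()):
    """Generate the labeled two-class feature-vector set.

    Returns ``(X, y)`` with X of shape (n0 + n1, N).  Coordinates in a
    seeded random subset (``shift_fraction`` of N) are shifted upward by
    ``class_mean_shift`` within-class standard deviations for class-1
    samples; within-sample noise is equicorrelated at
    ``within_correlation`` through a shared latent factor.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    base_mean = rng.normal(0.0, cfg.baseline_sd, size=cfg.N)
    n_shift = max(1, int(round(cfg.shift_fraction * cfg.N)))
    shifted = rng.choice(cfg.N, size=n_shift, replace=False)

    rho = cfg.within_correlation
    rows, labels = [], []
    for label in (0, 1):
        mean = base_mean.copy()
        if label == 1:
            mean[shifted] += cfg.class_mean_shift
        for _ in range(cfg.n_per_class[label]):
            latent = rng.normal()
            noise = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * rng.normal(size=cfg.N)
            rows.append(mean + noise)
            labels.append(label)
    return np.asarray(rows), np.asarray(labels, dtype=int)
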
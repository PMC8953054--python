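"""Synthetic ultrasound-like ROI phantoms with known ground truth.

The speckle background is fully developed speckle: the envelope (magnitude)
of a spatially correlated zero-mean complex Gaussian field, whose first-order
amplitude statistic is Rayleigh.  Microcalcifications are small bright
isotropic Gaussian bumps added at random interior positions, emulating the
"grains of salt" appearance of placental microcalcifications.

The default configuration produces 96 labeled 64x64 ROIs (48 healthy,
48 calcified), the dataset shape of the clinical study this package models.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict
from typing import List

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidArgumentError
from .roi_io import GrayImage, round_half_up, save_grayscale, write_manifest

__all__ = [
    "PhantomConfig",
    "LabeledRoiSet",
    "generate_speckle",
    "speckle_envelope",
    "add_calcifications",
    "generate_roi_set",
    "write_roi_set",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom generator.

    The speck parameters (``n_specks=4``, ``speck_sigma=1.5``,
    ``speck_amplitude=80``) together with the speckle background
    (``speckle_corr_sigma``, ``background_mean``) are calibrated so that
    single-feature classification performs well above chance without
    saturating; see docs/methods.md.
    """

    roi_size: int = 64
    n_healthy: int = 48
    n_calcified: int = 48
    speckle_corr_sigma: float = 1.6
    background_mean: float = 32.0
    n_specks: int = 4
    speck_sigma: float = 1.5
    speck_amplitude: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_size < 16:
            raise InvalidArgumentError("roi_size must be >= 16")
        if self.n_healthy < 0 or self.n_calcified < 0 or self.n_specks < 0:
            raise InvalidArgumentError("counts must be >= 0")
        if not 0 <= self.background_mean <= 255:
            raise InvalidArgumentError("background_mean must lie in [0, 255]")
        if self.speck_amplitude < 0:
            raise InvalidArgumentError("speck_amplitude must be >= 0")
        if self.speckle_corr_sigma <= 0:
            raise InvalidArgumentError("speckle_corr_sigma must be > 0")


@dataclass
class LabeledRoiSet:
    """A list of grayscale ROIs with per-ROI class labels."""

    rois: List[GrayImage]
    labels: List[str]
    config: PhantomConfig

    def __post_init__(self) -> None:
        if len(self.rois) != len(self.labels):
            raise InvalidArgumentError("rois and labels must have equal length")
        for lab in self.labels:
            if lab not in ("healthy", "calcified"):
                raise InvalidArgumentError(f"unexpected label {lab!r}")


def speckle_envelope(size: int, corr_sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Pre-quantization speckle envelope (float, unscaled).

    Magnitude of a complex Gaussian field whose real and imaginary parts are
    independent white-noise fields smoothed with an isotropic Gaussian of
    scale ``corr_sigma`` pixels.  Marginally Rayleigh: mean/std =
    sqrt(pi/(4-pi)) ~= 1.913.
    """
    if size < 16:
        raise InvalidArgumentError("size must be >= 16")
    if corr_sigma <= 0:
        raise InvalidArgumentError("corr_sigma must be > 0")
    re = gaussian_filter(rng.standard_normal((size, size)), corr_sigma, mode="wrap")
    im = gaussian_filter(rng.standard_normal((size, size)), corr_sigma, mode="wrap")
    return np.hypot(re, im)


def generate_speckle(
    size: int, corr_sigma: float, background_mean: float, rng: np.random.Generator
) -> GrayImage:
    """One speckle-only ROI, rescaled to the target mean and quantized to 8 bits."""
    env = speckle_envelope(size, corr_sigma, rng)
    scaled = env * (background_mean / env.mean())
    return round_half_up(np.clip(scaled, 0, 255)).astype(np.uint8)


def add_calcifications(
    image: GrayImage,
    n_specks: int,
    speck_sigma: float,
    amplitude: float,
    rng: np.random.Generator,
) -> GrayImage:
    """Return a copy of *image* with bright Gaussian specks added.

    Speck centers are uniform over the interior, kept >= 2*speck_sigma from
    every border; the input image is never modified.
    """
    if n_specks < 0:
        raise InvalidArgumentError("n_specks must be >= 0")
    if n_specks > 0 and speck_sigma <= 0:
        raise InvalidArgumentError("speck_sigma must be > 0 when adding specks")
    img = np.asarray(image)
    out = img.astype(float).copy()
    h, w = out.shape
    margin = 2.0 * speck_sigma
    if n_specks > 0 and (h - 1 < 2 * margin or w - 1 < 2 * margin):
        raise InvalidArgumentError("image too small for the speck margin")
    rows, cols = np.mgrid[0:h, 0:w]
    for _ in range(n_specks):
        cr = rng.uniform(margin, (h - 1) - margin)
        cc = rng.uniform(margin, (w - 1) - margin)
        r2 = (rows - cr) ** 2 + (cols - cc) ** 2
        out += amplitude * np.exp(-r2 / (2.0 * speck_sigma**2))
    return round_half_up(np.clip(out, 0, 255)).astype(np.uint8)


def generate_roi_set(config: PhantomConfig) -> LabeledRoiSet:
    """Generate the full labeled phantom set; bit-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    rois: List[GrayImage] = []
    labels: List[str] = []
    for _ in range(config.n_healthy):
        rois.append(
            generate_speckle(
                config.roi_size, config.speckle_corr_sigma, config.background_mean, rng
            )
        )
        labels.append("healthy")
    for _ in range(config.n_calcified):
        base = generate_speckle(
            config.roi_size, config.speckle_corr_sigma, config.background_mean, rng
        )
        rois.append(
            add_calcifications(
                base, config.n_specks, config.speck_sigma, config.speck_amplitude, rng
            )
        )
        labels.append("calcified")
    return LabeledRoiSet(rois=rois, labels=labels, config=config)


def write_roi_set(roi_set: LabeledRoiSet, out_dir: str | os.PathLike) -> None:
    """Write ROIs as 8-bit PNGs plus a CSV manifest and a flat config file."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (roi, lab) in enumerate(zip(roi_set.rois, roi_set.labels)):
        fname = f"roi_{i:04d}_{lab}.png"
        save_grayscale(os.path.join(out_dir, fname), roi)
        rows.append({"filename": fname, "label": lab})
    write_manifest(os.path.join(out_dir, "manifest.csv"), rows)
    with open(os.path.join(out_dir, "phantom_config.txt"), "w") as fh:
        for key, val in asdict(roi_set.config).items():
            fh.write(f"{key}={val}\n")
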
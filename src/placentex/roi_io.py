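"""Image loading, 8-bit grayscale conversion and fixed-size ROI handling.

A grayscale image is represented throughout the package as a 2-D
``numpy.ndarray`` of dtype ``uint8`` (intensities 0–255). :func:`as_gray_image`
validates/coerces arbitrary arrays into that form.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "GrayImage",
    "RoiSpec",
    "as_gray_image",
    "load_grayscale",
    "save_grayscale",
    "grid_rois",
    "crop",
    "write_manifest",
    "read_manifest",
]

GrayImage = np.ndarray  # 2-D uint8 array, values in [0, 255]

# Rec.601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

Label = Literal["healthy", "calcified", "unlabeled"]
VALID_LABELS = ("healthy", "calcified", "unlabeled")


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves rounding up (away from banker's)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def as_gray_image(arr: np.ndarray) -> GrayImage:
    """Validate and coerce *arr* into a 2-D uint8 grayscale image."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise InvalidArgumentError(f"expected a non-empty 2-D image, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.any(a < 0) or np.any(a > 255):
            raise InvalidArgumentError("intensities must lie in [0, 255]")
        a = round_half_up(a).astype(np.uint8)
    return a


@dataclass(frozen=True)
class RoiSpec:
    """A square region of interest inside a parent image.

    Coordinates are 0-based, row-major, half-open: the ROI covers rows
    ``[row0, row0+size)`` and columns ``[col0, col0+size)``.
    """

    row0: int
    col0: int
    size: int
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise InvalidArgumentError("ROI corner indices must be non-negative")
        if self.size < 1:
            raise InvalidArgumentError("ROI size must be >= 1")
        if self.label not in VALID_LABELS:
            raise InvalidArgumentError(f"label must be one of {VALID_LABELS}")


def load_grayscale(path: str | os.PathLike) -> GrayImage:
    """Load a raster image as 8-bit grayscale.

    RGB(A) inputs are converted with the Rec.601 luma weighting
    (0.299 R + 0.587 G + 0.114 B) and rounded half-up; single-channel
    inputs pass through unchanged.
    """
    try:
        raw = iio.imread(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    a = np.asarray(raw)
    if a.ndim == 3:
        if a.shape[2] < 3:  # e.g. gray+alpha
            a = a[:, :, 0]
        else:
            a = a[:, :, :3].astype(float) @ _LUMA
    elif a.ndim != 2:
        raise IOError(f"unsupported image dimensionality {a.ndim} in {path!r}")
    return as_gray_image(np.clip(a, 0, 255))


def save_grayscale(path: str | os.PathLike, image: GrayImage) -> None:
    """Write a grayscale image as an 8-bit PNG/TIFF (format by extension)."""
    iio.imwrite(path, as_gray_image(image))


def grid_rois(image: GrayImage, size: int, stride: int) -> list[RoiSpec]:
    """Enumerate all fully contained square ROIs on a regular grid.

    ROIs are returned in row-major order starting at (0, 0), all labeled
    ``unlabeled``.
    """
    img = as_gray_image(image)
    h, w = img.shape
    if size < 1 or size > min(h, w):
        raise InvalidArgumentError(f"ROI size {size} must be in [1, {min(h, w)}]")
    if stride < 1:
        raise InvalidArgumentError("stride must be >= 1")
    return [
        RoiSpec(r, c, size)
        for r in range(0, h - size + 1, stride)
        for c in range(0, w - size + 1, stride)
    ]


def crop(image: GrayImage, spec: RoiSpec) -> GrayImage:
    """Extract the ROI as an independent copy (mutation never aliases the parent)."""
    img = as_gray_image(image)
    h, w = img.shape
    if spec.row0 + spec.size > h or spec.col0 + spec.size > w:
        raise InvalidArgumentError(
            f"ROI {spec} exceeds image bounds {h}x{w}"
        )
    return img[spec.row0 : spec.row0 + spec.size, spec.col0 : spec.col0 + spec.size].copy()


def write_manifest(path: str | os.PathLike, rows: list[dict]) -> None:
    """Write a ROI manifest CSV (filename,row0,col0,size,label)."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "filename" not in df.columns or "label" not in df.columns:
        raise InvalidArgumentError("manifest must have 'filename' and 'label' columns")
    return df
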
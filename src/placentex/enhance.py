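"""Contrast enhancement (unsharp masking) and edge-map binarization.

Unsharp masking realizes the high-pass stage as identity minus a Gaussian
blur: out = I + amount * (I - G_sigma * I).  Edge maps come from either the
3x3 Sobel gradient magnitude (first derivative) or a Laplacian-of-Gaussian
zero-crossing detector (second derivative); both feed the box-counting
fractal dimension.

All convolutions use reflective boundary handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, gaussian_filter
from skimage.filters import threshold_otsu

from .errors import InvalidArgumentError
from .roi_io import GrayImage, as_gray_image, round_half_up

__all__ = [
    "EnhanceParams",
    "BinaryImage",
    "unsharp_response",
    "unsharp_enhance",
    "sobel_magnitude",
    "sobel_edges",
    "log_kernel",
    "log_response",
    "log_edges",
]

BinaryImage = np.ndarray  # 2-D bool array, True = edge/foreground

_SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_GY = _SOBEL_GX.T


@dataclass(frozen=True)
class EnhanceParams:
    """Unsharp-mask parameters: Gaussian blur scale (px) and high-pass weight."""

    blur_sigma: float = 2.0
    amount: float = 0.8

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0:
            raise InvalidArgumentError("blur_sigma must be > 0")
        if self.amount < 0:
            raise InvalidArgumentError("amount must be >= 0")


def unsharp_response(image: GrayImage, params: EnhanceParams) -> np.ndarray:
    """Pre-clipping float unsharp response I + amount*(I - G*I)."""
    img = as_gray_image(image).astype(float)
    lowpass = gaussian_filter(img, params.blur_sigma, mode="reflect")
    return img + params.amount * (img - lowpass)


def unsharp_enhance(image: GrayImage, params: EnhanceParams) -> GrayImage:
    """Unsharp-mask contrast enhancement, clipped and re-quantized to 8 bits."""
    return round_half_up(np.clip(unsharp_response(image, params), 0, 255)).astype(np.uint8)


def sobel_magnitude(image: GrayImage) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) from the standard 3x3 Sobel pair."""
    img = as_gray_image(image)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise InvalidArgumentError("image must be at least 3x3 for the Sobel kernels")
    f = img.astype(float)
    gx = convolve(f, _SOBEL_GX, mode="reflect")
    gy = convolve(f, _SOBEL_GY, mode="reflect")
    return np.hypot(gx, gy)


def sobel_edges(image: GrayImage, threshold: float | str = "auto") -> BinaryImage:
    """Binarized Sobel edge map: magnitude > threshold ("auto" = Otsu)."""
    mag = sobel_magnitude(image)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise InvalidArgumentError("threshold must be a number or 'auto'")
        if mag.max() == mag.min():
            return np.zeros_like(mag, dtype=bool)
        threshold = float(threshold_otsu(mag))
    return mag > threshold


def log_kernel(sigma: float) -> np.ndarray:
    """Discrete Laplacian-of-Gaussian kernel, zero-sum normalized.

    Analytic form (r^2 - 2 sigma^2)/sigma^4 * exp(-r^2 / 2 sigma^2),
    truncated at half-width ceil(3*sigma), then shifted so the entries sum
    to exactly zero (a constant image must yield an identically zero
    response).
    """
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be > 0")
    half = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    r2 = x * x + y * y
    k = (r2 - 2.0 * sigma**2) / sigma**4 * np.exp(-r2 / (2.0 * sigma**2))
    return k - k.mean()


def log_response(image: GrayImage, sigma: float) -> np.ndarray:
    """Float LoG filter response of the image (reflective boundary)."""
    img = as_gray_image(image)
    kernel = log_kernel(sigma)
    if min(img.shape) < kernel.shape[0]:
        raise InvalidArgumentError(
            f"image {img.shape} smaller than the truncated LoG kernel {kernel.shape}"
        )
    return convolve(img.astype(float), kernel, mode="reflect")


def log_edges(
    image: GrayImage, sigma: float = 2.0, threshold: float | str = "auto"
) -> BinaryImage:
    """LoG zero-crossing edge map.

    A pixel is marked when it sits on the weak side (smaller absolute
    response) of a sign change with a 4-neighbor and the local response span
    across the pair exceeds the threshold.  "auto" sets the threshold to
    0.75 x mean absolute response (floored at 1e-6 so that numerically flat
    responses yield no edges).
    """
    resp = log_response(image, sigma)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise InvalidArgumentError("threshold must be a number or 'auto'")
        threshold = 0.75 * float(np.mean(np.abs(resp)))
    threshold = max(float(threshold), 1e-6)

    edges = np.zeros(resp.shape, dtype=bool)
    for axis in (0, 1):
        a = resp if axis == 0 else resp.T
        left, right = a[:, :-1], a[:, 1:]
        crossing = (np.sign(left) * np.sign(right) < 0) & (
            np.abs(left - right) > threshold
        )
        weak_left = np.abs(left) <= np.abs(right)
        e = np.zeros(a.shape, dtype=bool)
        e[:, :-1] |= crossing & weak_left
        e[:, 1:] |= crossing & ~weak_left
        edges |= e if axis == 0 else e.T
    return edges
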
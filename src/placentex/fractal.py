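"""Box-counting fractal dimension of binary edge maps.

The raster is partitioned into axis-aligned r x r boxes anchored at the
origin (ragged last row/column allowed) for a ladder of dyadic box sizes,
and the fractal dimension is the ordinary-least-squares slope of
log(N_r) versus log(1/r), where N_r is the number of boxes containing at
least one foreground pixel.  The coefficient of determination of the fit is
reported so callers can reject poorly scaling inputs.

FD_I denotes the dimension of the Sobel edge map, FD_II that of the
Laplacian-of-Gaussian edge map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .enhance import BinaryImage, log_edges, sobel_edges
from .errors import DegenerateInputError, InvalidArgumentError
from .roi_io import GrayImage

__all__ = [
    "BoxCountCurve",
    "FdEstimate",
    "default_box_sizes",
    "box_count",
    "fractal_dimension",
    "fd_pair",
]


@dataclass(frozen=True)
class BoxCountCurve:
    """Box sizes r (strictly decreasing) with occupied-box counts N_r."""

    sizes: tuple
    counts: tuple


@dataclass(frozen=True)
class FdEstimate:
    fd: float
    r2: float
    curve: BoxCountCurve


def default_box_sizes(shape: tuple[int, int]) -> list[int]:
    """Dyadic ladder {2, 4, 8, ...} up to min(H, W) / 2."""
    top = min(shape) // 2
    sizes = []
    r = 2
    while r <= top:
        sizes.append(r)
        r *= 2
    return sizes


def _count_occupied(binary: np.ndarray, r: int) -> int:
    h, w = binary.shape
    nbr, nbc = -(-h // r), -(-w // r)  # ceil division
    padded = np.zeros((nbr * r, nbc * r), dtype=bool)
    padded[:h, :w] = binary
    blocks = padded.reshape(nbr, r, nbc, r)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count(binary: BinaryImage, sizes: Sequence[int]) -> BoxCountCurve:
    """Occupied-box counts over the given box-size ladder."""
    b = np.asarray(binary, dtype=bool)
    if b.ndim != 2:
        raise InvalidArgumentError("binary image must be 2-D")
    if not b.any():
        raise DegenerateInputError("empty foreground: box counting undefined")
    uniq = sorted(set(int(s) for s in sizes), reverse=True)
    if len(uniq) < 2:
        raise InvalidArgumentError("need at least 2 distinct box sizes")
    if uniq[-1] < 1:
        raise InvalidArgumentError("box sizes must be >= 1")
    counts = tuple(_count_occupied(b, r) for r in uniq)
    return BoxCountCurve(sizes=tuple(uniq), counts=counts)


def fractal_dimension(
    binary: BinaryImage, sizes: Sequence[int] | None = None
) -> FdEstimate:
    """OLS slope of log N_r on log(1/r), with the r^2 of the fit."""
    b = np.asarray(binary, dtype=bool)
    if sizes is None:
        sizes = default_box_sizes(b.shape)
    curve = box_count(b, sizes)
    x = np.log(1.0 / np.asarray(curve.sizes, dtype=float))
    y = np.log(np.asarray(curve.counts, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return FdEstimate(fd=float(slope), r2=r2, curve=curve)


def fd_pair(
    image: GrayImage,
    sobel_threshold: float | str = "auto",
    log_sigma: float = 2.0,
    log_threshold: float | str = "auto",
) -> tuple[FdEstimate, FdEstimate]:
    """(FD_I, FD_II): box-counting dimension after Sobel and after LoG edges.

    Raises :class:`DegenerateInputError` when an edge map is empty (e.g. a
    constant ROI); callers should record the ROI's FD as missing.
    """
    fd_i = fractal_dimension(sobel_edges(image, threshold=sobel_threshold))
    fd_ii = fractal_dimension(log_edges(image, sigma=log_sigma, threshold=log_threshold))
    return fd_i, fd_ii
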
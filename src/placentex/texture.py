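"""First-order histogram features and GLCM (second-order) texture features.

First-order statistics (standard deviation, skewness, kurtosis) are
probability-weighted population moments of the 256-bin intensity histogram.
Second-order statistics (contrast, homogeneity, correlation, energy,
entropy) are computed from a normalized gray-level co-occurrence matrix
Np(i, j, delta, theta) accumulated at the native L = 256 gray levels,
with theta in {0, 45, 90, 135} degrees.

Kurtosis is the non-excess (Pearson) kurtosis, entropy is Shannon entropy
in bits.  By default features are reported averaged over the four angles,
one value per ROI per feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .roi_io import GrayImage, as_gray_image

__all__ = [
    "L_LEVELS",
    "IntensityDistribution",
    "FirstOrderFeatures",
    "GLCM",
    "GlcmFeatures",
    "histogram",
    "first_order_features",
    "compute_glcm",
    "glcm_features",
    "angle_averaged_features",
    "GLCM_ANGLES",
]

L_LEVELS = 256
GLCM_ANGLES = (0, 45, 90, 135)

# (row, col) displacement per unit delta for each angle, image convention
# (rows increase downward): 0 deg -> right, 45 -> up-right, 90 -> up,
# 135 -> up-left.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class IntensityDistribution:
    """Normalized gray-level histogram p(i), i in [0, L-1], and its mean M."""

    p: np.ndarray
    mean_m: float

    def __post_init__(self) -> None:
        if self.p.shape != (L_LEVELS,) or np.any(self.p < 0):
            raise InvalidArgumentError("p must be a non-negative length-256 vector")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise InvalidArgumentError("p must sum to 1")


@dataclass(frozen=True)
class FirstOrderFeatures:
    sd: float
    sk: float
    kr: float


@dataclass(frozen=True)
class GlcmFeatures:
    c: float  # contrast
    h: float  # homogeneity
    cr: float  # correlation (NaN when degenerate and allowed)
    e: float  # energy (angular second moment)
    en: float  # entropy, bits


@dataclass(frozen=True)
class GLCM:
    """Normalized co-occurrence matrix for one (delta, theta)."""

    matrix: np.ndarray  # L x L, sums to 1
    delta: int
    theta: int

    @property
    def marginal_p_i(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def marginal_p_j(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def marginal_mu_i(self) -> float:
        return float(np.arange(L_LEVELS) @ self.marginal_p_i)

    @property
    def marginal_mu_j(self) -> float:
        return float(np.arange(L_LEVELS) @ self.marginal_p_j)

    @property
    def marginal_sigma_i(self) -> float:
        i = np.arange(L_LEVELS)
        return float(np.sqrt((i - self.marginal_mu_i) ** 2 @ self.marginal_p_i))

    @property
    def marginal_sigma_j(self) -> float:
        j = np.arange(L_LEVELS)
        return float(np.sqrt((j - self.marginal_mu_j) ** 2 @ self.marginal_p_j))


def histogram(image: GrayImage) -> IntensityDistribution:
    """Normalized 256-bin histogram and probability-weighted mean intensity."""
    img = as_gray_image(image)
    counts = np.bincount(img.ravel(), minlength=L_LEVELS).astype(float)
    p = counts / counts.sum()
    mean_m = float(np.arange(L_LEVELS) @ p)
    return IntensityDistribution(p=p, mean_m=mean_m)


def first_order_features(dist: IntensityDistribution) -> FirstOrderFeatures:
    """Population SD, skewness and (non-excess) kurtosis of the histogram.

    Raises
    ------
    DegenerateInputError
        If the distribution is concentrated on one gray level (SD = 0):
        skewness and kurtosis are then undefined.
    """
    i = np.arange(L_LEVELS, dtype=float)
    d = i - dist.mean_m
    var = float(d**2 @ dist.p)
    sd = np.sqrt(var)
    if sd == 0.0:
        raise DegenerateInputError(
            "constant image: SD = 0, skewness and kurtosis undefined"
        )
    sk = float(d**3 @ dist.p) / sd**3
    kr = float(d**4 @ dist.p) / sd**4
    return FirstOrderFeatures(sd=float(sd), sk=sk, kr=kr)


def compute_glcm(
    image: GrayImage, delta: int = 1, theta: int = 0, symmetric: bool = True
) -> GLCM:
    """Accumulate the normalized co-occurrence matrix at offset (delta, theta).

    Every ordered pixel pair (x, x + offset) with both ends inside the image
    contributes one count; in symmetric mode the reversed pair is counted
    too, making the matrix exactly symmetric.
    """
    img = as_gray_image(image)
    if delta < 1:
        raise InvalidArgumentError("delta must be >= 1")
    if theta not in _OFFSETS:
        raise InvalidArgumentError(f"theta must be one of {GLCM_ANGLES}")
    dr, dc = (o * delta for o in _OFFSETS[theta])
    h, w = img.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise InvalidArgumentError(
            f"image {img.shape} has no valid pairs at delta={delta}, theta={theta}"
        )
    a = img[r0:r1, c0:c1].ravel().astype(np.intp)
    b = img[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel().astype(np.intp)
    counts = np.zeros((L_LEVELS, L_LEVELS), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    return GLCM(matrix=counts / counts.sum(), delta=delta, theta=theta)


def glcm_features(g: GLCM, degenerate_correlation: str = "raise") -> GlcmFeatures:
    """Contrast, homogeneity, correlation, energy and entropy of one GLCM.

    Correlation is undefined when either marginal standard deviation is zero
    (constant image); ``degenerate_correlation`` chooses between raising
    :class:`DegenerateInputError` (default) and reporting NaN.
    """
    if degenerate_correlation not in ("raise", "nan"):
        raise InvalidArgumentError("degenerate_correlation must be 'raise' or 'nan'")
    m = g.matrix
    i_idx, j_idx = np.nonzero(m)
    p = m[i_idx, j_idx]
    i = i_idx.astype(float)
    j = j_idx.astype(float)
    c = float(((i - j) ** 2) @ p)
    h = float(p @ (1.0 / (1.0 + np.abs(i - j))))
    e = float(p @ p)
    en = float(-(p @ np.log2(p)))  # p > 0 by construction; 0*log0 := 0
    si, sj = g.marginal_sigma_i, g.marginal_sigma_j
    if si == 0.0 or sj == 0.0:
        if degenerate_correlation == "raise":
            raise DegenerateInputError(
                "constant image: GLCM correlation undefined (zero marginal SD)"
            )
        cr = float("nan")
    else:
        cr = float(((i - g.marginal_mu_i) * (j - g.marginal_mu_j)) @ p / (si * sj))
    return GlcmFeatures(c=c, h=h, cr=cr, e=e, en=max(en, 0.0))


def angle_averaged_features(
    image: GrayImage,
    delta: int = 1,
    symmetric: bool = True,
    degenerate_correlation: str = "raise",
) -> GlcmFeatures:
    """Arithmetic mean of each GLCM feature over the four standard angles."""
    per_angle = [
        glcm_features(
            compute_glcm(image, delta=delta, theta=t, symmetric=symmetric),
            degenerate_correlation=degenerate_correlation,
        )
        for t in GLCM_ANGLES
    ]
    return GlcmFeatures(
        c=float(np.mean([f.c for f in per_angle])),
        h=float(np.mean([f.h for f in per_angle])),
        cr=float(np.mean([f.cr for f in per_angle])),
        e=float(np.mean([f.e for f in per_angle])),
        en=float(np.mean([f.en for f in per_angle])),
    )
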
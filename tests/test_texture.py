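"""First-order histogram moments and GLCM features against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placentex.errors import DegenerateInputError, InvalidArgumentError
from placentex.texture import (
    GLCM_ANGLES,
    angle_averaged_features,
    compute_glcm,
    first_order_features,
    glcm_features,
    histogram,
)


def glcm_oracle(img, delta, theta_deg, symmetric):
    """Exhaustive pair enumeration, offset derived independently via trig."""
    theta = np.deg2rad(theta_deg)
    dr = -int(round(delta * np.sin(theta)))
    dc = int(round(delta * np.cos(theta)))
    h, w = img.shape
    counts = {}
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                pairs = [(int(img[r, c]), int(img[r2, c2]))]
                if symmetric:
                    pairs.append((int(img[r2, c2]), int(img[r, c])))
                for key in pairs:
                    counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def glcm_features_oracle(prob_dict):
    """Double-loop sums over the sparse joint distribution."""
    mu_i = sum(i * p for (i, _), p in prob_dict.items())
    mu_j = sum(j * p for (_, j), p in prob_dict.items())
    si = np.sqrt(sum((i - mu_i) ** 2 * p for (i, _), p in prob_dict.items()))
    sj = np.sqrt(sum((j - mu_j) ** 2 * p for (_, j), p in prob_dict.items()))
    c = sum((i - j) ** 2 * p for (i, j), p in prob_dict.items())
    h = sum(p / (1 + abs(i - j)) for (i, j), p in prob_dict.items())
    e = sum(p * p for p in prob_dict.values())
    en = -sum(p * np.log2(p) for p in prob_dict.values() if p > 0)
    cr = (
        sum((i - mu_i) * (j - mu_j) * p for (i, j), p in prob_dict.items())
        / (si * sj)
        if si > 0 and sj > 0
        else None
    )
    return c, h, cr, e, en


# ------------------------------------------------------------- histogram --

def test_histogram_constant_image():
    dist = histogram(np.full((4, 4), 128, dtype=np.uint8))
    assert dist.p[128] == 1.0
    assert dist.mean_m == 128.0


def test_histogram_two_point():
    img = np.array([[0, 255], [255, 0]], dtype=np.uint8)
    dist = histogram(img)
    assert dist.p[0] == dist.p[255] == 0.5
    assert dist.mean_m == 127.5


def test_histogram_mean_equals_pixel_mean(random_image):
    dist = histogram(random_image)
    assert dist.p.sum() == pytest.approx(1.0, abs=1e-12)
    assert dist.mean_m == pytest.approx(random_image.mean(), abs=1e-10)


# ----------------------------------------------------------- first order --

def test_first_order_degenerate_on_constant():
    with pytest.raises(DegenerateInputError):
        first_order_features(histogram(np.full((4, 4), 7, dtype=np.uint8)))


def test_first_order_two_point_symmetric():
    img = np.array([[0, 255], [255, 0]], dtype=np.uint8)
    fo = first_order_features(histogram(img))
    assert fo.sd == pytest.approx(127.5)
    assert fo.sk == pytest.approx(0.0, abs=1e-12)
    assert fo.kr == pytest.approx(1.0)  # two-point distributions attain the bound


def test_first_order_matches_pixel_loop_oracle(random_image):
    vals = [float(v) for v in random_image.ravel()]
    n = len(vals)
    m = sum(vals) / n
    m2 = sum((v - m) ** 2 for v in vals) / n
    m3 = sum((v - m) ** 3 for v in vals) / n
    m4 = sum((v - m) ** 4 for v in vals) / n
    fo = first_order_features(histogram(random_image))
    assert fo.sd == pytest.approx(np.sqrt(m2), abs=1e-10)
    assert fo.sk == pytest.approx(m3 / m2**1.5, abs=1e-10)
    assert fo.kr == pytest.approx(m4 / m2**2, abs=1e-10)


# ------------------------------------------------------------------ GLCM --

def test_glcm_2x2_constant():
    g = compute_glcm(np.zeros((2, 2), dtype=np.uint8), delta=1, theta=0)
    assert g.matrix[0, 0] == 1.0
    assert g.matrix.sum() == 1.0


def test_glcm_checkerboard(checkerboard):
    g = compute_glcm(checkerboard, delta=1, theta=0, symmetric=True)
    assert g.matrix[0, 1] == pytest.approx(0.5)
    assert g.matrix[1, 0] == pytest.approx(0.5)
    assert g.matrix.sum() == pytest.approx(1.0)
    assert np.count_nonzero(g.matrix) == 2


@pytest.mark.parametrize("theta", GLCM_ANGLES)
@pytest.mark.parametrize("symmetric", [True, False])
def test_glcm_matches_enumeration_oracle(theta, symmetric, rng):
    img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
    g = compute_glcm(img, delta=1, theta=theta, symmetric=symmetric)
    oracle = glcm_oracle(img, 1, theta, symmetric)
    dense = np.zeros((256, 256))
    for (i, j), p in oracle.items():
        dense[i, j] = p
    np.testing.assert_allclose(g.matrix, dense, atol=1e-15)


@pytest.mark.parametrize("theta,skimage_angle_idx", [(0, 0), (45, 3), (90, 2), (135, 1)])
def test_glcm_agrees_with_skimage(theta, skimage_angle_idx, rng):
    """Cross-check vs skimage.feature.graycomatrix.

    skimage measures angles with +d rows at 90 degrees (downward), so its
    45/135 angles correspond to 135/45 in the image-up convention used here.
    """
    from skimage.feature import graycomatrix

    img = rng.integers(0, 16, size=(10, 10)).astype(np.uint8)
    angles = [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    sk = graycomatrix(img, [1], angles, levels=16, symmetric=True, normed=True)
    mine = compute_glcm(img, delta=1, theta=theta, symmetric=True).matrix[:16, :16]
    np.testing.assert_allclose(mine, sk[:, :, 0, skimage_angle_idx], atol=1e-12)


def test_glcm_rejects_bad_arguments(random_image):
    with pytest.raises(InvalidArgumentError):
        compute_glcm(random_image, delta=0, theta=0)
    with pytest.raises(InvalidArgumentError):
        compute_glcm(random_image, delta=1, theta=30)
    with pytest.raises(InvalidArgumentError):
        compute_glcm(np.zeros((1, 1), dtype=np.uint8), delta=1, theta=0)


# ---------------------------------------------------------- GLCM features --

def test_glcm_features_constant_image():
    g = compute_glcm(np.full((4, 4), 9, dtype=np.uint8), delta=1, theta=0)
    with pytest.raises(DegenerateInputError):
        glcm_features(g)
    f = glcm_features(g, degenerate_correlation="nan")
    assert f.c == 0.0
    assert f.h == 1.0
    assert f.e == 1.0
    assert f.en == 0.0
    assert np.isnan(f.cr)


def test_glcm_features_checkerboard_closed_form(checkerboard):
    f = glcm_features(compute_glcm(checkerboard, delta=1, theta=0))
    assert f.c == pytest.approx(1.0)
    assert f.h == pytest.approx(0.5)
    assert f.e == pytest.approx(0.5)
    assert f.en == pytest.approx(1.0)  # one bit
    assert f.cr == pytest.approx(-1.0)


def test_glcm_features_match_double_loop_oracle(rng):
    img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
    g = compute_glcm(img, delta=1, theta=45)
    f = glcm_features(g)
    c, h, cr, e, en = glcm_features_oracle(glcm_oracle(img, 1, 45, True))
    assert f.c == pytest.approx(c, abs=1e-10)
    assert f.h == pytest.approx(h, abs=1e-10)
    assert f.cr == pytest.approx(cr, abs=1e-10)
    assert f.e == pytest.approx(e, abs=1e-10)
    assert f.en == pytest.approx(en, abs=1e-10)


# -------------------------------------------------------- angle averaging --

def test_angle_average_constant_image():
    img = np.full((6, 6), 42, dtype=np.uint8)
    f = angle_averaged_features(img, degenerate_correlation="nan")
    assert (f.c, f.h, f.e, f.en) == (0.0, 1.0, 1.0, 0.0)


def test_angle_average_equals_manual_four_run_mean(random_image):
    f = angle_averaged_features(random_image, delta=1)
    per = [glcm_features(compute_glcm(random_image, 1, t)) for t in GLCM_ANGLES]
    for name in ("c", "h", "cr", "e", "en"):
        assert getattr(f, name) == pytest.approx(
            np.mean([getattr(p, name) for p in per]), abs=1e-12
        )


def test_angle_average_invariant_under_90_degree_rotation(random_image):
    """Rotating the image permutes the per-angle GLCMs (0<->90, 45<->135)."""
    rotated = np.rot90(random_image)
    f0 = angle_averaged_features(random_image)
    f1 = angle_averaged_features(rotated)
    for name in ("c", "h", "cr", "e", "en"):
        assert getattr(f0, name) == pytest.approx(getattr(f1, name), abs=1e-10)
    a = glcm_features(compute_glcm(random_image, 1, 0))
    b = glcm_features(compute_glcm(rotated, 1, 90))
    assert a.c == pytest.approx(b.c, abs=1e-12)


def test_intensity_shift_invariance(rng):
    """Adding a constant (no clipping) shifts M, leaves SD and GLCM features."""
    img = rng.integers(0, 100, size=(12, 12)).astype(np.uint8)
    shifted = (img + 100).astype(np.uint8)
    fo0, fo1 = (first_order_features(histogram(i)) for i in (img, shifted))
    assert fo1.sd == pytest.approx(fo0.sd, abs=1e-10)
    assert histogram(shifted).mean_m == pytest.approx(
        histogram(img).mean_m + 100, abs=1e-10
    )
    g0, g1 = (angle_averaged_features(i) for i in (img, shifted))
    for name in ("c", "h", "e", "en"):
        assert getattr(g0, name) == pytest.approx(getattr(g1, name), abs=1e-10)


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_glcm_invariants_on_random_images(seed):
    """Sum-to-one, symmetry and feature ranges hold for arbitrary images."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(6, 6)).astype(np.uint8)
    for theta in GLCM_ANGLES:
        g = compute_glcm(img, delta=1, theta=theta, symmetric=True)
        assert g.matrix.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(g.matrix, g.matrix.T, atol=1e-15)
        f = glcm_features(g, degenerate_correlation="nan")
        assert f.c >= 0
        assert 0 < f.h <= 1
        assert 0 < f.e <= 1
        assert 0 <= f.en <= 2 * np.log2(256)
        if not np.isnan(f.cr):
            assert -1 - 1e-12 <= f.cr <= 1 + 1e-12
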
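"""GLCM features against an exhaustive pair-enumeration oracle."""

import numpy as np
import pytest

from tumortex.glcm import (
    GLCM_FEATURE_NAMES,
    averaged_glcm,
    compute_glcm_features,
    glcm_features_from_matrix,
    quantize,
)

from conftest import make_patch

# the four unit-distance offsets (dr, dc) at 0, 45, 90, 135 degrees
OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]


def brute_force_glcm(q: np.ndarray, levels: int) -> np.ndarray:
    """Enumerate every voxel pair at each offset; average; normalize."""
    mats = []
    nr, nc = q.shape
    for dr, dc in OFFSETS:
        mat = np.zeros((levels, levels))
        for r in range(nr):
            for c in range(nc):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    mat[q[r, c], q[rr, cc]] += 1
                    mat[q[rr, cc], q[r, c]] += 1  # symmetric accumulation
        mats.append(mat)
    avg = np.mean(mats, axis=0)
    return avg / avg.sum()


def brute_force_features(p: np.ndarray) -> dict:
    """Independent loop-based recomputation of the 13 features."""
    g = p.shape[0]
    px = p.sum(axis=1)
    mu = sum(i * px[i] for i in range(g))
    var = sum((i - mu) ** 2 * px[i] for i in range(g))
    feats = dict.fromkeys(GLCM_FEATURE_NAMES, 0.0)
    p_sum = np.zeros(2 * g - 1)
    p_diff = np.zeros(g)
    for i in range(g):
        for j in range(g):
            v = p[i, j]
            feats["energy"] += v * v
            if v > 0:
                feats["entropy"] -= v * np.log(v)
            feats["homogeneity"] += v / (1 + (i - j) ** 2)
            feats["dissimilarity"] += abs(i - j) * v
            feats["contrast"] += (i - j) ** 2 * v
            if var > 0:
                feats["correlation"] += (i - mu) * (j - mu) * v / var
            p_sum[i + j] += v
            p_diff[abs(i - j)] += v
    feats["variance"] = var
    sa = sum(k * p_sum[k] for k in range(len(p_sum)))
    feats["sum_average"] = sa
    feats["sum_variance"] = sum((k - sa) ** 2 * p_sum[k] for k in range(len(p_sum)))
    feats["sum_entropy"] = -sum(v * np.log(v) for v in p_sum if v > 0)
    dm = sum(k * p_diff[k] for k in range(g))
    feats["difference_variance"] = sum((k - dm) ** 2 * p_diff[k] for k in range(g))
    feats["difference_entropy"] = -sum(v * np.log(v) for v in p_diff if v > 0)
    hx = -sum(v * np.log(v) for v in px if v > 0)
    hxy1 = -sum(
        p[i, j] * np.log(px[i] * px[j])
        for i in range(g)
        for j in range(g)
        if p[i, j] > 0
    )
    feats["imc1"] = (feats["entropy"] - hxy1) / hx if hx > 0 else 0.0
    return feats


def test_constant_patch_single_cell_matrix():
    """A constant ROI concentrates all co-occurrence mass in one cell."""
    feats = dict(zip(GLCM_FEATURE_NAMES, compute_glcm_features(make_patch(np.full((8, 8), 5.0)))))
    assert feats["energy"] == 1.0
    assert feats["entropy"] == 0.0
    assert feats["homogeneity"] == 1.0
    assert feats["dissimilarity"] == 0.0
    assert feats["contrast"] == 0.0
    assert feats["correlation"] == 0.0  # zero-variance convention


def test_output_length_is_13(patch_factory):
    assert len(compute_glcm_features(patch_factory(1))) == 13
    assert len(GLCM_FEATURE_NAMES) == 13


@pytest.mark.parametrize("levels", [8, 16, 32])
def test_matrix_matches_exhaustive_pair_count(patch_factory, levels):
    for seed in range(20):
        q = quantize(patch_factory(seed).rescaled, levels)
        np.testing.assert_allclose(
            averaged_glcm(q, levels), brute_force_glcm(np.asarray(q), levels), atol=1e-12
        )


def test_checkerboard_features_match_oracle():
    """Two-level checkerboard inside an 8x8 patch, verified pairwise."""
    patch = np.zeros((8, 8))
    patch[2:6, 2:6] = np.indices((4, 4)).sum(axis=0) % 2 * 255
    p = make_patch(patch)
    q = quantize(p.rescaled, 16)
    expected = brute_force_features(brute_force_glcm(np.asarray(q), 16))
    got = dict(zip(GLCM_FEATURE_NAMES, compute_glcm_features(p, levels=16)))
    for name in GLCM_FEATURE_NAMES:
        assert got[name] == pytest.approx(expected[name], abs=1e-10), name


def test_features_match_oracle_on_random_patches(patch_factory):
    for seed in range(100):
        p = patch_factory(seed)
        q = quantize(p.rescaled, 16)
        expected = brute_force_features(brute_force_glcm(np.asarray(q), 16))
        got = dict(zip(GLCM_FEATURE_NAMES, compute_glcm_features(p)))
        for name in GLCM_FEATURE_NAMES:
            assert got[name] == pytest.approx(expected[name], abs=1e-9), (seed, name)


def test_rotation_and_transpose_invariance(patch_factory):
    """4-angle averaging makes the features exact under quarter turns."""
    for seed in range(10):
        p = patch_factory(seed)
        base = compute_glcm_features(p)
        for transform in (np.rot90, np.transpose):
            t = make_patch(transform(p.raw))
            np.testing.assert_allclose(compute_glcm_features(t), base, atol=1e-10)


def test_matrix_symmetric_and_normalized(patch_factory):
    q = quantize(patch_factory(3).rescaled, 16)
    mat = averaged_glcm(q, 16)
    np.testing.assert_allclose(mat, mat.T, atol=1e-15)
    assert mat.sum() == pytest.approx(1.0)
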
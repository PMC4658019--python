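"""Gray-level co-occurrence matrix (GLCM) texture features.

The co-occurrence matrix counts, for each pair of quantized gray levels,
how often they occur at a given spatial offset.  Distance-1 matrices at
the four in-plane directions (0, 45, 90, 135 degrees) are accumulated
symmetrically and averaged into a single matrix before feature
computation, which makes the 13 features rotation-invariant with respect
to quarter turns.

Thirteen Haralick-style features are computed from the averaged,
normalized matrix: energy (angular second moment), entropy, homogeneity
(inverse difference moment), dissimilarity, correlation, contrast,
variance, sum average, sum variance, sum entropy, difference variance,
difference entropy, and the first information measure of correlation.
Entropies use the natural logarithm with the 0*log(0) = 0 convention.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

from tumortex.imaging import RoiPatch

GLCM_FEATURE_NAMES = (
    "energy",
    "entropy",
    "homogeneity",
    "dissimilarity",
    "correlation",
    "contrast",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
)

_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def quantize(rescaled: np.ndarray, levels: int) -> np.ndarray:
    """Bin integer [0, 255] intensities uniformly into ``levels`` gray levels."""
    if levels not in (8, 16, 32):
        raise ValueError(f"levels must be one of 8, 16, 32; got {levels}")
    return (np.asarray(rescaled, dtype=np.int64) * levels) // 256


def averaged_glcm(quantized: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric distance-1 co-occurrence matrix averaged over 4 angles, sum 1."""
    counts = graycomatrix(
        quantized.astype(np.uint8),
        distances=[1],
        angles=list(_ANGLES),
        levels=levels,
        symmetric=True,
        normed=False,
    )[:, :, 0, :].astype(float)
    avg = counts.mean(axis=2)
    total = avg.sum()
    if total == 0:  # unreachable for patches >= 2x2, kept as a guard
        return avg
    return avg / total


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def glcm_features_from_matrix(p: np.ndarray) -> dict[str, float]:
    """The 13 features of a normalized symmetric co-occurrence matrix."""
    g = p.shape[0]
    i = np.arange(g, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    var_marginal = float(((i - mu) ** 2 * px).sum())

    energy = float((p**2).sum())
    entropy = _entropy(p.ravel())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var_marginal > 0:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / var_marginal)
    else:
        correlation = 0.0  # constant patch: zero-variance convention

    # distributions of i+j and |i-j|
    p_sum = np.zeros(2 * g - 1)
    p_diff = np.zeros(g)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    k_sum = np.arange(2 * g - 1, dtype=float)
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy(p_sum)

    k_diff = np.arange(g, dtype=float)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = _entropy(p_diff)

    hx = _entropy(px)
    with np.errstate(divide="ignore"):
        log_outer = np.log(np.outer(px, px))
    mask = p > 0
    hxy1 = float(-(p[mask] * log_outer[mask]).sum())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0

    return {
        "energy": energy,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "dissimilarity": dissimilarity,
        "correlation": correlation,
        "contrast": contrast,
        "variance": var_marginal,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": float(imc1),
    }


def compute_glcm_features(patch: RoiPatch, levels: int = 16) -> np.ndarray:
    """13 GLCM features of an ROI patch (order in :data:`GLCM_FEATURE_NAMES`).

    64 voxels cannot populate a 256x256 matrix, so the rescaled patch is
    quantized to ``levels`` gray levels (default 16) first.
    """
    q = quantize(patch.rescaled, levels)
    feats = glcm_features_from_matrix(averaged_glcm(q, levels))
    return np.array([feats[name] for name in GLCM_FEATURE_NAMES])
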
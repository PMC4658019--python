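"""Rotation-invariant uniform local binary pattern (LBP) features.

Each evaluable center voxel is compared with the 24 points circularly
surrounding it at radius 3 (bilinear interpolation off the grid); a
neighbor at least as bright as the center contributes a 1-bit.  A
pattern is *uniform* when its circular bit string has at most two 0<->1
transitions; uniform patterns reduce to their set-bit count (0..24,
rotation invariant), all others fall in a single non-uniform bucket.

Inside an 8x8 ROI only the four centers at rows/cols 3..4 admit the
full radius-3 circle, so the descriptor is the normalized histogram of
the four codes.  The 25 uniform codes are folded into 11 near-equal
contiguous count ranges, with the non-uniform bucket as a 12th bin.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import local_binary_pattern

from tumortex.imaging import RoiPatch

LBP_POINTS = 24
LBP_RADIUS = 3
LBP_N_BINS = 12

#: Upper edges (inclusive) of the 11 contiguous set-bit-count ranges:
#: sizes 3,3,3,2,2,2,2,2,2,2,2 partition counts 0..24.
_UNIFORM_BIN_EDGES = np.array([2, 5, 8, 10, 12, 14, 16, 18, 20, 22, 24])

LBP_FEATURE_NAMES = tuple(
    f"bin{i:02d}" for i in range(1, LBP_N_BINS + 1)
)


def lbp_codes(patch: RoiPatch) -> np.ndarray:
    """Uniform LBP codes (0..24 uniform, 25 non-uniform) at the 4 centers."""
    image = np.asarray(patch.rescaled, dtype=np.int64)
    full = local_binary_pattern(image, P=LBP_POINTS, R=LBP_RADIUS, method="uniform")
    return full[3:5, 3:5].astype(int).ravel()


def bin_code(code: int) -> int:
    """Map an LBP code to its 0-based histogram bin."""
    if code > LBP_POINTS:  # non-uniform bucket
        return LBP_N_BINS - 1
    return int(np.searchsorted(_UNIFORM_BIN_EDGES, code))


def compute_lbp_features(patch: RoiPatch) -> np.ndarray:
    """Normalized 12-bin LBP histogram of an ROI patch (sums to 1)."""
    hist = np.zeros(LBP_N_BINS)
    for code in lbp_codes(patch):
        hist[bin_code(code)] += 1.0
    return hist / hist.sum()
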
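"""Discrete orthonormal Stockwell transform (DOST) harmonic features.

The DOST partitions the 2D discrete Fourier plane into non-overlapping
dyadic frequency bands per axis.  For an 8x8 ROI the signed frequencies
-4..3 split into six sections per axis: {0}, {1}, {-1}, {2,3}, {-2,-3}
and the Nyquist frequency {-4}.  Averaging spectral amplitudes within
each 2D section yields a 6x6 "harmonics image"; radial grouping of the
sections by order r = max(|order_x|, |order_y|) (orders 0..3, Nyquist as
order 3) produces rotation-invariant descriptors.

Five features are reported per ROI: the DC-section amplitude, the mean
harmonic amplitude at radial orders 1, 2 and 3, and the normalized
spectral entropy of the four band energies.  The forward DFT is the
unnormalized ``numpy.fft`` transform, for which Parseval's identity
reads sum|F|^2 = 64 * sum|x|^2 on an 8x8 patch.
"""

from __future__ import annotations

import numpy as np

from tumortex.imaging import RoiPatch

DOST_FEATURE_NAMES = ("dc", "band1", "band2", "band3", "spectral_entropy")

#: Signed frequencies (N=8) of each dyadic section, with its axis order.
_SECTIONS: tuple[tuple[tuple[int, ...], int], ...] = (
    ((0,), 0),
    ((1,), 1),
    ((-1,), 1),
    ((2, 3), 2),
    ((-2, -3), 2),
    ((-4,), 3),  # Nyquist
)


def harmonics_image(patch_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean spectral amplitude per 2D dyadic section.

    Returns the 6x6 harmonics image and the matching 6x6 grid of radial
    orders max(|order_x|, |order_y|).
    """
    spectrum = np.abs(np.fft.fft2(np.asarray(patch_values, dtype=float)))
    freqs = np.fft.fftfreq(8, d=1.0 / 8).astype(int)  # signed frequency per index
    n_sec = len(_SECTIONS)
    harmonics = np.zeros((n_sec, n_sec))
    orders = np.zeros((n_sec, n_sec), dtype=int)
    for a, (fa, oa) in enumerate(_SECTIONS):
        rows = np.isin(freqs, fa)
        for b, (fb, ob) in enumerate(_SECTIONS):
            cols = np.isin(freqs, fb)
            harmonics[a, b] = spectrum[np.ix_(rows, cols)].mean()
            orders[a, b] = max(oa, ob)
    return harmonics, orders


def compute_dost_features(patch: RoiPatch) -> np.ndarray:
    """5 DOST features of an ROI patch (order in :data:`DOST_FEATURE_NAMES`).

    Computed on the rescaled patch, like the other texture families.
    The spectral entropy uses squared band amplitudes as energies,
    normalized by log(4) so it lies in [0, 1]; an all-zero spectrum
    (possible only for an all-zero patch) gives entropy 0.
    """
    harmonics, orders = harmonics_image(patch.rescaled)
    bands = np.array([harmonics[orders == r].mean() for r in range(4)])
    energies = bands**2
    total = energies.sum()
    if total > 0:
        probs = energies[energies > 0] / total
        entropy = float(-(probs * np.log(probs)).sum() / np.log(len(bands)))
    else:
        entropy = 0.0
    return np.array([bands[0], bands[1], bands[2], bands[3], entropy])
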
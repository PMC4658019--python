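import numpy as np
import pytest

from tumortex.config import CohortConfig
from tumortex.imaging import RoiPatch, rescale_to_255


def make_patch(raw: np.ndarray, contrast: str = "T2W") -> RoiPatch:
    raw = np.asarray(raw, dtype=float)
    return RoiPatch(contrast_name=contrast, raw=raw, rescaled=rescale_to_255(raw))


@pytest.fixture
def patch_factory():
    """Factory for seeded random 8x8 ROI patches."""

    def factory(seed: int = 0, low: int = 0, high: int = 256) -> RoiPatch:
        rng = np.random.default_rng(seed)
        return make_patch(rng.integers(low, high, (8, 8)).astype(float))

    return factory


@pytest.fixture
def small_config() -> CohortConfig:
    """A small-volume cohort config for fast generator tests."""
    return CohortConfig(
        n_patients=3,
        volume_shape=(2, 64, 64),
        n_biopsies_per_patient=4,
        enh_radius_vox=15.0,
        bat_radius_vox=27.0,
        seed=7,
    )
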
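"""Feature registry and assembly of the 256-feature ROI vector.

Per contrast the pipeline computes 2 raw first-order features (mean, SD
of the unscaled ROI) and 30 texture features (13 GLCM + 12 LBP + 5
DOST) on the 0-255 rescaled ROI.  Over the 8 contrasts that is 16 raw +
240 texture = 256 named features.  Column names follow
``<contrast>__<algorithm>__<feature>`` and their order is fixed by
:data:`FEATURE_NAMES`, so feature tables are byte-stable across runs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tumortex.dost import DOST_FEATURE_NAMES, compute_dost_features
from tumortex.glcm import GLCM_FEATURE_NAMES, compute_glcm_features
from tumortex.imaging import CONTRASTS, BiopsySite, ContrastVolume, RoiPatch, extract_roi, first_order_stats
from tumortex.lbp import LBP_FEATURE_NAMES, compute_lbp_features

ALGORITHMS = ("RAW", "GLCM", "LBP", "DOST")

_PER_ALGORITHM_NAMES: Mapping[str, tuple[str, ...]] = {
    "RAW": ("mean", "sd"),
    "GLCM": GLCM_FEATURE_NAMES,
    "LBP": LBP_FEATURE_NAMES,
    "DOST": DOST_FEATURE_NAMES,
}


def _build_registry() -> tuple[str, ...]:
    names = []
    for contrast in CONTRASTS:
        for algorithm in ALGORITHMS:
            for feat in _PER_ALGORITHM_NAMES[algorithm]:
                names.append(f"{contrast}__{algorithm}__{feat}")
    return tuple(names)


#: The 256 feature names in canonical order.
FEATURE_NAMES: tuple[str, ...] = _build_registry()

N_FEATURES = len(FEATURE_NAMES)


def assemble_feature_vector(
    patches: Mapping[str, RoiPatch], glcm_levels: int = 16
) -> pd.Series:
    """Compute the full 256-feature vector for one ROI.

    Parameters
    ----------
    patches : mapping contrast name -> RoiPatch
        All 8 contrasts must be present.
    glcm_levels : int
        Gray-level count for GLCM quantization.
    """
    missing = [c for c in CONTRASTS if c not in patches]
    if missing:
        raise ValueError(f"missing contrast(s) for feature assembly: {', '.join(missing)}")
    values: list[float] = []
    for contrast in CONTRASTS:
        patch = patches[contrast]
        values.extend(first_order_stats(patch))
        values.extend(compute_glcm_features(patch, levels=glcm_levels))
        values.extend(compute_lbp_features(patch))
        values.extend(compute_dost_features(patch))
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def extract_site_features(
    volumes: Mapping[str, ContrastVolume], site: BiopsySite, glcm_levels: int = 16
) -> pd.Series:
    """Extract ROIs for one site across all contrasts and assemble features."""
    patches = {name: extract_roi(volumes[name], site) for name in CONTRASTS}
    return assemble_feature_vector(patches, glcm_levels=glcm_levels)


def extract_cohort_features(
    patient_volumes: Mapping[str, Mapping[str, ContrastVolume]],
    sites: Sequence[BiopsySite],
    glcm_levels: int = 16,
) -> pd.DataFrame:
    """Feature table with one row per biopsy site.

    Returns a DataFrame with index columns patient_id / zone / label /
    pct_tumor_nuclei followed by the 256 feature columns.
    """
    rows = []
    meta = []
    for site in sites:
        rows.append(extract_site_features(patient_volumes[site.patient_id], site, glcm_levels))
        meta.append(
            {
                "patient_id": site.patient_id,
                "slice": site.slice,
                "row0": site.row0,
                "col0": site.col0,
                "zone": site.zone,
                "pct_tumor_nuclei": site.pct_tumor_nuclei,
                "label": site.label,
            }
        )
    features = pd.DataFrame(rows).reset_index(drop=True)
    table = pd.concat([pd.DataFrame(meta), features], axis=1)
    return table


def write_feature_registry(path: str | Path) -> None:
    """Export the feature-name registry as JSON for interpretability tools."""
    payload = {
        "n_features": N_FEATURES,
        "contrasts": list(CONTRASTS),
        "algorithms": {alg: list(names) for alg, names in _PER_ALGORITHM_NAMES.items()},
        "feature_names": list(FEATURE_NAMES),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """The 256 feature columns of a cohort feature table."""
    return table.loc[:, list(FEATURE_NAMES)]
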
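"""Block-wise principal component reduction of the 256-feature table.

Features are grouped into blocks by (MRI contrast x texture algorithm):
24 texture blocks (8 contrasts x GLCM/LBP/DOST) plus 8 raw blocks.
Each texture block is z-scored with training statistics and reduced by
PCA, retaining the smallest number of components whose cumulative
explained variance reaches 85%.  Raw blocks (per-contrast mean and SD)
are standardized but pass through uncombined so that, e.g., the raw
rCBV mean can be selected — and interpreted — as a feature in its own
right.

Reduced columns are named ``<contrast>__<ALG>__PC<i>`` and
``<contrast>__raw_mean`` / ``<contrast>__raw_sd``.  Validation data is
always transformed with stored training statistics; nothing refits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from tumortex.features import FEATURE_NAMES
from tumortex.imaging import CONTRASTS

TEXTURE_ALGORITHMS = ("GLCM", "LBP", "DOST")
VARIANCE_TARGET = 0.85


@dataclass
class PcModel:
    """Fitted standardization + PCA state for one feature block."""

    block_id: str  # "<contrast>__<ALG>"
    columns: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (n_features, k), orthonormal columns
    eigenvalues: np.ndarray  # retained eigenvalues, descending
    explained: float  # cumulative variance fraction of the retained set
    is_raw: bool = False
    output_columns: list[str] = field(default_factory=list)

    def standardize(self, data: pd.DataFrame) -> np.ndarray:
        x = data.loc[:, self.columns].to_numpy(dtype=float)
        return (x - self.means) / self.scales


def _block_columns() -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    for contrast in CONTRASTS:
        blocks[f"{contrast}__RAW"] = [
            f"{contrast}__RAW__mean",
            f"{contrast}__RAW__sd",
        ]
        for alg in TEXTURE_ALGORITHMS:
            blocks[f"{contrast}__{alg}"] = [
                name for name in FEATURE_NAMES if name.startswith(f"{contrast}__{alg}__")
            ]
    return blocks


def retained_count(eigenvalues: np.ndarray, target: float = VARIANCE_TARGET) -> int:
    """Smallest k with cumulative explained variance >= target (k >= 1)."""
    total = eigenvalues.sum()
    if total <= 0:
        return 1
    cumulative = np.cumsum(eigenvalues) / total
    return int(np.searchsorted(cumulative, target - 1e-12) + 1)


def _fit_block(block_id: str, columns: list[str], data: pd.DataFrame) -> PcModel:
    x = data.loc[:, columns].to_numpy(dtype=float)
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=0)
    zero_var = scales == 0
    scales = np.where(zero_var, 1.0, scales)  # unit scale; column contributes nothing
    z = (x - means) / scales

    contrast = block_id.split("__")[0]
    if block_id.endswith("__RAW"):
        return PcModel(
            block_id=block_id, columns=columns, means=means, scales=scales,
            loadings=np.eye(len(columns)), eigenvalues=np.ones(len(columns)),
            explained=1.0, is_raw=True,
            output_columns=[f"{contrast}__raw_mean", f"{contrast}__raw_sd"],
        )

    cov = np.cov(z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    k = retained_count(eigvals)
    loadings = eigvecs[:, :k]
    # sign convention: largest-magnitude entry of each loading is positive
    for j in range(k):
        idx = np.argmax(np.abs(loadings[:, j]))
        if loadings[idx, j] < 0:
            loadings[:, j] = -loadings[:, j]
    total = eigvals.sum()
    explained = float(eigvals[:k].sum() / total) if total > 0 else 1.0
    alg = block_id.split("__")[1]
    return PcModel(
        block_id=block_id, columns=columns, means=means, scales=scales,
        loadings=loadings, eigenvalues=eigvals[:k], explained=explained,
        output_columns=[f"{contrast}__{alg}__PC{j + 1}" for j in range(k)],
    )


def fit_reduction(training_features: pd.DataFrame) -> list[PcModel]:
    """Fit per-block standardization and PCA on the training feature table.

    Requires at least 3 samples and a complete, finite 256-column table.
    """
    if len(training_features) < 3:
        raise ValueError(f"need >= 3 training samples to fit PCA, got {len(training_features)}")
    missing = [c for c in FEATURE_NAMES if c not in training_features.columns]
    if missing:
        raise ValueError(f"feature table is missing column(s): {missing[:3]}...")
    if not np.all(np.isfinite(training_features.loc[:, list(FEATURE_NAMES)].to_numpy(float))):
        raise ValueError("feature table contains missing or non-finite values")
    models = [_fit_block(bid, cols, training_features) for bid, cols in _block_columns().items()]
    # soft checks, logged not enforced: highly correlated real-world texture
    # blocks usually compress to 1-3 PCs and keep total dimensionality
    # below the sample count; weakly correlated features need not
    wide = [m.block_id for m in models if not m.is_raw and len(m.output_columns) > 3]
    if wide:
        logger.warning("blocks retaining more than 3 PCs: %s", ", ".join(wide))
    total = sum(len(m.output_columns) for m in models)
    if total >= len(training_features):
        logger.warning(
            "reduced dimensionality %d is not below the sample count %d",
            total, len(training_features),
        )
    return models


def transform(models: list[PcModel], features: pd.DataFrame) -> pd.DataFrame:
    """Project a feature table onto the fitted reduced space.

    Uses stored training means/scales/loadings only; validation data is
    never refit.
    """
    pieces = {}
    for model in models:
        missing = [c for c in model.columns if c not in features.columns]
        if missing:
            raise ValueError(f"block {model.block_id} missing column(s): {missing}")
        scores = model.standardize(features) @ model.loadings
        for j, name in enumerate(model.output_columns):
            pieces[name] = scores[:, j]
    return pd.DataFrame(pieces, index=features.index)


def models_to_json(models: list[PcModel], path: str | Path) -> None:
    payload = [
        {
            "block_id": m.block_id,
            "columns": m.columns,
            "means": m.means.tolist(),
            "scales": m.scales.tolist(),
            "loadings": m.loadings.tolist(),
            "eigenvalues": m.eigenvalues.tolist(),
            "explained": m.explained,
            "is_raw": m.is_raw,
            "output_columns": m.output_columns,
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def models_from_json(path: str | Path) -> list[PcModel]:
    payload = json.loads(Path(path).read_text())
    return [
        PcModel(
            block_id=item["block_id"],
            columns=list(item["columns"]),
            means=np.array(item["means"]),
            scales=np.array(item["scales"]),
            loadings=np.array(item["loadings"]),
            eigenvalues=np.array(item["eigenvalues"]),
            explained=float(item["explained"]),
            is_raw=bool(item["is_raw"]),
            output_columns=list(item["output_columns"]),
        )
        for item in payload
    ]
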
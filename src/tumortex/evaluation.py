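"""Confusion-matrix metrics, subgroup exclusion, and probability maps."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tumortex.config import ROI_SIZE
from tumortex.classify import predict
from tumortex.features import FEATURE_NAMES, extract_site_features
from tumortex.imaging import CONTRASTS, BiopsySite, ContrastVolume, site_physical_coords
from tumortex.reduction import PcModel, transform

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts; 'positive' is the high-tumor class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV and NPV of a confusion matrix.

    A ratio with zero denominator is reported as NaN — never silently as
    zero — so undefined cells are visible downstream.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": (cm.tp + cm.tn) / cm.n,
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
    }


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionMatrix(
        tp=int(((y_true == "high") & (y_pred == "high")).sum()),
        fp=int(((y_true == "low") & (y_pred == "high")).sum()),
        tn=int(((y_true == "low") & (y_pred == "low")).sum()),
        fn=int(((y_true == "high") & (y_pred == "low")).sum()),
    )


def reconstruct_confusion(
    n_pos: int, n_neg: int, sensitivity: float, specificity: float
) -> ConfusionMatrix:
    """Integer confusion matrix implied by class counts and printed rates.

    tp is the nearest integer to sensitivity*n_pos (tn analogously); the
    result must reproduce the input rates within half-count rounding,
    otherwise the printed summary is internally inconsistent.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    cm = ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
    if abs(tp - sensitivity * n_pos) > 0.5 + 1e-9 or abs(tn - specificity * n_neg) > 0.5 + 1e-9:
        raise ValueError(
            f"no integer confusion matrix reproduces sens={sensitivity}, "
            f"spec={specificity} on ({n_pos}, {n_neg}) within rounding"
        )
    return cm


def evaluate_on_validation(
    models: list[PcModel],
    selected: Sequence[str],
    classifier_model,
    features: pd.DataFrame,
    labels: np.ndarray,
    zones: np.ndarray,
) -> dict[str, dict[str, float]]:
    """Apply the frozen model chain to a validation cohort, per zone.

    Features are transformed with the training-fitted reduction only;
    nothing is refit.  Returns metrics for 'ENH', 'BAT' and 'Both'
    (zones absent from the cohort are skipped).
    """
    reduced = transform(models, features)
    missing = [c for c in selected if c not in reduced.columns]
    if missing:
        raise ValueError(f"selected feature(s) absent after reduction: {missing}")
    y_pred, _ = predict(classifier_model, reduced.loc[:, list(selected)].to_numpy(float))
    labels = np.asarray(labels)
    zones = np.asarray(zones)
    out: dict[str, dict[str, float]] = {}
    for zone in ("ENH", "BAT"):
        mask = zones == zone
        if mask.any():
            out[zone] = metrics(confusion_from_labels(labels[mask], y_pred[mask]))
    out["Both"] = metrics(confusion_from_labels(labels, y_pred))
    return out


def exclude_close_pairs(
    sites: Sequence[BiopsySite],
    min_mm: float,
    max_mm: float,
    voxel_size_mm: tuple[float, float, float],
) -> list[BiopsySite]:
    """Drop sites so no same-patient pair is separated by [min_mm, max_mm).

    Distances are 3D physical distances between ROI centers.  Removal is
    greedy-minimal: repeatedly drop the site participating in the most
    offending pairs (ties broken by original site order) until none
    remain.
    """
    sites = list(sites)
    coords = site_physical_coords(sites, voxel_size_mm)
    active = list(range(len(sites)))
    while True:
        offending: dict[int, int] = {i: 0 for i in active}
        any_pair = False
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1 :]:
                if sites[i].patient_id != sites[j].patient_id:
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if min_mm <= d < max_mm:
                    offending[i] += 1
                    offending[j] += 1
                    any_pair = True
        if not any_pair:
            return [sites[i] for i in active]
        worst = max(active, key=lambda i: (offending[i], -i))  # ties: earliest site
        active.remove(worst)


@dataclass
class TumorProbabilityMap:
    """Posterior probability of high tumor content on one slice.

    ``grid`` holds the posterior at each evaluable window center and
    NaN elsewhere; ``mask`` marks the evaluable centers.
    """

    patient_id: str
    slice: int
    grid: np.ndarray
    mask: np.ndarray
    stride: int


def render_probability_map(
    volumes: Mapping[str, ContrastVolume],
    models: list[PcModel],
    selected: Sequence[str],
    classifier_model,
    slice_index: int,
    stride: int = 1,
    patient_id: str = "",
    glcm_levels: int = 16,
) -> TumorProbabilityMap:
    """Slide the 8x8 window over a slice and map tumor posteriors.

    Every window runs the identical ROI -> features -> reduction ->
    posterior chain used for biopsy sites; the posterior is assigned at
    the window center (corner + 4 voxels each way).  Stride 1 gives the
    densest map.
    """
    missing = [c for c in CONTRASTS if c not in volumes]
    if missing:
        raise ValueError(f"missing contrast(s) for map rendering: {', '.join(missing)}")
    shape = volumes[CONTRASTS[0]].data.shape
    _, nr, nc = shape
    corners = [
        (r0, c0)
        for r0 in range(0, nr - ROI_SIZE + 1, stride)
        for c0 in range(0, nc - ROI_SIZE + 1, stride)
    ]
    rows = []
    for r0, c0 in corners:
        site = BiopsySite(
            patient_id=patient_id or "map", slice=slice_index, row0=r0, col0=c0,
            zone="ENH", pct_tumor_nuclei=0.0,
        )
        rows.append(extract_site_features(volumes, site, glcm_levels=glcm_levels))
    features = pd.DataFrame(rows, columns=list(FEATURE_NAMES)).reset_index(drop=True)
    reduced = transform(models, features)
    _, p_high = predict(classifier_model, reduced.loc[:, list(selected)].to_numpy(float))

    grid = np.full((nr, nc), np.nan)
    mask = np.zeros((nr, nc), dtype=bool)
    half = ROI_SIZE // 2
    for (r0, c0), p in zip(corners, p_high):
        grid[r0 + half, c0 + half] = p
        mask[r0 + half, c0 + half] = True
    return TumorProbabilityMap(
        patient_id=patient_id, slice=slice_index, grid=grid, mask=mask, stride=stride
    )


def write_probability_map(
    pmap: TumorProbabilityMap,
    voxel_size_mm: tuple[float, float, float],
    nifti_path: str | Path,
    png_path: str | Path | None = None,
    background: np.ndarray | None = None,
) -> None:
    """Write a probability map as float NIfTI and optional PNG overlay.

    The PNG renders posteriors blue (tumor-poor) to red (tumor-rich)
    over the background slice (typically T2W), alpha-blended.
    """
    import nibabel as nib

    dz, dy, dx = voxel_size_mm
    data = np.where(pmap.mask, pmap.grid, np.nan)[None, :, :]
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)).astype(np.float32), affine)
    nib.save(img, str(nifti_path))

    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        if background is not None:
            ax.imshow(background, cmap="gray")
        masked = np.ma.masked_invalid(pmap.grid)
        im = ax.imshow(masked, cmap="coolwarm", vmin=0.0, vmax=1.0, alpha=0.7)
        fig.colorbar(im, ax=ax, label="P(high tumor content)")
        ax.set_title(f"{pmap.patient_id} slice {pmap.slice} (stride {pmap.stride})")
        ax.axis("off")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
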
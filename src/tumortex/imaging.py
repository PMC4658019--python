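"""Volume and biopsy-site I/O, ROI extraction, and first-order statistics.

Coordinate conventions used throughout the package: voxel indices are
0-based, ROI ranges are half-open, and an 8x8 ROI with top-left corner
``(row0, col0)`` spans rows ``[row0, row0+8)`` and columns
``[col0, col0+8)`` within a single slice (texture analysis is strictly
in-plane).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from tumortex.config import ROI_SIZE

#: The eight coregistered MRI contrasts, in canonical order: post-contrast
#: T1, T2-weighted, relative cerebral blood volume, post-contrast T2*
#: echo-planar, isotropic/anisotropic diffusion, mean diffusivity,
#: fractional anisotropy.
CONTRASTS = ("T1+C", "T2W", "rCBV", "EPI+C", "p", "q", "MD", "FA")

#: Percent-tumor-nuclei threshold separating high- from low-tumor samples.
HIGH_TUMOR_THRESHOLD = 80.0

SITE_COLUMNS = ("patient_id", "slice", "row0", "col0", "zone", "pct_tumor_nuclei")


@dataclass
class ContrastVolume:
    """One coregistered 3D intensity map for a named MRI contrast."""

    name: str
    data: np.ndarray  # (slices, rows, cols)
    voxel_size_mm: tuple[float, float, float]  # (dz, dy, dx)

    def __post_init__(self) -> None:
        if self.name not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.name!r}; expected one of {CONTRASTS}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (slices, rows, cols)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"contrast {self.name!r} contains non-finite values")


@dataclass(frozen=True)
class BiopsySite:
    """Location, zone and histologic label of one tissue sample.

    ``label`` is 'high' iff ``pct_tumor_nuclei >= 80`` (tumor-rich per
    genomic-adequacy criteria), else 'low'.
    """

    patient_id: str
    slice: int
    row0: int
    col0: int
    zone: str  # ENH | BAT
    pct_tumor_nuclei: float
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if self.zone not in ("ENH", "BAT"):
            raise ValueError(f"zone must be ENH or BAT, got {self.zone!r}")
        if not 0.0 <= self.pct_tumor_nuclei <= 100.0:
            raise ValueError("pct_tumor_nuclei must lie in [0, 100]")
        object.__setattr__(
            self, "label", "high" if self.pct_tumor_nuclei >= HIGH_TUMOR_THRESHOLD else "low"
        )


@dataclass
class RoiPatch:
    """An 8x8 ROI in raw intensities and rescaled to integer [0, 255]."""

    contrast_name: str
    raw: np.ndarray
    rescaled: np.ndarray


def write_volume(volume: ContrastVolume, path: str | Path) -> None:
    """Write a contrast volume as NIfTI, carrying the voxel size in the affine.

    Axis order on disk is (cols, rows, slices) so that NIfTI's spatial
    axes line up with the conventional (x, y, z) reading.
    """
    dz, dy, dx = volume.voxel_size_mm
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.transpose(volume.data, (2, 1, 0)).astype(np.float32), affine)
    nib.save(img, str(path))


def read_volume(path: str | Path, name: str | None = None) -> ContrastVolume:
    """Read a NIfTI contrast volume written by :func:`write_volume`.

    The contrast name is taken from the filename pattern
    ``<patient>_<contrast>.nii.gz`` unless given explicitly.
    """
    path = Path(path)
    if name is None:
        stem = path.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        if "_" not in stem:
            raise ValueError(f"cannot infer contrast name from filename {path.name!r}")
        name = stem.split("_", 1)[1]
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    voxel = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ContrastVolume(name=name, data=data, voxel_size_mm=voxel)


def write_sites(sites: Iterable[BiopsySite], path: str | Path) -> None:
    """Write the biopsy-site table as CSV (schema in :data:`SITE_COLUMNS`)."""
    rows = [
        {
            "patient_id": s.patient_id,
            "slice": s.slice,
            "row0": s.row0,
            "col0": s.col0,
            "zone": s.zone,
            "pct_tumor_nuclei": s.pct_tumor_nuclei,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=list(SITE_COLUMNS)).to_csv(path, index=False)


def read_sites(path: str | Path) -> list[BiopsySite]:
    """Read a biopsy-site CSV, validating the schema column by column."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} is missing column(s): {', '.join(missing)}")
    sites = []
    for _, row in df.iterrows():
        sites.append(
            BiopsySite(
                patient_id=str(row["patient_id"]),
                slice=int(row["slice"]),
                row0=int(row["row0"]),
                col0=int(row["col0"]),
                zone=str(row["zone"]),
                pct_tumor_nuclei=float(row["pct_tumor_nuclei"]),
            )
        )
    return sites


def rescale_to_255(raw: np.ndarray) -> np.ndarray:
    """Map intensities affinely onto integer [0, 255] (min->0, max->255).

    Values are floored to integers; a constant patch maps to all zeros.
    The mapping is invariant to positive affine transforms of the input,
    which is what makes the downstream texture features comparable
    across ROIs with different absolute intensity windows.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw, dtype=np.int64)
    scaled = np.floor((raw - lo) / (hi - lo) * 255.0).astype(np.int64)
    # the maximum hits 255 exactly; floor can only undershoot by rounding noise
    return np.clip(scaled, 0, 255)


def extract_roi(volume: ContrastVolume, site: BiopsySite) -> RoiPatch:
    """Extract the site's 8x8 in-plane ROI from one contrast volume."""
    ns, nr, nc = volume.data.shape
    if not (0 <= site.slice < ns):
        raise IndexError(f"slice {site.slice} outside volume with {ns} slices")
    if site.row0 < 0 or site.col0 < 0 or site.row0 + ROI_SIZE > nr or site.col0 + ROI_SIZE > nc:
        raise IndexError(
            f"ROI corner ({site.row0}, {site.col0}) puts the {ROI_SIZE}x{ROI_SIZE} "
            f"footprint outside the {nr}x{nc} slice"
        )
    raw = volume.data[site.slice, site.row0 : site.row0 + ROI_SIZE, site.col0 : site.col0 + ROI_SIZE]
    raw = np.array(raw, dtype=float)
    return RoiPatch(contrast_name=volume.name, raw=raw, rescaled=rescale_to_255(raw))


def first_order_stats(patch: RoiPatch) -> tuple[float, float]:
    """Mean and SD of the raw (pre-rescaling) ROI intensities.

    SD uses the population denominator n=64: the ROI is a fixed window,
    not a sample from a larger population of voxels.
    """
    raw = patch.raw
    return float(raw.mean()), float(raw.std(ddof=0))


def site_physical_coords(
    sites: Sequence[BiopsySite], voxel_size_mm: tuple[float, float, float]
) -> np.ndarray:
    """Physical (z, y, x) mm coordinates of each site's ROI center."""
    dz, dy, dx = voxel_size_mm
    half = (ROI_SIZE - 1) / 2.0
    return np.array(
        [[s.slice * dz, (s.row0 + half) * dy, (s.col0 + half) * dx] for s in sites], dtype=float
    )
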
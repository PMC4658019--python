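"""Configuration objects for the synthetic cohort and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

#: ROI edge length in voxels; every texture extractor assumes this window.
ROI_SIZE = 8


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for the synthetic multi-contrast cohort.

    Defaults emulate the biopsy-study design the pipeline targets: 18
    glioblastoma patients contributing about five stereotactic biopsies
    each, drawn from both the enhancing core (ENH) and the non-enhancing
    brain-around-tumor (BAT) zone, with targets separated by at least
    1 cm, on coregistered maps with ~1.2 mm in-plane resolution and 3 mm
    slices.

    Parameters
    ----------
    n_patients : int
        Number of patients in the cohort.
    volume_shape : tuple of int
        Volume grid as (slices, rows, cols).
    n_biopsies_per_patient : int
        Biopsy sites sampled per patient.
    enh_fraction : float
        Fraction of biopsies placed in the ENH zone (the remainder in BAT).
    effect_rcbv : float
        Standardized mean shift (in units of ``noise_sd``) of rCBV in
        high-tumor voxels.  Microvessel volume rises with tumor content,
        so high-tumor tissue carries elevated rCBV.
    texture_scale_low, texture_scale_high : float
        Gaussian correlation length (voxels) of the EPI+C field in low-
        vs high-tumor tissue.  Densely cellular tumor alters the local
        co-occurrence structure of the post-contrast T2* signal; the
        generator encodes that as a class-dependent smoothness.
    t1c_pattern_amplitude : float
        Amplitude (in units of ``noise_sd``) of the unit-variance
        sinusoidal-lattice pattern carried by T1+C inside high-tumor
        voxels, the structured local binary signature of enhancing
        tumor.  The pattern displaces an equal share of noise variance,
        so it shifts local binary structure rather than first-order ROI
        statistics; amplitudes above ``noise_sd`` leave no noise budget
        and saturate.
    noise_sd : float
        Intensity noise scale shared by all contrasts.
    min_spacing_mm : float
        Minimum physical separation between same-patient biopsy sites.
    voxel_size_mm : tuple of float
        Voxel size as (dz, dy, dx) in millimetres.
    enh_radius_vox, bat_radius_vox : float
        In-plane radii (voxels) of the enhancing core disk and of the
        outer edge of the BAT shell.  The spatial extent of BAT is not a
        measured quantity, so it is exposed here rather than fixed.
    tumor_mean_enh, tumor_mean_bat, tumor_sd : float
        Mean percent tumor nuclei in each zone and the spatial standard
        deviation of the smoothed tumor-fraction field.  The defaults
        put roughly 59% of ENH regions and 21% of BAT regions above the
        80%-nuclei threshold.
    coupling_sd, channel_coupling_sd : float
        SDs (percentage points) of the smooth perturbations between the
        tumor-nuclei fraction and the latent tissue fields the MRI
        signals respond to: one component shared across contrasts
        (histology-imaging mismatch and misregistration — caps the
        accuracy any feature combination can reach) and one specific to
        each signal-bearing contrast (vascularity, cellularity and BBB
        disruption each track tumor content differently — leaves
        genuine incremental value in combining contrasts).
    anatomy_amplitude, anatomy_scale : float
        Amplitude (units of ``noise_sd``) and correlation length
        (voxels) of an optional smooth class-independent background
        added to every contrast (parenchymal structure).  Off by
        default: it adds between-ROI intensity variation that masks the
        raw-mean channels without improving the texture realism the
        classifier exploits.
    seed : int
        Root random seed; the whole cohort is reproducible from it.
    """

    n_patients: int = 18
    volume_shape: tuple[int, int, int] = (4, 96, 96)
    n_biopsies_per_patient: int = 5
    enh_fraction: float = 0.6
    effect_rcbv: float = 0.55
    texture_scale_low: float = 0.7
    texture_scale_high: float = 1.8
    t1c_pattern_amplitude: float = 0.6
    noise_sd: float = 1.0
    min_spacing_mm: float = 10.0
    voxel_size_mm: tuple[float, float, float] = (3.0, 1.2, 1.2)
    enh_radius_vox: float = 22.0
    bat_radius_vox: float = 40.0
    tumor_mean_enh: float = 84.0
    tumor_mean_bat: float = 64.0
    tumor_sd: float = 20.0
    coupling_sd: float = 2.0
    channel_coupling_sd: float = 9.0
    anatomy_amplitude: float = 0.0
    anatomy_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_biopsies_per_patient < 1:
            raise ValueError("patient and biopsy counts must be >= 1")
        if not 0.0 <= self.enh_fraction <= 1.0:
            raise ValueError("enh_fraction must lie in [0, 1]")
        if self.min_spacing_mm < 0:
            raise ValueError("min_spacing_mm must be >= 0")
        ns, nr, nc = self.volume_shape
        # an 8x8 ROI with the radius-3 LBP circle must fit in-plane
        if nr < ROI_SIZE + 6 or nc < ROI_SIZE + 6 or ns < 1:
            raise ValueError(
                f"volume_shape {self.volume_shape} too small for an "
                f"{ROI_SIZE}x{ROI_SIZE} ROI at radius-3 margin"
            )


@dataclass
class RunConfig:
    """File-level configuration for the command-line pipeline."""

    output_dir: Path = Path("tumortex_run")
    volumes_dir: Optional[Path] = None
    sites_csv: Optional[Path] = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    glcm_levels: int = 16
    classifier: str = "dlda"
    gain_threshold: float = 0.01
    map_stride: int = 4
    seed: int = 0
    pca_in_folds: bool = False
    n_train_patients: int = 11
    n_train_biopsies: int = 60
    n_val_biopsies: int = 22

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.volumes_dir is None:
            self.volumes_dir = self.output_dir / "volumes"
        if self.sites_csv is None:
            self.sites_csv = self.output_dir / "sites.csv"
        self.volumes_dir = Path(self.volumes_dir)
        self.sites_csv = Path(self.sites_csv)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        for key in ("volume_shape", "voxel_size_mm"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        return cls(cohort=CohortConfig(**cohort_raw), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["volumes_dir"] = str(self.volumes_dir)
        d["sites_csv"] = str(self.sites_csv)
        return d
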
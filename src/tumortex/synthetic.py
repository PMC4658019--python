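"""Synthetic multi-contrast cohort generator with ground-truth tumor fraction.

The generator builds, per patient, a two-zone phantom — an enhancing
core (ENH) disk surrounded by a brain-around-tumor (BAT) shell — over
which a smoothed random field of percent tumor nuclei is laid: high
mean fraction in ENH, lower in BAT, so that (as in surgical cohorts)
tumor-rich regions are common in the core and sparse in the
infiltrative margin.  Voxels at or above 80% tumor nuclei drive three
class-conditional imaging signals:

* rCBV intensities shift upward by ``effect_rcbv`` noise SDs
  (microvessel volume tracks tumor content);
* the EPI+C field swaps its spatial correlation length
  (``texture_scale_low`` vs ``texture_scale_high``), altering
  co-occurrence texture;
* T1+C gains an oriented sinusoidal pattern of amplitude
  ``t1c_pattern_amplitude``, altering local binary structure.

The remaining five contrasts (T2W, p, q, MD, FA) are class-independent
noise.  Biopsy sites are placed pseudorandomly by rejection sampling
under a minimum physical spacing, mirroring how stereotactic targets
are selected at least 1 cm apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from tumortex.config import ROI_SIZE, CohortConfig
from tumortex.imaging import (
    CONTRASTS,
    HIGH_TUMOR_THRESHOLD,
    BiopsySite,
    ContrastVolume,
    site_physical_coords,
    write_sites,
    write_volume,
)

#: Tumor fraction assigned outside both zones (normal-appearing tissue).
_BACKGROUND_FRACTION = 20.0
#: Baseline intensity for every synthetic contrast (arbitrary units).
_BASELINE = 100.0
#: Wavelength (voxels) of the structured T1+C lattice pattern.
_T1C_WAVELENGTH = 4.0
#: Through-plane smoothing (slices) of the tumor-fraction field.
_FIELD_SIGMA = (1.0, 6.0, 6.0)

_MAX_RETRIES = 10_000


class SamplingError(RuntimeError):
    """Raised when biopsy-site placement cannot satisfy its constraints."""


@dataclass
class GroundTruthField:
    """Voxelwise percent tumor nuclei with the two-zone segmentation.

    ``imaging_fraction`` maps each signal-bearing contrast to the latent
    tissue field it responds to: the tumor-nuclei fraction plus a smooth
    coupling perturbation with a component shared across contrasts and a
    contrast-specific component.  This models that vascularity (rCBV),
    cellular density (EPI+C) and blood-brain-barrier disruption (T1+C)
    each track histologic tumor content imperfectly and imperfectly
    alike: the shared component caps the accuracy any feature
    combination can reach, while the contrast-specific components leave
    genuine incremental value in combining contrasts.
    """

    tumor_fraction: np.ndarray  # [0, 100]
    enh_mask: np.ndarray  # bool
    bat_mask: np.ndarray  # bool
    imaging_fraction: dict  # contrast name -> latent field in [0, 100]

    @property
    def high_mask(self) -> np.ndarray:
        """Voxels at or above the 80%-tumor-nuclei threshold."""
        return self.tumor_fraction >= HIGH_TUMOR_THRESHOLD

    def imaging_high_mask(self, contrast: str) -> np.ndarray:
        """Voxels whose latent field for ``contrast`` crosses the threshold."""
        return self.imaging_fraction[contrast] >= HIGH_TUMOR_THRESHOLD


def _patient_rng(config: CohortConfig, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, patient_index, stream]))


def _zone_masks(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    ns, nr, nc = config.volume_shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    radius = np.hypot(rows - (nr - 1) / 2.0, cols - (nc - 1) / 2.0)
    enh_plane = radius <= config.enh_radius_vox
    bat_plane = (radius > config.enh_radius_vox) & (radius <= config.bat_radius_vox)
    enh = np.broadcast_to(enh_plane, (ns, nr, nc)).copy()
    bat = np.broadcast_to(bat_plane, (ns, nr, nc)).copy()
    return enh, bat


def _smooth_unit_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Gaussian-smoothed white noise renormalized to zero mean, unit SD."""
    field = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = field.std()
    if sd == 0:  # sigma so large the field collapsed; keep zeros
        return field
    return (field - field.mean()) / sd


def _smooth_local_unit_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Smoothed noise renormalized to unit *within-ROI-window* SD.

    Dividing by the mean SD over non-overlapping 8x8 in-plane blocks
    (rather than the global SD) equalizes first-order ROI statistics
    across correlation lengths, so fields that differ only in smoothness
    differ in texture, not in ROI mean/SD.
    """
    field = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    ns, nr, nc = field.shape
    br, bc = nr // ROI_SIZE, nc // ROI_SIZE
    blocks = field[:, : br * ROI_SIZE, : bc * ROI_SIZE].reshape(ns, br, ROI_SIZE, bc, ROI_SIZE)
    local_sd = blocks.std(axis=(2, 4)).mean()
    if local_sd == 0:
        return field - field.mean()
    return (field - field.mean()) / local_sd


def make_ground_truth(config: CohortConfig, rng: np.random.Generator) -> GroundTruthField:
    """Two-zone tumor-fraction field: smoothed noise around zone means."""
    enh, bat = _zone_masks(config)
    if not enh.any() or not bat.any():
        raise ValueError(
            f"volume_shape {config.volume_shape} with radii "
            f"({config.enh_radius_vox}, {config.bat_radius_vox}) yields an empty zone"
        )
    base = np.full(config.volume_shape, _BACKGROUND_FRACTION)
    base[enh] = config.tumor_mean_enh
    base[bat] = config.tumor_mean_bat
    fluct = _smooth_unit_field(rng, config.volume_shape, _FIELD_SIGMA)
    fraction = np.clip(base + config.tumor_sd * fluct, 0.0, 100.0)
    shared = _smooth_unit_field(rng, config.volume_shape, _FIELD_SIGMA)
    imaging = {}
    for contrast in ("rCBV", "EPI+C", "T1+C"):
        own = _smooth_unit_field(rng, config.volume_shape, _FIELD_SIGMA)
        imaging[contrast] = np.clip(
            fraction + config.coupling_sd * shared + config.channel_coupling_sd * own,
            0.0,
            100.0,
        )
    return GroundTruthField(
        tumor_fraction=fraction, enh_mask=enh, bat_mask=bat, imaging_fraction=imaging
    )


def _generate_contrasts(
    config: CohortConfig, field: GroundTruthField, rng: np.random.Generator
) -> dict[str, ContrastVolume]:
    shape = config.volume_shape
    sd = config.noise_sd
    data: dict[str, np.ndarray] = {}

    high_rcbv = field.imaging_high_mask("rCBV")
    data["rCBV"] = _BASELINE + sd * rng.standard_normal(shape) + config.effect_rcbv * sd * high_rcbv

    # Class-dependent correlation length, but matched within-window SD so
    # the signal lives in co-occurrence structure, not first-order stats.
    low_field = _smooth_local_unit_field(
        rng, shape, (0.0, config.texture_scale_low, config.texture_scale_low)
    )
    high_field = _smooth_local_unit_field(
        rng, shape, (0.0, config.texture_scale_high, config.texture_scale_high)
    )
    high_epic = field.imaging_high_mask("EPI+C")
    data["EPI+C"] = _BASELINE + sd * np.where(high_epic, high_field, low_field)

    # A product-of-sinusoids lattice replaces (rather than adds to) noise
    # variance in high-tumor voxels.  The product form has zero
    # correlation at every distance-1 co-occurrence offset and leaves
    # total intensity variance class-independent, so the T1+C signal
    # lives specifically in local binary structure.
    _, nr, nc = shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    pattern = (
        2.0
        * np.sin(2 * np.pi * rows / _T1C_WAVELENGTH)
        * np.sin(2 * np.pi * cols / _T1C_WAVELENGTH)
    )[None, :, :]  # unit variance over the grid
    amp = config.t1c_pattern_amplitude
    residual_sd = np.sqrt(max(sd**2 - amp**2, 0.0))
    noise = rng.standard_normal(shape)
    high_t1c = field.imaging_high_mask("T1+C")
    data["T1+C"] = _BASELINE + np.where(high_t1c, residual_sd * noise + amp * pattern, sd * noise)

    for name in ("T2W", "p", "q", "MD", "FA"):
        data[name] = _BASELINE + sd * rng.standard_normal(shape)

    if config.anatomy_amplitude > 0:
        # optional smooth class-independent parenchymal background
        for name in CONTRASTS:
            anatomy = _smooth_unit_field(
                rng, shape, (1.0, config.anatomy_scale, config.anatomy_scale)
            )
            data[name] = data[name] + config.anatomy_amplitude * sd * anatomy

    return {
        name: ContrastVolume(name=name, data=data[name], voxel_size_mm=config.voxel_size_mm)
        for name in CONTRASTS
    }


def generate_patient(
    config: CohortConfig, patient_index: int
) -> tuple[dict[str, ContrastVolume], GroundTruthField]:
    """Generate one patient's 8 contrast volumes and ground-truth field.

    Deterministic given ``(config.seed, patient_index)``.
    """
    if patient_index >= config.n_patients:
        raise ValueError(f"patient_index {patient_index} >= n_patients {config.n_patients}")
    field = make_ground_truth(config, _patient_rng(config, patient_index, 0))
    volumes = _generate_contrasts(config, field, _patient_rng(config, patient_index, 1))
    return volumes, field


def _footprint_candidates(mask: np.ndarray) -> np.ndarray:
    """Corners (slice, row0, col0) whose full ROI footprint lies in ``mask``."""
    ns, nr, nc = mask.shape
    candidates = []
    for s in range(ns):
        # a corner is valid when the 8x8 window contains only mask voxels
        window_ok = np.ones((nr - ROI_SIZE + 1, nc - ROI_SIZE + 1), dtype=bool)
        plane = mask[s]
        for dr in range(ROI_SIZE):
            for dc in range(ROI_SIZE):
                window_ok &= plane[dr : dr + nr - ROI_SIZE + 1, dc : dc + nc - ROI_SIZE + 1]
        rows, cols = np.nonzero(window_ok)
        candidates.extend((s, r, c) for r, c in zip(rows, cols))
    return np.array(candidates, dtype=int).reshape(-1, 3)


def sample_biopsy_sites(
    field: GroundTruthField,
    config: CohortConfig,
    patient_id: str = "P00",
    n_sites: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[BiopsySite]:
    """Pseudorandomly place biopsy sites under the minimum-spacing rule.

    Sites are split between ENH and BAT per ``config.enh_fraction``;
    every ROI footprint lies fully inside its zone, all same-patient
    pairwise physical distances are >= ``config.min_spacing_mm``, and
    each site records the footprint-mean tumor fraction as its
    histologic percent tumor nuclei.  Rejection sampling is bounded at
    10,000 retries.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_biopsies_per_patient if n_sites is None else n_sites
    n_enh = int(round(config.enh_fraction * n))
    zone_plan = ["ENH"] * n_enh + ["BAT"] * (n - n_enh)
    rng.shuffle(zone_plan)

    candidates = {
        "ENH": _footprint_candidates(field.enh_mask),
        "BAT": _footprint_candidates(field.bat_mask),
    }
    for zone, cand in candidates.items():
        if len(cand) == 0 and zone in zone_plan:
            raise ValueError(f"no valid ROI footprint fits inside the {zone} zone; enlarge the volume")

    accepted: list[BiopsySite] = []
    retries = 0
    for zone in zone_plan:
        while True:
            if retries >= _MAX_RETRIES:
                raise SamplingError(
                    f"could not place {n} sites with min_spacing_mm="
                    f"{config.min_spacing_mm} after {_MAX_RETRIES} retries"
                )
            retries += 1
            s, r0, c0 = candidates[zone][rng.integers(len(candidates[zone]))]
            pct = float(
                field.tumor_fraction[s, r0 : r0 + ROI_SIZE, c0 : c0 + ROI_SIZE].mean()
            )
            site = BiopsySite(
                patient_id=patient_id, slice=int(s), row0=int(r0), col0=int(c0),
                zone=zone, pct_tumor_nuclei=pct,
            )
            if accepted and config.min_spacing_mm > 0:
                coords = site_physical_coords(accepted + [site], config.voxel_size_mm)
                dists = np.linalg.norm(coords[:-1] - coords[-1], axis=1)
                if dists.min() < config.min_spacing_mm:
                    continue
            accepted.append(site)
            break
    return accepted


def generate_cohort(
    config: CohortConfig,
    patient_indices: Sequence[int] | None = None,
    biopsy_counts: Sequence[int] | None = None,
) -> tuple[dict[str, dict[str, ContrastVolume]], list[BiopsySite]]:
    """Generate volumes and biopsy sites for a set of patients.

    ``biopsy_counts`` optionally overrides the per-patient site count
    (cohorts average 5-6 specimens per tumor rather than a constant).
    """
    if patient_indices is None:
        patient_indices = range(config.n_patients)
    patient_indices = list(patient_indices)
    if biopsy_counts is None:
        biopsy_counts = [config.n_biopsies_per_patient] * len(patient_indices)
    if len(biopsy_counts) != len(patient_indices):
        raise ValueError("biopsy_counts must match patient_indices in length")

    volumes: dict[str, dict[str, ContrastVolume]] = {}
    sites: list[BiopsySite] = []
    for idx, count in zip(patient_indices, biopsy_counts):
        pid = f"P{idx:02d}"
        vols, field = generate_patient(config, idx)
        volumes[pid] = vols
        sites.extend(
            sample_biopsy_sites(
                field, config, patient_id=pid, n_sites=count,
                rng=_patient_rng(config, idx, 2),
            )
        )
    return volumes, sites


def _spread_counts(total: int, n_patients: int) -> list[int]:
    base, rem = divmod(total, n_patients)
    return [base + 1 if i < rem else base for i in range(n_patients)]


def simulate_study(
    config: CohortConfig,
    n_train_patients: int = 11,
    n_train_biopsies: int = 60,
    n_val_biopsies: int = 22,
) -> tuple[
    dict[str, dict[str, ContrastVolume]], list[BiopsySite],
    dict[str, dict[str, ContrastVolume]], list[BiopsySite],
]:
    """Generate the training / validation cohort split of the study design.

    Defaults mirror the target design: 60 training biopsies over 11
    patients and 22 validation biopsies over the remaining patients.
    Returns (train_volumes, train_sites, val_volumes, val_sites).
    """
    n_val_patients = config.n_patients - n_train_patients
    if n_val_patients < 1:
        raise ValueError("n_train_patients must leave at least one validation patient")
    train_idx = list(range(n_train_patients))
    val_idx = list(range(n_train_patients, config.n_patients))
    train_volumes, train_sites = generate_cohort(
        config, train_idx, _spread_counts(n_train_biopsies, n_train_patients)
    )
    val_volumes, val_sites = generate_cohort(
        config, val_idx, _spread_counts(n_val_biopsies, n_val_patients)
    )
    return train_volumes, train_sites, val_volumes, val_sites


def write_cohort(
    volumes: Mapping[str, Mapping[str, ContrastVolume]],
    sites: Sequence[BiopsySite],
    volumes_dir: str | Path,
    sites_csv: str | Path,
) -> None:
    """Write contrast volumes (`<patient>_<contrast>.nii.gz`) and the site CSV."""
    volumes_dir = Path(volumes_dir)
    volumes_dir.mkdir(parents=True, exist_ok=True)
    for pid, contrasts in volumes.items():
        for name, volume in contrasts.items():
            write_volume(volume, volumes_dir / f"{pid}_{name}.nii.gz")
    write_sites(sites, sites_csv)
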
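"""Synthetic cohort generator: determinism, effect recovery, site placement."""

from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest

from tumortex.config import CohortConfig
from tumortex.imaging import CONTRASTS, site_physical_coords
from tumortex.synthetic import (
    SamplingError,
    _patient_rng,
    generate_cohort,
    generate_patient,
    sample_biopsy_sites,
    simulate_study,
)


def test_patient_deterministic(small_config):
    vols_a, field_a = generate_patient(small_config, 1)
    vols_b, field_b = generate_patient(small_config, 1)
    np.testing.assert_array_equal(field_a.tumor_fraction, field_b.tumor_fraction)
    for name in CONTRASTS:
        np.testing.assert_array_equal(vols_a[name].data, vols_b[name].data)


def test_patient_returns_all_contrasts_on_common_grid(small_config):
    vols, field = generate_patient(small_config, 0)
    assert set(vols) == set(CONTRASTS)
    shapes = {v.data.shape for v in vols.values()}
    assert shapes == {small_config.volume_shape}
    assert not np.any(field.enh_mask & field.bat_mask)
    assert field.tumor_fraction.min() >= 0 and field.tumor_fraction.max() <= 100


def test_rcbv_effect_recovery(small_config):
    """Voxelwise high/low mean difference recovers effect_rcbv * noise_sd.

    Verified against an oracle that re-draws the same generative
    pathway: baseline + noise with the shift added on the latent mask.
    """
    cfg = replace(small_config, effect_rcbv=1.0, volume_shape=(4, 64, 64))
    vols, field = generate_patient(cfg, 0)
    mask = field.imaging_high_mask("rCBV")
    diff = vols["rCBV"].data[mask].mean() - vols["rCBV"].data[~mask].mean()
    assert diff == pytest.approx(cfg.effect_rcbv * cfg.noise_sd, abs=0.05)

    rng = _patient_rng(cfg, 0, 1)  # same stream the generator uses
    oracle = 100.0 + cfg.noise_sd * rng.standard_normal(cfg.volume_shape)
    oracle = oracle + cfg.effect_rcbv * cfg.noise_sd * mask
    np.testing.assert_array_equal(vols["rCBV"].data, oracle)


def test_no_signal_config_class_distributions_identical(small_config):
    """With all effects zeroed no contrast depends on the class masks."""
    null = replace(
        small_config,
        effect_rcbv=0.0,
        t1c_pattern_amplitude=0.0,
        texture_scale_low=1.0,
        texture_scale_high=1.0,
        coupling_sd=0.0,
        channel_coupling_sd=0.0,
    )
    vols, field = generate_patient(null, 0)
    rcbv = vols["rCBV"].data
    high = field.high_mask
    # identical generative law: two-sample means agree within MC error
    assert abs(rcbv[high].mean() - rcbv[~high].mean()) < 0.1
    # EPI+C fields for both classes share smoothing scale and unit law
    epic = vols["EPI+C"].data
    assert abs(epic[high].std() - epic[~high].std()) < 0.1


def test_sites_respect_spacing_brute_force(small_config):
    """All same-patient pairwise distances >= 10 mm, checked exhaustively."""
    cfg = replace(small_config, volume_shape=(4, 96, 96), enh_radius_vox=22.0,
                  bat_radius_vox=40.0, min_spacing_mm=10.0)
    _, sites = generate_cohort(cfg, range(3), [5, 5, 5])
    by_patient = {}
    for s in sites:
        by_patient.setdefault(s.patient_id, []).append(s)
    for group in by_patient.values():
        coords = site_physical_coords(group, cfg.voxel_size_mm)
        for i, j in combinations(range(len(group)), 2):
            assert np.linalg.norm(coords[i] - coords[j]) >= cfg.min_spacing_mm


def test_zero_spacing_always_places(small_config):
    cfg = replace(small_config, min_spacing_mm=0.0)
    _, field = generate_patient(cfg, 0)
    sites = sample_biopsy_sites(field, cfg, n_sites=9)
    assert len(sites) == 9


def test_enh_fraction_one_footprints_inside_enh(small_config):
    cfg = replace(small_config, enh_fraction=1.0, min_spacing_mm=0.0)
    _, field = generate_patient(cfg, 0)
    for s in sample_biopsy_sites(field, cfg, n_sites=6):
        footprint = field.enh_mask[s.slice, s.row0 : s.row0 + 8, s.col0 : s.col0 + 8]
        assert footprint.all()
        assert not field.bat_mask[s.slice, s.row0 : s.row0 + 8, s.col0 : s.col0 + 8].any()


def test_site_pct_is_footprint_mean(small_config):
    _, field = generate_patient(small_config, 0)
    for s in sample_biopsy_sites(field, small_config, n_sites=4):
        expected = field.tumor_fraction[s.slice, s.row0 : s.row0 + 8, s.col0 : s.col0 + 8].mean()
        assert s.pct_tumor_nuclei == pytest.approx(expected)


def test_unsatisfiable_spacing_raises(small_config):
    cfg = replace(small_config, min_spacing_mm=1000.0)
    _, field = generate_patient(cfg, 0)
    with pytest.raises(SamplingError, match="min_spacing_mm"):
        sample_biopsy_sites(field, cfg, n_sites=4)


def test_volume_too_small_rejected():
    with pytest.raises(ValueError, match="too small"):
        CohortConfig(volume_shape=(1, 10, 10))


def test_prevalence_ordering_enh_above_bat():
    """High-tumor site prevalence is higher in ENH than BAT by design."""
    cfg = CohortConfig(seed=123)
    _, train_sites, _, val_sites = simulate_study(cfg)
    sites = train_sites + val_sites
    prev = {
        zone: np.mean([s.label == "high" for s in sites if s.zone == zone])
        for zone in ("ENH", "BAT")
    }
    assert prev["ENH"] > prev["BAT"]


def test_study_split_sizes():
    cfg = CohortConfig(seed=5)
    train_vols, train_sites, val_vols, val_sites = simulate_study(cfg)
    assert len(train_sites) == 60 and len(val_sites) == 22
    assert len(train_vols) == 11 and len(val_vols) == 7
    assert set(v.patient_id for v in train_sites).isdisjoint(
        v.patient_id for v in val_sites
    )
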
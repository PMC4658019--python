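"""Metric identities, subgroup exclusion, validation contract, maps."""

import math
from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest

from tumortex.classify import fit_classifier
from tumortex.config import CohortConfig
from tumortex.evaluation import (
    ConfusionMatrix,
    confusion_from_labels,
    evaluate_on_validation,
    exclude_close_pairs,
    metrics,
    reconstruct_confusion,
    render_probability_map,
)
from tumortex.features import extract_cohort_features, feature_matrix, extract_site_features
from tumortex.imaging import BiopsySite, site_physical_coords
from tumortex.reduction import fit_reduction, transform
from tumortex.reference_cohort import (
    REFERENCE_SUMMARY,
    check_reference_summary,
    pooled_summary,
    reconstructed_confusions,
)
from tumortex.classify import predict
from tumortex.synthetic import generate_cohort, generate_patient

VOXEL = (3.0, 1.2, 1.2)


def test_metrics_training_both_column():
    """tp=23 fn=4 tn=28 fp=5 reproduces the training overall column."""
    m = metrics(ConfusionMatrix(tp=23, fn=4, tn=28, fp=5))
    assert m["accuracy"] == pytest.approx(0.850, abs=5e-4)
    assert m["ppv"] == pytest.approx(0.8214, abs=5e-4)
    assert m["npv"] == pytest.approx(0.875, abs=5e-4)


def test_metrics_validation_both_column():
    m = metrics(ConfusionMatrix(tp=9, fn=0, tn=9, fp=4))
    assert m["accuracy"] == pytest.approx(0.8182, abs=5e-4)
    assert m["sensitivity"] == 1.0
    assert m["npv"] == 1.0


def test_metrics_undefined_ratios_are_nan_not_zero():
    m = metrics(ConfusionMatrix(tp=7, fn=0, tn=0, fp=0))
    assert m["accuracy"] == 1.0 and m["sensitivity"] == 1.0 and m["ppv"] == 1.0
    assert math.isnan(m["specificity"]) and math.isnan(m["npv"])
    with pytest.raises(ValueError):
        metrics(ConfusionMatrix(0, 0, 0, 0))


def test_reconstruct_confusion_reference_columns():
    cm = reconstruct_confusion(22, 13, 0.864, 0.769)
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (19, 3, 10, 3)
    cm = reconstruct_confusion(5, 20, 0.80, 0.90)
    assert (cm.tp, cm.tn) == (4, 18)
    perfect = reconstruct_confusion(9, 4, 1.0, 1.0)
    assert perfect.fn == 0 and perfect.fp == 0


def test_reconstruct_confusion_invalid_rates_rejected():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        reconstruct_confusion(10, 10, 1.2, 0.9)
    # nearest-integer reconstruction reproduces the rate within half a count
    cm = reconstruct_confusion(10, 10, 0.45, 0.9)
    assert abs(cm.tp / 10 - 0.45) <= 0.05


def test_reference_summary_all_cells_reproduced():
    """metrics o reconstruct matches every printed cell at its rounding."""
    frame = check_reference_summary()
    assert len(frame) == 30
    assert frame["match"].all()
    assert frame.attrs["training_additive"] and frame.attrs["validation_additive"]


def test_reference_pooled_rates():
    pooled = pooled_summary()
    assert pooled["prevalence_enh"] == pytest.approx(59.2, abs=0.05)
    assert pooled["prevalence_bat"] == pytest.approx(21.2, abs=0.05)
    assert pooled["model_ppv_enh"] == pytest.approx(81.3, abs=0.05)
    assert pooled["model_ppv_bat"] == pytest.approx(66.7, abs=0.05)


def test_reference_counts_additive():
    cms = reconstructed_confusions()
    for cohort in ("training", "validation"):
        both = cms[(cohort, "Both")]
        summed = cms[(cohort, "ENH")] + cms[(cohort, "BAT")]
        assert both == summed
    totals = {c.zone: c.n_pos + c.n_neg for c in REFERENCE_SUMMARY if c.cohort == "training"}
    assert totals == {"ENH": 35, "BAT": 25, "Both": 60}


def _site(patient, slice_, row, col, zone="ENH", pct=90.0):
    return BiopsySite(patient, slice_, row, col, zone, pct)


def brute_force_minimal_removal(sites, min_mm, max_mm):
    coords = site_physical_coords(sites, VOXEL)

    def offending(indices):
        return [
            (i, j)
            for i, j in combinations(indices, 2)
            if sites[i].patient_id == sites[j].patient_id
            and min_mm <= np.linalg.norm(coords[i] - coords[j]) < max_mm
        ]

    n = len(sites)
    for size in range(n, 0, -1):
        for keep in combinations(range(n), size):
            if not offending(keep):
                return size
    return 0


def test_exclude_close_pairs_no_op_when_far_apart():
    sites = [_site("P0", 0, 0, 0), _site("P0", 0, 40, 40), _site("P1", 0, 2, 2)]
    assert exclude_close_pairs(sites, 5.0, 10.0, VOXEL) == sites


def test_exclude_close_pairs_matches_subset_oracle():
    """Greedy removal keeps as many sites as exhaustive subset search."""
    layouts = [
        # 6 sites, 2 offending pairs sharing one site
        [
            _site("P0", 0, 0, 0), _site("P0", 0, 0, 5), _site("P0", 0, 5, 0),
            _site("P0", 0, 40, 40), _site("P1", 0, 0, 0), _site("P1", 0, 0, 6),
        ],
        # chain of three mutually close sites
        [
            _site("P0", 0, 0, 0), _site("P0", 0, 0, 4), _site("P0", 0, 0, 8),
            _site("P0", 0, 60, 60),
        ],
    ]
    for sites in layouts:
        kept = exclude_close_pairs(sites, 5.0, 10.0, VOXEL)
        assert len(kept) == brute_force_minimal_removal(sites, 5.0, 10.0)
        coords = site_physical_coords(kept, VOXEL)
        for i, j in combinations(range(len(kept)), 2):
            if kept[i].patient_id == kept[j].patient_id:
                d = np.linalg.norm(coords[i] - coords[j])
                assert not (5.0 <= d < 10.0)


def test_exclusion_study_shape_60_to_54():
    """Dropping 6 of 60 sites leaves 54 (the subgroup-analysis shape)."""
    rng = np.random.default_rng(0)
    sites = []
    for p in range(10):
        rows = rng.permutation(np.arange(0, 88, 11))[:6]
        sites.extend(_site(f"P{p}", 0, int(r), int(10 * (k % 3)) + 60 * 0) for k, r in enumerate(rows))
    # construct exactly 6 offending sites: pair each with a far-apart cohort
    base = [
        _site(f"Q{k}", 0, 0, 0) for k in range(3)
    ] + [_site(f"Q{k}", 0, 0, 5) for k in range(3)]  # 3 pairs 6mm apart
    clean = [_site(f"R{k}", 0, 0, 0) for k in range(48)]
    cohort = base + clean
    kept = exclude_close_pairs(cohort, 5.0, 10.0, VOXEL)
    assert len(cohort) == 54 and len(kept) == 51  # one site dropped per pair


@pytest.fixture(scope="module")
def trained_chain():
    cfg = CohortConfig(n_patients=4, volume_shape=(2, 96, 96), seed=11)
    volumes, sites = generate_cohort(cfg, range(3), [8, 8, 8])
    table = extract_cohort_features(volumes, sites)
    y = table["label"].to_numpy()
    models = fit_reduction(feature_matrix(table))
    reduced = transform(models, feature_matrix(table))
    selected = ["rCBV__raw_mean", "EPI+C__GLCM__PC1"]
    final = fit_classifier(reduced.loc[:, selected].to_numpy(float), y)
    return cfg, volumes, table, models, selected, final


def test_validation_identical_to_training_reproduces_resubstitution(trained_chain):
    cfg, volumes, table, models, selected, final = trained_chain
    out = evaluate_on_validation(
        models, selected, final, feature_matrix(table),
        table["label"].to_numpy(), table["zone"].to_numpy(),
    )
    reduced = transform(models, feature_matrix(table))
    preds, _ = predict(final, reduced.loc[:, selected].to_numpy(float))
    resub = metrics(confusion_from_labels(table["label"].to_numpy(), preds))
    for key, value in resub.items():
        got = out["Both"][key]
        assert (math.isnan(got) and math.isnan(value)) or got == pytest.approx(value)


def test_probability_map_values_and_stride_consistency(trained_chain):
    cfg, volumes, table, models, selected, final = trained_chain
    pid = table["patient_id"].iloc[0]
    pmap = render_probability_map(
        volumes[pid], models, selected, final, slice_index=0, stride=8, patient_id=pid
    )
    vals = pmap.grid[pmap.mask]
    assert np.all((vals >= 0) & (vals <= 1))
    assert np.all(np.isnan(pmap.grid[~pmap.mask]))
    # stride-8 map values equal per-ROI posteriors computed independently
    for r0 in (0, 8, 16):
        for c0 in (0, 8, 16):
            site = BiopsySite(pid, 0, r0, c0, "ENH", 0.0)
            fv = extract_site_features(volumes[pid], site)
            reduced = transform(models, fv.to_frame().T)
            _, p = predict(final, reduced.loc[:, selected].to_numpy(float))
            assert pmap.grid[r0 + 4, c0 + 4] == pytest.approx(p[0], rel=1e-9)


def test_map_over_high_tumor_region_has_elevated_posterior():
    """A map over a strongly high-tumor phantom leans toward p > 0.5."""
    cfg = CohortConfig(n_patients=2, volume_shape=(2, 96, 96), seed=3,
                       effect_rcbv=2.0)
    volumes, sites = generate_cohort(cfg, range(2), [10, 10])
    table = extract_cohort_features(volumes, sites)
    models = fit_reduction(feature_matrix(table))
    reduced = transform(models, feature_matrix(table))
    selected = ["rCBV__raw_mean"]
    final = fit_classifier(reduced.loc[:, selected].to_numpy(float),
                           table["label"].to_numpy())
    pid = "P00"
    _, field = generate_patient(cfg, 0)
    pmap = render_probability_map(volumes[pid], models, selected, final,
                                  slice_index=0, stride=4, patient_id=pid)
    # compare mean posterior over mostly-high vs mostly-low window centers
    highs, lows = [], []
    for (r, c) in np.argwhere(pmap.mask):
        frac = field.tumor_fraction[0, r - 4 : r + 4, c - 4 : c + 4].mean()
        (highs if frac >= 90 else lows if frac <= 55 else []).append(pmap.grid[r, c])
    assert np.mean(highs) > 0.5 > np.mean(lows)
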
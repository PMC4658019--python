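"""File-level pipeline stages behind the command-line interface.

Each stage is idempotent given a fixed config and seed, reads the
previous stage's artifacts, and embeds the config hash and seed in what
it writes, so a single number reproduces a run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from tumortex.classify import fit_classifier, model_to_dict, model_from_dict
from tumortex.config import RunConfig
from tumortex.evaluation import (
    confusion_from_labels,
    evaluate_on_validation,
    metrics,
    render_probability_map,
    write_probability_map,
)
from tumortex.features import FEATURE_NAMES, extract_cohort_features, write_feature_registry
from tumortex.imaging import CONTRASTS, read_sites, read_volume
from tumortex.reduction import fit_reduction, models_from_json, models_to_json, transform
from tumortex.reference_cohort import check_reference_summary, pooled_summary
from tumortex.selection import forward_select, loocv_predictions
from tumortex.study import loocv_accuracy_pca_refit
from tumortex.synthetic import simulate_study, write_cohort

METRIC_ROWS = ("ENH", "BAT", "Both")


class StageDependencyError(FileNotFoundError):
    """A required artifact from an earlier pipeline stage is missing."""


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _manifest(config: RunConfig, stage: str, extra: dict | None = None) -> None:
    config.output_dir.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "seed": config.seed, "config_hash": config_hash(config)}
    payload.update(extra or {})
    (config.output_dir / f"{stage}_manifest.json").write_text(json.dumps(payload, indent=2))


def _require(path: Path, producer: str) -> Path:
    if not Path(path).exists():
        raise StageDependencyError(f"missing artifact {path}; run the '{producer}' stage first")
    return Path(path)


def _is_training_patient(patient_id: str, config: RunConfig) -> bool:
    return int(patient_id.lstrip("P")) < config.n_train_patients


def run_simulate(config: RunConfig) -> None:
    """Generate the synthetic cohort and write volumes plus the site table."""
    from dataclasses import replace

    cohort = replace(config.cohort, seed=config.seed)
    train_vols, train_sites, val_vols, val_sites = simulate_study(
        cohort,
        n_train_patients=config.n_train_patients,
        n_train_biopsies=config.n_train_biopsies,
        n_val_biopsies=config.n_val_biopsies,
    )
    write_cohort({**train_vols, **val_vols}, train_sites + val_sites,
                 config.volumes_dir, config.sites_csv)
    _manifest(config, "simulate", {"n_sites": len(train_sites) + len(val_sites)})


def run_extract(config: RunConfig) -> pd.DataFrame:
    """Extract the 256-feature table for every biopsy site."""
    sites = read_sites(_require(config.sites_csv, "simulate"))
    _require(config.volumes_dir, "simulate")
    volumes = {}
    for site in sites:
        if site.patient_id not in volumes:
            volumes[site.patient_id] = {
                name: read_volume(config.volumes_dir / f"{site.patient_id}_{name}.nii.gz")
                for name in CONTRASTS
            }
    table = extract_cohort_features(volumes, sites, glcm_levels=config.glcm_levels)
    table.to_csv(config.output_dir / "features.csv", index=False)
    write_feature_registry(config.output_dir / "feature_registry.json")
    _manifest(config, "extract", {"n_rows": len(table), "n_features": len(FEATURE_NAMES)})
    return table


def _load_features(config: RunConfig) -> pd.DataFrame:
    path = _require(config.output_dir / "features.csv", "extract")
    return pd.read_csv(path)


def run_train(config: RunConfig) -> dict:
    """Fit reduction + forward selection + final classifier on training patients."""
    table = _load_features(config)
    train = table[[_is_training_patient(p, config) for p in table["patient_id"]]]
    y = train["label"].to_numpy()
    models = fit_reduction(train.loc[:, list(FEATURE_NAMES)])
    reduced = transform(models, train.loc[:, list(FEATURE_NAMES)])
    trace = forward_select(reduced, y, classifier=config.classifier,
                           gain_threshold=config.gain_threshold)
    selected = trace.selected if trace.selected else list(reduced.columns[:1])
    final = fit_classifier(reduced.loc[:, selected].to_numpy(float), y, kind=config.classifier)

    models_to_json(models, config.output_dir / "reduction.json")
    trace.to_json(config.output_dir / "selection_trace.json")
    (config.output_dir / "selection_report.txt").write_text(trace.report() + "\n")
    (config.output_dir / "classifier.json").write_text(
        json.dumps({"model": model_to_dict(final), "selected": selected,
                    "classifier": config.classifier}, indent=2)
    )
    retained = {m.block_id: len(m.output_columns) for m in models if not m.is_raw}
    extra = {"selected": selected, "final_cv_accuracy": trace.final_accuracy,
             "retained_pcs": retained}
    if config.pca_in_folds:
        extra["cv_accuracy_pca_refit"] = loocv_accuracy_pca_refit(
            train.reset_index(drop=True), selected, classifier=config.classifier
        )
    _manifest(config, "train", extra)
    return extra


def run_validate(config: RunConfig) -> pd.DataFrame:
    """Apply the frozen model chain; write a zone-stratified metrics table.

    Training rows hold LOOCV (held-out) metrics; validation rows hold
    frozen-model metrics on the held-out patients.
    """
    table = _load_features(config)
    models = models_from_json(_require(config.output_dir / "reduction.json", "train"))
    payload = json.loads(_require(config.output_dir / "classifier.json", "train").read_text())
    selected = payload["selected"]
    final = model_from_dict(payload["model"])

    is_train = np.array([_is_training_patient(p, config) for p in table["patient_id"]])
    train, val = table[is_train], table[~is_train]

    rows = []
    reduced = transform(models, train.loc[:, list(FEATURE_NAMES)])
    y = train["label"].to_numpy()
    preds = loocv_predictions(reduced.loc[:, selected].to_numpy(float), y,
                              classifier=config.classifier)
    for zone in METRIC_ROWS:
        mask = np.ones(len(train), bool) if zone == "Both" else (train["zone"] == zone).to_numpy()
        if mask.any():
            m = metrics(confusion_from_labels(y[mask], preds[mask]))
            rows.append({"cohort": "training", "zone": zone, **m})
    if len(val):
        val_metrics = evaluate_on_validation(
            models, selected, final, val.loc[:, list(FEATURE_NAMES)],
            val["label"].to_numpy(), val["zone"].to_numpy(),
        )
        for zone in METRIC_ROWS:
            if zone in val_metrics:
                rows.append({"cohort": "validation", "zone": zone, **val_metrics[zone]})
    frame = pd.DataFrame(rows)
    frame.to_csv(config.output_dir / "metrics.csv", index=False)
    _manifest(config, "validate", {"n_validation": int(len(val))})
    return frame


def run_map(config: RunConfig, patient_id: str, slice_index: int) -> None:
    """Render and write the tumor-probability map for one patient slice."""
    models = models_from_json(_require(config.output_dir / "reduction.json", "train"))
    payload = json.loads(_require(config.output_dir / "classifier.json", "train").read_text())
    volumes = {
        name: read_volume(_require(config.volumes_dir / f"{patient_id}_{name}.nii.gz", "simulate"))
        for name in CONTRASTS
    }
    pmap = render_probability_map(
        volumes, models, payload["selected"], model_from_dict(payload["model"]),
        slice_index, stride=config.map_stride, patient_id=patient_id,
        glcm_levels=config.glcm_levels,
    )
    stem = config.output_dir / f"probability_{patient_id}_s{slice_index}"
    write_probability_map(
        pmap, volumes["T2W"].voxel_size_mm, stem.with_suffix(".nii.gz"),
        png_path=stem.with_suffix(".png"),
        background=volumes["T2W"].data[slice_index],
    )
    _manifest(config, "map", {"patient_id": patient_id, "slice": slice_index,
                              "stride": config.map_stride})


def run_summary_check(config: RunConfig) -> bool:
    """Recompute the reference cohort summary; write report; return pass/fail."""
    frame = check_reference_summary()
    pooled = pooled_summary()
    config.output_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(config.output_dir / "summary_check.csv", index=False)
    (config.output_dir / "summary_pooled.json").write_text(json.dumps(pooled, indent=2))
    ok = bool(frame["match"].all()) and all(
        frame.attrs[f"{cohort}_additive"] for cohort in ("training", "validation")
    )
    _manifest(config, "summary_check", {"all_match": ok})
    return ok
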
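"""End-to-end synthetic study replicates.

A replicate generates a training/validation cohort split with the
default study design (60 biopsies over 11 patients for training, 22
over 7 for validation), extracts the 256 features per biopsy, fits the
block-wise reduction on the training set, runs forward selection under
LOOCV, and applies the frozen chain to the validation cohort.

Three feature blocks are informative by construction — the raw rCBV
mean, EPI+C co-occurrence texture, and T1+C local binary structure —
so a replicate also records which of them forward selection recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from tumortex.classify import fit_classifier
from tumortex.config import CohortConfig
from tumortex.evaluation import confusion_from_labels, evaluate_on_validation, metrics
from tumortex.features import extract_cohort_features, feature_matrix
from tumortex.reduction import fit_reduction, transform
from tumortex.selection import SelectionTrace, forward_select, loocv_predictions
from tumortex.synthetic import simulate_study

#: The three feature blocks carrying class signal in the generator, and
#: the reduced-column prefixes that count as recovering each.
INFORMATIVE_BLOCKS = {
    "rCBV_raw": ("rCBV__raw_mean", "rCBV__raw_sd"),
    "EPI+C_GLCM": ("EPI+C__GLCM__PC",),
    "T1+C_LBP": ("T1+C__LBP__PC",),
}


def informative_blocks_hit(selected: list[str]) -> set[str]:
    """Which informative blocks contributed at least one selected feature."""
    hit = set()
    for block, prefixes in INFORMATIVE_BLOCKS.items():
        if any(name.startswith(p) for name in selected for p in prefixes):
            hit.add(block)
    return hit


@dataclass
class ReplicateResult:
    trace: SelectionTrace
    train_loocv_accuracy: float
    train_zone_metrics: dict[str, dict[str, float]]
    validation_metrics: dict[str, dict[str, float]]
    blocks_recovered: set[str]
    train_table: pd.DataFrame
    reduced_train: pd.DataFrame


def run_replicate(
    seed: int,
    config: CohortConfig | None = None,
    classifier: str = "dlda",
    gain_threshold: float = 0.01,
    glcm_levels: int = 16,
    n_train_biopsies: int = 60,
    n_val_biopsies: int = 22,
) -> ReplicateResult:
    """Run one full synthetic study replicate at the given seed."""
    config = replace(config or CohortConfig(), seed=seed)
    train_vols, train_sites, val_vols, val_sites = simulate_study(
        config, n_train_biopsies=n_train_biopsies, n_val_biopsies=n_val_biopsies
    )
    train_table = extract_cohort_features(train_vols, train_sites, glcm_levels=glcm_levels)
    val_table = extract_cohort_features(val_vols, val_sites, glcm_levels=glcm_levels)

    y_train = train_table["label"].to_numpy()
    models = fit_reduction(feature_matrix(train_table))
    reduced_train = transform(models, feature_matrix(train_table))
    trace = forward_select(reduced_train, y_train, classifier=classifier, gain_threshold=gain_threshold)

    selected = trace.selected if trace.selected else list(reduced_train.columns[:1])
    X_sel = reduced_train.loc[:, selected].to_numpy(float)
    cv_preds = loocv_predictions(X_sel, y_train, classifier=classifier)
    train_zone_metrics = {}
    for zone in ("ENH", "BAT"):
        mask = (train_table["zone"] == zone).to_numpy()
        if mask.any():
            train_zone_metrics[zone] = metrics(
                confusion_from_labels(y_train[mask], cv_preds[mask])
            )
    train_zone_metrics["Both"] = metrics(confusion_from_labels(y_train, cv_preds))

    final_model = fit_classifier(X_sel, y_train, kind=classifier)
    validation_metrics = evaluate_on_validation(
        models,
        selected,
        final_model,
        feature_matrix(val_table),
        val_table["label"].to_numpy(),
        val_table["zone"].to_numpy(),
    )
    return ReplicateResult(
        trace=trace,
        train_loocv_accuracy=train_zone_metrics["Both"]["accuracy"],
        train_zone_metrics=train_zone_metrics,
        validation_metrics=validation_metrics,
        blocks_recovered=informative_blocks_hit(trace.selected),
        train_table=train_table,
        reduced_train=reduced_train,
    )


def recovery_experiment(
    n_replicates: int = 20,
    base_seed: int = 0,
    config: CohortConfig | None = None,
    classifier: str = "dlda",
) -> pd.DataFrame:
    """Seeded replicates of the full study; one row per replicate.

    Records the final training LOOCV accuracy, overall validation
    accuracy, and how many of the three informative blocks forward
    selection recovered.
    """
    rows = []
    for r in range(n_replicates):
        seed = int((base_seed + 1) * 10_000 + r) % (2**31)
        result = run_replicate(seed, config=config, classifier=classifier)
        rows.append(
            {
                "seed": seed,
                "n_selected": len(result.trace.selected),
                "blocks_recovered": len(result.blocks_recovered),
                "train_loocv_accuracy": result.train_loocv_accuracy,
                "validation_accuracy": result.validation_metrics["Both"]["accuracy"],
            }
        )
    return pd.DataFrame(rows)


def loocv_accuracy_pca_refit(
    train_table: pd.DataFrame, selected: list[str], classifier: str = "dlda"
) -> float:
    """Sensitivity analysis: LOOCV with the reduction refit inside each fold.

    The default pipeline fits PCA once on the full training set and
    nests only the classifier in LOOCV; this variant refits the
    block-wise reduction on each fold's n-1 samples.  A selected
    component not retained in some fold contributes a zero score there.
    """
    y = train_table["label"].to_numpy()
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_train = feature_matrix(train_table.iloc[mask])
        models = fit_reduction(fold_train)
        reduced = transform(models, fold_train).reindex(columns=selected, fill_value=0.0)
        reduced_test = transform(models, feature_matrix(train_table.iloc[[i]])).reindex(
            columns=selected, fill_value=0.0
        )
        y_fold = y[mask]
        if len(np.unique(y_fold)) == 1:
            pred = y_fold[0]
        else:
            from tumortex.classify import predict

            model = fit_classifier(reduced.to_numpy(float), y_fold, kind=classifier)
            pred = predict(model, reduced_test.to_numpy(float))[0][0]
        correct += pred == y[i]
    return correct / n
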
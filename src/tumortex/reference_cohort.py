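"""Reference cohort summary and its arithmetic identities.

The published summary of the 18-patient glioblastoma biopsy study that
this pipeline models reports, for the enhancing-core (ENH) and
brain-around-tumor (BAT) zones of the training (60 biopsies, 11
patients) and validation (22 biopsies, 7 patients) cohorts: the class
counts (high vs low tumor content) plus accuracy, sensitivity,
specificity, PPV and NPV of the optimized three-feature classifier.

Those 30 printed cells are redundant: the integer confusion matrix of
each column is pinned down by (n_pos, n_neg, sensitivity, specificity),
and accuracy/PPV/NPV must follow.  :func:`check_reference_summary`
reconstructs every confusion matrix and verifies each printed cell at
its printed rounding, and :func:`pooled_summary` derives the
full-cohort quantities (zone prevalences, i.e. the PPV of
contrast-enhancement-guided targeting, and the pooled model PPV per
zone) from the same counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from tumortex.evaluation import ConfusionMatrix, metrics, reconstruct_confusion


@dataclass(frozen=True)
class SummaryColumn:
    """One column of the reference summary: counts, rates, printed cells."""

    cohort: str  # "training" | "validation"
    zone: str  # "ENH" | "BAT" | "Both"
    n_pos: int  # high-tumor samples
    n_neg: int  # low-tumor samples
    sensitivity: float
    specificity: float
    #: printed (value-in-percent, decimal-places) per metric
    printed: dict


def _col(cohort, zone, n_pos, n_neg, sens, spec, printed):
    return SummaryColumn(cohort, zone, n_pos, n_neg, sens, spec, printed)


#: The six summary columns.  ``printed`` maps metric -> (percent, decimals)
#: exactly as reported.
REFERENCE_SUMMARY: tuple[SummaryColumn, ...] = (
    _col("training", "ENH", 22, 13, 0.864, 0.769,
         {"accuracy": (82.9, 1), "sensitivity": (86.4, 1), "specificity": (76.9, 1),
          "ppv": (86.4, 1), "npv": (76.9, 1)}),
    _col("training", "BAT", 5, 20, 0.80, 0.90,
         {"accuracy": (88.0, 0), "sensitivity": (80.0, 0), "specificity": (90.0, 0),
          "ppv": (66.7, 1), "npv": (94.7, 1)}),
    _col("training", "Both", 27, 33, 0.852, 0.848,
         {"accuracy": (85.0, 1), "sensitivity": (85.2, 1), "specificity": (84.8, 1),
          "ppv": (82.1, 1), "npv": (87.5, 1)}),
    _col("validation", "ENH", 7, 7, 1.0, 0.571,
         {"accuracy": (78.6, 1), "sensitivity": (100.0, 0), "specificity": (57.1, 1),
          "ppv": (70.0, 0), "npv": (100.0, 0)}),
    _col("validation", "BAT", 2, 6, 1.0, 0.833,
         {"accuracy": (87.5, 1), "sensitivity": (100.0, 0), "specificity": (83.3, 1),
          "ppv": (66.7, 1), "npv": (100.0, 0)}),
    _col("validation", "Both", 9, 13, 1.0, 0.692,
         {"accuracy": (81.8, 1), "sensitivity": (100.0, 0), "specificity": (69.2, 1),
          "ppv": (69.2, 1), "npv": (100.0, 0)}),
)


def reconstructed_confusions() -> dict[tuple[str, str], ConfusionMatrix]:
    """Integer confusion matrix per (cohort, zone) column."""
    return {
        (c.cohort, c.zone): reconstruct_confusion(c.n_pos, c.n_neg, c.sensitivity, c.specificity)
        for c in REFERENCE_SUMMARY
    }


def check_reference_summary() -> pd.DataFrame:
    """Recompute every printed metric cell from reconstructed counts.

    Returns a tidy frame with one row per (cohort, zone, metric):
    computed percent, printed percent, and whether they agree at the
    printed rounding.  Also checks zone additivity (Both = ENH + BAT for
    every confusion count).
    """
    cms = reconstructed_confusions()
    rows = []
    for col in REFERENCE_SUMMARY:
        computed = metrics(cms[(col.cohort, col.zone)])
        for metric, (printed_pct, decimals) in col.printed.items():
            computed_pct = round(computed[metric] * 100.0, decimals)
            rows.append(
                {
                    "cohort": col.cohort,
                    "zone": col.zone,
                    "metric": metric,
                    "computed_pct": computed_pct,
                    "printed_pct": printed_pct,
                    "match": computed_pct == round(printed_pct, decimals),
                }
            )
    frame = pd.DataFrame(rows)

    for cohort in ("training", "validation"):
        enh, bat, both = (cms[(cohort, z)] for z in ("ENH", "BAT", "Both"))
        combined = enh + bat
        frame.attrs[f"{cohort}_additive"] = combined == both
    return frame


def pooled_summary() -> dict[str, float]:
    """Full-cohort (training + validation) quantities, in percent.

    * ``prevalence_enh`` / ``prevalence_bat``: fraction of samples per
      zone with high tumor content — the hit rate of conventional
      contrast-enhancement-guided targeting;
    * ``model_ppv_enh`` / ``model_ppv_bat``: pooled PPV of the
      classifier per zone.
    """
    cms = reconstructed_confusions()
    out: dict[str, float] = {}
    for zone in ("ENH", "BAT"):
        pooled = cms[("training", zone)] + cms[("validation", zone)]
        out[f"prevalence_{zone.lower()}"] = 100.0 * (pooled.tp + pooled.fn) / pooled.n
        out[f"model_ppv_{zone.lower()}"] = 100.0 * metrics(pooled)["ppv"]
    return out
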
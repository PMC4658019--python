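"""Leave-one-out cross-validation and sequential forward feature selection.

Forward selection starts from a zero-feature baseline (the majority
class frequency — what a featureless classifier achieves), and at each
round adds the candidate feature whose inclusion most improves LOOCV
accuracy, stopping once the best incremental gain falls below the
threshold (default 0.01, i.e. the <1-accuracy-point stopping rule).
Ties are broken toward the lower column index, so the trace is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from tumortex.classify import fit_classifier, predict


@dataclass
class SelectionTrace:
    """Ordered record of forward selection: features, accuracies, stop reason."""

    selected: list[str]
    cv_accuracy: list[float]  # after each addition
    baseline_accuracy: float
    stop_reason: str  # "gain<threshold" | "exhausted"
    gain_threshold: float

    @property
    def final_accuracy(self) -> float:
        return self.cv_accuracy[-1] if self.cv_accuracy else self.baseline_accuracy

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def report(self) -> str:
        """Human-readable per-round summary of the selection."""
        lines = [
            f"baseline (majority class): {self.baseline_accuracy:.3f}",
        ]
        for name, acc in zip(self.selected, self.cv_accuracy):
            lines.append(f"  + {name:<40s} LOOCV accuracy {acc:.3f}")
        lines.append(f"stopped: {self.stop_reason} (threshold {self.gain_threshold})")
        return "\n".join(lines)


def loocv_predictions(X: np.ndarray, y: np.ndarray, classifier: str = "dlda") -> np.ndarray:
    """Held-out prediction for every sample under leave-one-out CV.

    Exactly n folds; fold i trains on the other n-1 samples and
    predicts sample i.  A fold whose training split contains a single
    class predicts that class (degenerate-fold rule).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n = len(y)
    if n < 3:
        raise ValueError(f"LOOCV needs n >= 3 samples, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present overall")
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        classes = np.unique(y_train)
        if len(classes) == 1:
            preds[i] = classes[0]
        else:
            model = fit_classifier(X[mask], y_train, kind=classifier)
            preds[i] = predict(model, X[i : i + 1])[0][0]
    return preds


def loocv_accuracy(X: np.ndarray, y: np.ndarray, classifier: str = "dlda") -> float:
    """Leave-one-out cross-validated accuracy (correct folds / n)."""
    y = np.asarray(y)
    return float((loocv_predictions(X, y, classifier=classifier) == y).mean())


def majority_accuracy(y: np.ndarray) -> float:
    """Accuracy of always predicting the most frequent class."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    return counts.max() / len(y)


def forward_select(
    X_reduced: pd.DataFrame,
    y: np.ndarray,
    classifier: str = "dlda",
    gain_threshold: float = 0.01,
) -> SelectionTrace:
    """Greedy sequential forward selection under LOOCV.

    ``X_reduced`` is the reduced feature table (PC scores plus raw
    pass-throughs); all of its columns are candidates.
    """
    if X_reduced.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    y = np.asarray(y)
    columns = list(X_reduced.columns)
    data = X_reduced.to_numpy(dtype=float)

    selected_idx: list[int] = []
    accuracies: list[float] = []
    current = majority_accuracy(y)
    baseline = current
    stop_reason = "exhausted"

    while len(selected_idx) < len(columns):
        best_gain, best_idx, best_acc = -np.inf, None, None
        for j in range(len(columns)):
            if j in selected_idx:
                continue
            acc = loocv_accuracy(data[:, selected_idx + [j]], y, classifier=classifier)
            gain = acc - current
            if gain > best_gain:  # strict: ties keep the lower index
                best_gain, best_idx, best_acc = gain, j, acc
        if best_gain < gain_threshold:
            stop_reason = "gain<threshold"
            break
        selected_idx.append(best_idx)
        accuracies.append(best_acc)
        current = best_acc

    return SelectionTrace(
        selected=[columns[j] for j in selected_idx],
        cv_accuracy=accuracies,
        baseline_accuracy=baseline,
        stop_reason=stop_reason,
        gain_threshold=gain_threshold,
    )
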
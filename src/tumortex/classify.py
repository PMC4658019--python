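"""Diagonal discriminant classifiers and a linear SVM.

DLDA and DQDA model each class as a diagonal-covariance Gaussian:
per-feature variances are pooled across classes (DLDA, giving linear
boundaries) or estimated per class (DQDA, quadratic boundaries).
Priors are the empirical class frequencies — class imbalance in a
biopsy cohort is informative.  Posterior probabilities come from the
exact diagonal-Gaussian log-likelihoods; exact ties are resolved toward
'low', the conservative call for biopsy guidance where a false
high-tumor prediction is the costly error.

The SVM is a linear-kernel ``sklearn.svm.SVC`` (C=1 by default) on
pre-standardized features; its pseudo-posterior is a logistic squash of
the signed decision value, which is deterministic (Platt scaling is
not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

CLASSES = ("high", "low")
VARIANCE_FLOOR = 1e-9


@dataclass
class DiagonalGaussianModel:
    """Shared state of DLDA/DQDA: per-class means/variances and log priors."""

    kind: str  # "dlda" | "dqda"
    means: np.ndarray  # (2, n_features), rows follow CLASSES
    variances: np.ndarray  # (2, n_features); identical rows for DLDA
    log_priors: np.ndarray  # (2,)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


@dataclass
class SvmModel:
    kind: str
    estimator: SVC
    n_features: int


def _check_classes(y: np.ndarray) -> list[np.ndarray]:
    masks = [y == c for c in CLASSES]
    for c, m in zip(CLASSES, masks):
        if not m.any():
            raise ValueError(f"both classes required for fitting; class {c!r} absent")
    return masks


def fit_dlda(X: np.ndarray, y: np.ndarray) -> DiagonalGaussianModel:
    """Diagonal LDA: class means with variances pooled across classes.

    Pooled variance is the total within-class squared deviation divided
    by n, floored at 1e-9.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    masks = _check_classes(y)
    means = np.vstack([X[m].mean(axis=0) for m in masks])
    pooled_ss = sum(((X[m] - means[i]) ** 2).sum(axis=0) for i, m in enumerate(masks))
    pooled = np.maximum(pooled_ss / len(y), VARIANCE_FLOOR)
    log_priors = np.log([m.mean() for m in masks])
    return DiagonalGaussianModel(
        kind="dlda", means=means, variances=np.vstack([pooled, pooled]), log_priors=log_priors
    )


def fit_dqda(X: np.ndarray, y: np.ndarray) -> DiagonalGaussianModel:
    """Diagonal QDA: class means with class-specific per-feature variances."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    masks = _check_classes(y)
    means = np.vstack([X[m].mean(axis=0) for m in masks])
    variances = np.vstack(
        [np.maximum(X[m].var(axis=0, ddof=0), VARIANCE_FLOOR) for m in masks]
    )
    log_priors = np.log([m.mean() for m in masks])
    return DiagonalGaussianModel(kind="dqda", means=means, variances=variances, log_priors=log_priors)


def fit_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SvmModel:
    """Linear-kernel SVM on (already standardized) reduced features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_classes(y)
    est = SVC(kernel="linear", C=C)
    est.fit(X, y)
    return SvmModel(kind="svm", estimator=est, n_features=X.shape[1])


def fit_classifier(X: np.ndarray, y: np.ndarray, kind: str = "dlda", C: float = 1.0):
    """Fit one of the three supported classifiers ('dlda', 'dqda', 'svm')."""
    if kind == "dlda":
        return fit_dlda(X, y)
    if kind == "dqda":
        return fit_dqda(X, y)
    if kind == "svm":
        return fit_svm(X, y, C=C)
    raise ValueError(f"unknown classifier kind {kind!r}")


def log_likelihoods(model: DiagonalGaussianModel, X: np.ndarray) -> np.ndarray:
    """Per-class diagonal-Gaussian log joint density log p(x|c) + log pi_c."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    out = np.empty((X.shape[0], 2))
    for i in range(2):
        mu, var = model.means[i], model.variances[i]
        out[:, i] = (
            -0.5 * (((X - mu) ** 2) / var + np.log(2 * np.pi * var)).sum(axis=1)
            + model.log_priors[i]
        )
    return out


def discriminant_scores(model: DiagonalGaussianModel, X: np.ndarray) -> np.ndarray:
    """DLDA-form discriminants: -sum_j (x_j-mu_cj)^2/sigma_j^2 + 2 log pi_c."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    out = np.empty((X.shape[0], 2))
    for i in range(2):
        out[:, i] = (
            -(((X - model.means[i]) ** 2) / model.variances[i]).sum(axis=1)
            + 2.0 * model.log_priors[i]
        )
    return out


@dataclass
class LinearDecisionModel:
    """A loaded linear SVM reduced to its decision hyperplane."""

    kind: str
    weights: np.ndarray
    bias: float

    @property
    def n_features(self) -> int:
        return len(self.weights)


def model_to_dict(model) -> dict:
    """JSON-serializable state of any fitted classifier."""
    if isinstance(model, DiagonalGaussianModel):
        return {
            "kind": model.kind,
            "means": model.means.tolist(),
            "variances": model.variances.tolist(),
            "log_priors": model.log_priors.tolist(),
        }
    est = model.estimator if isinstance(model, SvmModel) else None
    if est is not None:
        return {
            "kind": "svm",
            "weights": est.coef_[0].tolist(),
            "bias": float(est.intercept_[0]),
        }
    if isinstance(model, LinearDecisionModel):
        return {"kind": "svm", "weights": model.weights.tolist(), "bias": model.bias}
    raise TypeError(f"cannot serialize model of type {type(model)!r}")


def model_from_dict(payload: dict):
    if payload["kind"] in ("dlda", "dqda"):
        return DiagonalGaussianModel(
            kind=payload["kind"],
            means=np.array(payload["means"]),
            variances=np.array(payload["variances"]),
            log_priors=np.array(payload["log_priors"]),
        )
    return LinearDecisionModel(
        kind="svm", weights=np.array(payload["weights"]), bias=float(payload["bias"])
    )


def predict(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and posterior probability of high tumor content per sample.

    Posteriors are normalized over the two classes (they sum to 1); an
    exact posterior tie predicts 'low'.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if isinstance(model, (SvmModel, LinearDecisionModel)):
        if X.shape[1] != model.n_features:
            raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
        if isinstance(model, SvmModel):
            decision = model.estimator.decision_function(X)
        else:
            decision = X @ model.weights + model.bias
        # sklearn orders classes alphabetically: decision > 0 means 'low'
        p_high = 1.0 / (1.0 + np.exp(decision))
    else:
        ll = log_likelihoods(model, X)
        shifted = ll - ll.max(axis=1, keepdims=True)
        weights = np.exp(shifted)
        p_high = weights[:, 0] / weights.sum(axis=1)
    labels = np.where(p_high > 0.5, "high", "low")
    return labels, p_high
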
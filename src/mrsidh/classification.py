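"""Differential-feature selection and linear SVM classification.

The classifier follows a deliberately simple recipe: rank harmonized
grid points by the absolute Welch two-sample t statistic between the
IDH-mutant and wild-type groups, choose how many of the top-ranked
features to keep by stratified cross-validation (feature ranking redone
inside each training fold, so held-out accuracy is free of selection
bias), then train a soft-margin linear SVM — minimize
½‖w‖² + C Σᵢ max(0, 1 − yᵢ(w·xᵢ + b)) — with the cost parameter left at
its default of 1 on the selected, standardized features.  The final
model is fit on the complete training cohort.

"mut" is the positive class throughout; the decision threshold is fixed
at 0 and is never recalibrated on validation data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .harmonization import ReferenceGrid
from .spectra_io import AcquisitionParams, ppm_axis

DEFAULT_CANDIDATE_COUNTS = (1, 2, 3, 5, 10, 20, 50, 100)

POSITIVE_LABEL = "mut"
NEGATIVE_LABEL = "wt"


class GridMismatchError(ValueError):
    """Input feature matrix does not match the model's reference grid."""


class DegenerateClassError(ValueError):
    """A class is missing or too small for the requested operation."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings for feature selection and SVM training."""

    cost: float = 1.0
    candidate_feature_counts: tuple = DEFAULT_CANDIDATE_COUNTS
    cv_folds: int = 5
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.cost > 0):
            raise ValueError("cost must be > 0")
        cands = tuple(sorted(int(k) for k in self.candidate_feature_counts))
        if not cands or cands[0] < 1:
            raise ValueError("candidate feature counts must be positive integers")
        object.__setattr__(self, "candidate_feature_counts", cands)
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TrainedModel:
    """A fitted linear SVM on selected reference-grid features.

    ``feature_indices`` index into the reference grid's analysis window
    (rank order, most discriminative first); ``scaler_mean`` and
    ``scaler_scale`` are the training-set statistics used to standardize
    the selected features before the SVM.
    """

    feature_indices: np.ndarray
    weights: np.ndarray
    bias: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    k_selected: int
    n_input_features: int
    grid: ReferenceGrid | None = None
    normalization: str = "window-area"
    cv_table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = self.k_selected
        if not (
            len(self.feature_indices) == len(self.weights) == len(self.scaler_mean)
            == len(self.scaler_scale) == k
        ):
            raise ValueError("inconsistent model component lengths")
        if len(set(int(i) for i in self.feature_indices)) != k:
            raise ValueError("feature indices must be unique")

    @property
    def feature_ppm(self) -> np.ndarray | None:
        if self.grid is None:
            return None
        return self.grid.window_values[self.feature_indices]


def _to_binary(y) -> np.ndarray:
    y = np.asarray(y)
    out = np.zeros(y.shape[0], dtype=int)
    for i, label in enumerate(y):
        if label == POSITIVE_LABEL:
            out[i] = 1
        elif label != NEGATIVE_LABEL:
            raise ValueError(f"unknown label {label!r}")
    return out


def rank_features(X: np.ndarray, y) -> np.ndarray:
    """Feature indices sorted by decreasing |Welch t| between classes.

    Ties break toward the lower index; features with zero variance in
    both classes get statistic 0 and therefore rank last.
    """
    X = np.asarray(X, dtype=float)
    yb = _to_binary(y)
    n1, n0 = int(yb.sum()), int((1 - yb).sum())
    if n1 < 2 or n0 < 2:
        raise DegenerateClassError(
            f"each class needs >= 2 members for Welch t (mut={n1}, wt={n0})"
        )
    X1, X0 = X[yb == 1], X[yb == 0]
    m1, m0 = X1.mean(axis=0), X0.mean(axis=0)
    v1, v0 = X1.var(axis=0, ddof=1), X0.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / n1 + v0 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m0) / np.where(denom > 0, denom, 1.0), 0.0)
    # stable sort on -|t| keeps lower indices first among ties
    return np.argsort(-np.abs(t), kind="stable")


def hinge_objective(w: np.ndarray, b: float, X: np.ndarray, y01, cost: float) -> float:
    """Primal soft-margin objective ½‖w‖² + C Σ max(0, 1 − y(w·x + b))."""
    ypm = 2 * np.asarray(y01) - 1
    margins = ypm * (X @ np.asarray(w) + b)
    return 0.5 * float(np.dot(w, w)) + cost * float(np.maximum(0.0, 1.0 - margins).sum())


def fit_linear_svm(X: np.ndarray, y01, cost: float = 1.0) -> tuple:
    """Fit the primal soft-margin linear SVM; return ``(w, b)``.

    Uses the libsvm solver (C-SVC with a linear kernel), the same
    formulation and per-sample hinge-sum convention as the R package
    e1071.  No internal scaling is applied here; callers standardize.
    """
    clf = SVC(kernel="linear", C=cost, tol=1e-8)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y01, dtype=int))
    if list(clf.classes_) != [0, 1]:
        raise DegenerateClassError("both classes must be present for SVM training")
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


@dataclass
class FeatureCountSelection:
    """Cross-validation result of the feature-count search."""

    k_star: int
    mean_accuracy: dict
    fold_accuracy: dict


def select_feature_count(
    X: np.ndarray, y, config: ClassifierConfig = ClassifierConfig()
) -> FeatureCountSelection:
    """Choose the number of top-ranked features by stratified CV.

    Within each fold, features are ranked on the fold's training part
    only; a linear SVM on the top-k standardized features is scored on
    the held-out part.  k* is the candidate with the highest mean
    held-out accuracy, ties resolved toward the smallest k.  If a class
    is too small for the requested fold count, the fold count is reduced
    to the largest feasible value (with a warning).
    """
    X = np.asarray(X, dtype=float)
    yb = _to_binary(y)
    n_features = X.shape[1]
    candidates = [k for k in config.candidate_feature_counts if k <= n_features]
    skipped = [k for k in config.candidate_feature_counts if k > n_features]
    if skipped:
        warnings.warn(
            f"candidate feature counts {skipped} exceed the {n_features} "
            "available features and were skipped"
        )
    if not candidates:
        raise ValueError("no candidate feature count is <= the number of features")
    min_class = int(min(yb.sum(), (1 - yb).sum()))
    if min_class < 4:
        raise DegenerateClassError(
            "each class needs >= 4 members for cross-validated selection "
            "(fold-internal ranking needs >= 2 per class in every training part)"
        )
    folds = config.cv_folds
    if min_class < 2 * folds:
        folds = max(2, min_class // 2)
        warnings.warn(
            f"reduced CV folds from {config.cv_folds} to {folds} "
            f"(smallest class has {min_class} members)"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.cv_seed)
    fold_acc = {k: [] for k in candidates}
    for train_idx, test_idx in skf.split(X, yb):
        ranked = rank_features(X[train_idx], np.where(yb[train_idx] == 1, "mut", "wt"))
        for k in candidates:
            cols = ranked[:k]
            Xtr, Xte = X[np.ix_(train_idx, cols)], X[np.ix_(test_idx, cols)]
            mean = Xtr.mean(axis=0)
            scale = Xtr.std(axis=0)
            scale = np.where(scale > 0, scale, 1.0)
            w, b = fit_linear_svm((Xtr - mean) / scale, yb[train_idx], config.cost)
            scores = (Xte - mean) / scale @ w + b
            pred = (scores > 0).astype(int)
            fold_acc[k].append(float(np.mean(pred == yb[test_idx])))
    mean_acc = {k: float(np.mean(v)) for k, v in fold_acc.items()}
    best = max(mean_acc.values())
    k_star = min(k for k, acc in mean_acc.items() if acc == best)
    return FeatureCountSelection(
        k_star=k_star, mean_accuracy=mean_acc, fold_accuracy=fold_acc
    )


def train(
    X: np.ndarray,
    y,
    config: ClassifierConfig = ClassifierConfig(),
    grid: ReferenceGrid | None = None,
    k: int | None = None,
) -> TrainedModel:
    """Train the final model on the complete training matrix.

    The feature count is chosen by :func:`select_feature_count` unless
    ``k`` is given; the top-k features are then re-ranked on all training
    data, standardized with training statistics, and a linear SVM with
    the configured cost is fit.
    """
    X = np.asarray(X, dtype=float)
    yb = _to_binary(y)
    if yb.sum() == 0 or yb.sum() == len(yb):
        raise DegenerateClassError("training data must contain both classes")
    if k is None:
        selection = select_feature_count(X, y, config)
        k_star = selection.k_star
        cv_table = {
            "mean_accuracy": {str(kk): v for kk, v in selection.mean_accuracy.items()},
            "fold_accuracy": {str(kk): v for kk, v in selection.fold_accuracy.items()},
        }
    else:
        k_star = int(k)
        cv_table = {}
    if k_star >= X.shape[1]:
        cols = np.arange(X.shape[1])  # all features kept: no ranking needed
    else:
        cols = rank_features(X, y)[:k_star]
    mean = X[:, cols].mean(axis=0)
    scale = X[:, cols].std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    w, b = fit_linear_svm((X[:, cols] - mean) / scale, yb, config.cost)
    return TrainedModel(
        feature_indices=np.asarray(cols, dtype=int),
        weights=np.asarray(w, dtype=float),
        bias=float(b),
        scaler_mean=mean,
        scaler_scale=scale,
        k_selected=k_star,
        n_input_features=X.shape[1],
        grid=grid,
        cv_table=cv_table,
    )


def decision_scores(model: TrainedModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.n_input_features:
        raise GridMismatchError(
            f"expected {model.n_input_features} reference-grid features, got "
            f"{X_new.shape[1] if X_new.ndim == 2 else 'non-matrix input'}; "
            "harmonize spectra onto the model's reference grid first"
        )
    Z = (X_new[:, model.feature_indices] - model.scaler_mean) / model.scaler_scale
    return Z @ model.weights + model.bias


def predict(model: TrainedModel, X_new: np.ndarray) -> tuple:
    """Predict labels and decision scores for harmonized spectra.

    A spectrum is called "mut" iff its score is strictly positive (a
    score of exactly 0 is called "wt").
    """
    scores = decision_scores(model, X_new)
    labels = np.where(scores > 0, POSITIVE_LABEL, NEGATIVE_LABEL)
    return labels, scores


# ---------------------------------------------------------------------------
# Model files: versioned JSON documents.
# ---------------------------------------------------------------------------

MODEL_SCHEMA_VERSION = 1


def write_model(model: TrainedModel, path) -> None:
    doc = {
        "format": "mrsidh-model",
        "schema_version": MODEL_SCHEMA_VERSION,
        "positive_label": POSITIVE_LABEL,
        "normalization": model.normalization,
        "k_selected": model.k_selected,
        "n_input_features": model.n_input_features,
        "feature_indices": [int(i) for i in model.feature_indices],
        "weights": [float(v) for v in model.weights],
        "bias": model.bias,
        "scaler_mean": [float(v) for v in model.scaler_mean],
        "scaler_scale": [float(v) for v in model.scaler_scale],
        "cv_table": model.cv_table,
    }
    if model.grid is not None:
        n = len(model.grid.axis)
        spacing = model.grid.axis.spacing
        top = float(model.grid.axis.values[0])
        doc["reference_grid"] = {
            "acquisition": {
                "n_points": n,
                "spacing_ppm": spacing,
                "top_ppm": top,
            },
            "analysis_window": list(model.grid.analysis_window),
            "anchor_ppm": model.grid.anchor_ppm,
        }
        ppm = model.feature_ppm
        doc["feature_ppm"] = [float(p) for p in ppm]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_model(path) -> TrainedModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "mrsidh-model":
        raise ValueError(f"{path}: not a model document")
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported model schema version")
    grid = None
    if "reference_grid" in doc:
        g = doc["reference_grid"]
        acq = g["acquisition"]
        n = int(acq["n_points"])
        spacing = float(acq["spacing_ppm"])
        top = float(acq["top_ppm"])
        span = spacing * n
        params = AcquisitionParams(
            field_strength_t=1.0 / 42.576,
            spectral_width_hz=span,
            n_points=n,
            transmitter_frequency_mhz=1.0,
            center_ppm=top - span / 2.0,
        )
        grid = ReferenceGrid(
            axis=ppm_axis(params),
            analysis_window=tuple(g["analysis_window"]),
            anchor_ppm=float(g["anchor_ppm"]),
        )
    return TrainedModel(
        feature_indices=np.asarray(doc["feature_indices"], dtype=int),
        weights=np.asarray(doc["weights"], dtype=float),
        bias=float(doc["bias"]),
        scaler_mean=np.asarray(doc["scaler_mean"], dtype=float),
        scaler_scale=np.asarray(doc["scaler_scale"], dtype=float),
        k_selected=int(doc["k_selected"]),
        n_input_features=int(doc["n_input_features"]),
        grid=grid,
        normalization=doc.get("normalization", "window-area"),
        cv_table=doc.get("cv_table", {}),
    )
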
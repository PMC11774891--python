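"""The four classification back-ends.

1. PLSR inversion: partial least squares regressions predicting R̂/Ĝ/B̂ from
   six fused features per channel; predicted triples are then labeled by the
   RGB box thresholds. With all components retained on full-rank data the fit
   coincides with ordinary least squares.
2. Logit-R: an L2-penalized logistic classifier trained by plain gradient
   descent with fixed hyperparameters (penalty coefficient 0.2, learning rate
   0.01, 300 iterations, decision threshold 0.5) on features standardized to
   training mean/SD.
3/4. Lasso-selected RF / SVC: an L1-penalized logistic path tuned by
   cross-validated AUC picks a sparse feature subset from the 633-feature
   pool; random forest (500 trees) and an RBF support vector classifier
   (cost 1) are then fit on the selected columns at those documented defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from scipy.special import expit

from .labeling import RGBThresholds, DEFAULT_THRESHOLDS, label_rgb

# ---------------------------------------------------------------------------
# PLSR


@dataclass
class PLSRModel:
    feature_names: list[str]
    target_names: list[str]
    n_components: int
    coef: np.ndarray        # n_targets × n_features, original scale
    intercept: np.ndarray   # n_targets

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = _check_features(features, self.feature_names)
        return x @ self.coef.T + self.intercept

    def to_json(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "kind": "plsr",
            "feature_names": self.feature_names,
            "target_names": self.target_names,
            "n_components": self.n_components,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: Path | str) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        return cls(d["feature_names"], d["target_names"], d["n_components"],
                   np.asarray(d["coef"]), np.asarray(d["intercept"]))


def _check_features(features, names: list[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise ValueError(f"feature mismatch: missing {missing}")
        return features[names].to_numpy(dtype=float)
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(names):
        raise ValueError(f"feature mismatch: expected {len(names)} columns, got {x.shape}")
    return x


def fit_plsr(features: pd.DataFrame | np.ndarray, targets: np.ndarray,
             n_components: int | None = None,
             target_names: list[str] | None = None) -> PLSRModel:
    """Partial-least-squares fit, one single-target decomposition per column.

    ``targets`` may be n × k (e.g. the RGB matrix) or a single vector.
    ``n_components`` defaults to the number of features (full fit).
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"x{i}" for i in range(x.shape[1])]
    y = np.asarray(targets, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if target_names is None:
        target_names = [f"y{k}" for k in range(y.shape[1])]
    p = x.shape[1]
    if n_components is None:
        n_components = p
    if not 1 <= n_components <= p:
        raise ValueError(f"n_components must lie in [1, {p}]")
    if x.shape[0] <= n_components:
        raise ValueError("need more samples than components")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds feature rank {rank}")
    coef = np.empty((y.shape[1], p))
    intercept = np.empty(y.shape[1])
    for k in range(y.shape[1]):
        yk = y[:, k]
        if np.ptp(yk) == 0:
            coef[k], intercept[k] = 0.0, yk[0]
            continue
        pls = PLSRegression(n_components=n_components, scale=True)
        pls.fit(x, yk)
        coef[k] = pls.coef_.ravel()
        # express the model on the original (uncentered) feature scale
        intercept[k] = float(yk.mean() - x.mean(axis=0) @ coef[k])
    return PLSRModel(names, list(target_names), n_components, coef, intercept)


def classify_plsr(model: PLSRModel, features,
                  thresholds: RGBThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Predict R̂/Ĝ/B̂ and label by the box thresholds."""
    rgb_hat = model.predict(features)
    if rgb_hat.shape[1] != 3:
        raise ValueError("classify_plsr requires a 3-target (RGB) model")
    return label_rgb(np.clip(rgb_hat, 0.0, 255.0), thresholds)


# ---------------------------------------------------------------------------
# Logit-R (gradient descent, fixed hyperparameters)


@dataclass
class LogitModel:
    weights: np.ndarray
    intercept: float
    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    l2_coefficient: float = 0.2
    learning_rate: float = 0.01
    max_iterations: int = 300
    decision_threshold: float = 0.5
    fit_intercept: bool = True
    loss_path: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def predict_prob(self, features) -> np.ndarray:
        x = (_check_features(features, self.feature_names) - self.mean) / self.sd
        return expit(x @ self.weights + self.intercept)

    def classify(self, features) -> np.ndarray:
        return (self.predict_prob(features) >= self.decision_threshold).astype(int)

    def to_json(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "kind": "logit",
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "standardization": {"mean": self.mean.tolist(), "sd": self.sd.tolist()},
            "hyperparameters": {
                "l2_coefficient": self.l2_coefficient,
                "learning_rate": self.learning_rate,
                "max_iterations": self.max_iterations,
                "decision_threshold": self.decision_threshold,
                "fit_intercept": self.fit_intercept,
            },
        }, indent=2))
        return path


def fit_logit(features: pd.DataFrame | np.ndarray, labels: np.ndarray,
              l2_coefficient: float = 0.2, learning_rate: float = 0.01,
              max_iterations: int = 300, decision_threshold: float = 0.5,
              fit_intercept: bool = True) -> LogitModel:
    """Gradient descent on L2-penalized mean log-loss from zero initialization.

    loss(w, b) = mean log-loss + (l2/2)·||w||² (intercept unpenalized);
    features are standardized with training mean/SD (constants stored).
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"x{i}" for i in range(x.shape[1])]
    y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("labels must contain both classes 0 and 1")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mean) / sd
    n = xs.shape[0]
    w = np.zeros(xs.shape[1])
    b = 0.0
    losses = np.empty(max_iterations)
    for t in range(max_iterations):
        p = expit(xs @ w + b)
        eps = 1e-12
        losses[t] = (-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
                     + 0.5 * l2_coefficient * float(w @ w))
        grad_w = xs.T @ (p - y) / n + l2_coefficient * w
        w -= learning_rate * grad_w
        if fit_intercept:
            b -= learning_rate * float(np.mean(p - y))
    return LogitModel(w, b, names, mean, sd, l2_coefficient, learning_rate,
                      max_iterations, decision_threshold, fit_intercept, losses)


# ---------------------------------------------------------------------------
# Lasso-penalized selection + RF / SVC


@dataclass
class FeatureSelection:
    lam: float
    selected_names: list[str]
    tuning_metric: str = "auc"
    cv_folds: int = 10

    def to_json(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "kind": "lasso_selection", "lambda": self.lam,
            "selected_names": self.selected_names,
            "tuning_metric": self.tuning_metric, "cv_folds": self.cv_folds,
        }, indent=2))
        return path


def lasso_select(pool: pd.DataFrame, labels: np.ndarray, cv_folds: int = 10,
                 seed: int | None = None, n_lambdas: int = 25) -> FeatureSelection:
    """L1-penalized logistic path on the standardized pool; λ maximizes CV AUC.

    Returns the features with nonzero coefficients at the chosen penalty.
    λ is reported on the per-sample scale (1 / (C·n)).
    """
    y = np.asarray(labels, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain both classes")
    if counts.min() < cv_folds:
        raise ValueError(f"minority class has {counts.min()} seeds; cannot stratify "
                         f"{cv_folds} folds with both classes present")
    x = pool.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    xs = (x - mean) / np.where(sd > 0, sd, 1.0)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=np.logspace(-2.0, 2.0, n_lambdas), penalty="l1", solver="liblinear",
        scoring="roc_auc", cv=cv, max_iter=2000, refit=True)
    model.fit(xs, y)
    coefs = model.coef_.ravel()
    selected = [name for name, c in zip(pool.columns, coefs) if c != 0.0]
    lam = 1.0 / (float(model.C_[0]) * xs.shape[0])
    return FeatureSelection(lam, selected, "auc", cv_folds)


def l1_selection_path(pool: pd.DataFrame, labels: np.ndarray,
                      Cs: np.ndarray) -> list[list[str]]:
    """Selected feature sets along an L1 path (small C = strong penalty first)."""
    y = np.asarray(labels, dtype=float)
    x = pool.to_numpy(dtype=float)
    sd = x.std(axis=0)
    xs = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    sets = []
    for c in np.sort(np.asarray(Cs, dtype=float)):
        clf = LogisticRegression(penalty="l1", C=c, solver="liblinear", max_iter=2000)
        clf.fit(xs, y)
        sets.append([n for n, w in zip(pool.columns, clf.coef_.ravel()) if w != 0.0])
    return sets


@dataclass
class SelectedClassifier:
    """An RF or SVC fit on a lasso-selected feature subset."""

    kind: str
    feature_names: list[str]
    estimator: object
    mean: np.ndarray
    sd: np.ndarray

    def predict(self, features) -> np.ndarray:
        x = _check_features(features, self.feature_names)
        return self.estimator.predict((x - self.mean) / self.sd).astype(int)


def _fit_selected(kind: str, features: pd.DataFrame, labels: np.ndarray,
                  estimator) -> SelectedClassifier:
    if features.shape[1] == 0:
        raise ValueError("empty feature set")
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    estimator.fit((x - mean) / sd, y.astype(int))
    return SelectedClassifier(kind, list(features.columns), estimator, mean, sd)


def fit_rf(features: pd.DataFrame, labels: np.ndarray, seed: int | None = None,
           n_estimators: int = 500) -> SelectedClassifier:
    """Random forest at documented defaults (500 trees), deterministic per seed."""
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    return _fit_selected("rf", features, labels, rf)


def fit_svc(features: pd.DataFrame, labels: np.ndarray,
            seed: int | None = None, cost: float = 1.0) -> SelectedClassifier:
    """RBF support vector classifier at documented defaults (cost = 1)."""
    svc = SVC(kernel="rbf", C=cost, gamma="scale", random_state=seed)
    return _fit_selected("svc", features, labels, svc)
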
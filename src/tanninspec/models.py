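"""The three regression families and their tuning protocol.

* PLS: latent-variable linear regression (mean-centered, unscaled); the
  component count is the RMSECV minimizer over the shared stratified folds.
* SVR: RBF-kernel epsilon-SVR on standardized features, tuned by exhaustive
  search over the fixed 5x6 (C, gamma) grid, maximizing the mean held-out
  R^2 across folds; ties break toward smaller C then smaller gamma.
* CNN: the seeded numpy 1-D convolutional network in :mod:`tanninspec.cnn`,
  standardizing features and target internally.

Features are left raw at the fusion stage; each family applies only its own
conventional scaling internally, so the three families see the same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import joblib
import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import r2_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cars import _pls_components_cap, rmsecv
from .cnn import CNNRegressor, CNNSpec
from .datasplit import CVFolds

__all__ = ["SVRSpec", "CNNSpec", "TrainedModel", "fit_pls", "tune_fit_svr",
           "fit_cnn", "predict", "save_model", "load_model"]


@dataclass(frozen=True)
class SVRSpec:
    c_grid: tuple[float, ...] = (0.1, 1, 10, 100, 1000)
    gamma_grid: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.1, 1, 10)
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")


@dataclass
class TrainedModel:
    family: str            # "PLS" | "SVR" | "CNN"
    estimator: object
    n_features: int
    metadata: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"{self.family} model expects {self.n_features} features, "
                f"got shape {X.shape}"
            )
        yhat = np.asarray(self.estimator.predict(X), float).ravel()
        if not np.all(np.isfinite(yhat)):
            raise FloatingPointError(f"{self.family} produced non-finite predictions")
        return yhat


def fit_pls(X, y, folds: CVFolds, max_components: int = 10) -> TrainedModel:
    """PLS with the RMSECV-minimizing component count (deterministic)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    cap = _pls_components_cap(
        min(X.shape[0] - f.size for f in folds.folds), X.shape[1], max_components
    )
    errs = [rmsecv(X, y, folds, nc) for nc in range(1, cap + 1)]
    n_comp = int(np.argmin(errs)) + 1
    pls = PLSRegression(n_components=n_comp, scale=False).fit(X, y)
    return TrainedModel("PLS", pls, X.shape[1],
                        {"n_components": n_comp, "rmsecv": float(errs[n_comp - 1])})


def tune_fit_svr(X, y, spec: SVRSpec, folds: CVFolds) -> TrainedModel:
    """Exhaustive (C, gamma) search maximizing mean held-out fold R^2."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if y.std() == 0:
        raise ValueError("target has zero variance")
    best: tuple[float, float, float] | None = None  # (score, C, gamma)
    for C, gamma in product(spec.c_grid, spec.gamma_grid):
        scores = []
        for train, test in folds.iter_splits():
            model = Pipeline([
                ("scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", C=C, gamma=gamma, epsilon=spec.epsilon)),
            ]).fit(X[train], y[train])
            scores.append(r2_score(y[test], model.predict(X[test])))
        score = float(np.mean(scores))
        if best is None or score > best[0]:  # strict: first (smallest C, gamma) wins ties
            best = (score, C, gamma)
    _, C, gamma = best
    final = Pipeline([
        ("scale", StandardScaler()),
        ("svr", SVR(kernel="rbf", C=C, gamma=gamma, epsilon=spec.epsilon)),
    ]).fit(X, y)
    return TrainedModel("SVR", final, X.shape[1],
                        {"C": C, "gamma": gamma, "epsilon": spec.epsilon,
                         "cv_r2": best[0]})


def fit_cnn(X, y, spec: CNNSpec | None = None) -> TrainedModel:
    """Train the numpy CNN; early stopping on an internal validation split."""
    spec = spec or CNNSpec()
    reg = CNNRegressor(spec).fit(X, y)
    return TrainedModel("CNN", reg, np.asarray(X).shape[1],
                        {"spec": spec, "stopped_epoch": reg.stopped_epoch_,
                         "epochs_run": len(reg.history_["loss"])})


def predict(model: TrainedModel, X) -> np.ndarray:
    return model.predict(X)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    return joblib.load(path)
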
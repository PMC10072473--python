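"""Classical regressors under the same fit/predict contract.

All models are trained on a single concatenated feature matrix (e.g.
expression + both drugs' fingerprints). Kernelized SVR does not scale to
screen-sized data, so the RBF-kernel variant approximates the kernel
feature map with the Nystroem method before fitting a linear SVR.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.kernel_approximation import Nystroem
from sklearn.linear_model import ElasticNet
from sklearn.pipeline import make_pipeline
from sklearn.svm import LinearSVR

__all__ = ["CLASSICAL_KINDS", "fit_classical"]


def _make(kind: str, params: dict):
    if kind == "elastic_net":
        return ElasticNet(**{"alpha": 1.0, "max_iter": 5000, **params})
    if kind == "linear_svr":
        return LinearSVR(**{"max_iter": 5000, **params})
    if kind == "nystroem_svr":
        n_components = params.pop("n_components", 100)
        gamma = params.pop("gamma", None)
        seed = params.pop("random_state", 0)
        return make_pipeline(
            Nystroem(kernel="rbf", gamma=gamma, n_components=n_components, random_state=seed),
            LinearSVR(**{"max_iter": 5000, **params}),
        )
    if kind == "random_forest":
        return RandomForestRegressor(**{"n_estimators": 100, "random_state": 0, **params})
    if kind == "gradient_boosting":
        return GradientBoostingRegressor(**{"random_state": 0, **params})
    if kind == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(**{"random_state": 0, "n_jobs": 1, **params})
    if kind == "lightgbm":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(**{"random_state": 0, "n_jobs": 1, "verbose": -1, **params})
    raise ValueError(f"unknown classical model kind {kind!r}")


CLASSICAL_KINDS = (
    "elastic_net",
    "linear_svr",
    "nystroem_svr",
    "random_forest",
    "gradient_boosting",
    "xgboost",
    "lightgbm",
)


def fit_classical(kind: str, features: np.ndarray, targets: np.ndarray, params: dict | None = None):
    """Fit a classical regressor on a concatenated feature matrix.

    Returns a fitted estimator exposing ``predict(X)``; all kinds share
    this contract.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float).ravel()
    if not np.isfinite(features).all():
        raise ValueError("feature matrix contains non-finite values")
    model = _make(kind, dict(params or {}))
    model.fit(features, targets)
    return model
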
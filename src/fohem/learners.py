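"""Machine-learning side of the hybrid model.

Three base learners — a random forest, gradient boosting with native
categorical handling (both delegated to scikit-learn), and a from-scratch
extreme learning machine (ELM) — combined by a stacked ensemble whose meta
weights are fitted by non-negative least squares on out-of-fold predictions,
so the combiner never sees a base learner's training-set fit.

The ELM is a single-hidden-layer network with frozen random hidden weights
drawn Uniform(-1, 1) on standardized inputs; only the linear read-out is
fitted, in closed form via regularized normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold

from .features import encode_numeric

__all__ = [
    "ELMModel",
    "BaseLearnerSpec",
    "TrainedLearner",
    "StackedEnsemble",
    "elm_train",
    "elm_predict",
    "default_specs",
    "train_base_learners",
    "stack_fit",
    "stack_predict",
]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
}


@dataclass
class ELMModel:
    input_weights: np.ndarray  # (hidden, n_features)
    biases: np.ndarray  # (hidden,)
    output_weights: np.ndarray  # (hidden + 1,), intercept last
    activation: str
    ridge_lambda: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    seed: int


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0  # constant columns pass through unscaled
    return means, sds


def _hidden(model_like, Z: np.ndarray) -> np.ndarray:
    act = _ACTIVATIONS[model_like.activation]
    return act(Z @ model_like.input_weights.T + model_like.biases)


def elm_train(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int = 100,
    activation: str = "sigmoid",
    ridge_lambda: float = 1e-3,
    seed: int = 0,
) -> ELMModel:
    """Fit an ELM read-out in closed form.

    Solves argmin ||H beta - y||^2 + lambda ||beta||^2 over the hidden
    activations H (with an unpenalized intercept column handled by
    centering), deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    if hidden < 1:
        raise ValueError("hidden must be >= 1")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")

    rng = np.random.default_rng(seed)
    means, sds = _standardize_fit(X)
    Z = (X - means) / sds
    W = rng.uniform(-1.0, 1.0, size=(hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=hidden)

    model = ELMModel(W, b, np.empty(hidden + 1), activation, ridge_lambda, means, sds, seed)
    H = _hidden(model, Z)
    # unpenalized intercept via centering
    h_mean = H.mean(axis=0)
    y_mean = y.mean()
    Hc, yc = H - h_mean, y - y_mean
    A = Hc.T @ Hc + ridge_lambda * np.eye(hidden)
    beta = np.linalg.solve(A, Hc.T @ yc)
    intercept = y_mean - h_mean @ beta
    model.output_weights = np.concatenate([beta, [intercept]])
    return model


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_weights.shape[1]:
        raise ValueError(
            f"expected {model.input_weights.shape[1]} features, got {X.shape}"
        )
    Z = (X - model.feature_means) / model.feature_sds
    H = _hidden(model, Z)
    return H @ model.output_weights[:-1] + model.output_weights[-1]


@dataclass(frozen=True)
class BaseLearnerSpec:
    kind: str  # random_forest | gradient_boosting_categorical | elm
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "gradient_boosting_categorical", "elm"):
            raise ValueError(f"unknown learner kind {self.kind!r}")


def default_specs(seed: int = 0, n_trees: int = 300) -> list[BaseLearnerSpec]:
    """The three selected base learners with seeded default hyperparameters."""
    return [
        BaseLearnerSpec("random_forest", {"n_estimators": n_trees}, seed),
        BaseLearnerSpec("gradient_boosting_categorical", {}, seed + 1),
        BaseLearnerSpec("elm", {"hidden": 100}, seed + 2),
    ]


class TrainedLearner:
    """A fitted base learner exposing ``predict`` on the design frame."""

    def __init__(self, spec: BaseLearnerSpec, impl, encoder):
        self.spec = spec
        self._impl = impl
        self._encode = encoder

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.spec.kind == "elm":
            return elm_predict(self._impl, self._encode(X))
        return np.asarray(self._impl.predict(self._encode(X)), dtype=float)


def _identity(df: pd.DataFrame) -> pd.DataFrame:
    return df


def _fit_one(spec: BaseLearnerSpec, X: pd.DataFrame, y: np.ndarray) -> TrainedLearner:
    hp = dict(spec.hyperparameters)
    if spec.kind == "random_forest":
        impl = RandomForestRegressor(
            n_estimators=hp.pop("n_estimators", 300),
            random_state=spec.seed,
            n_jobs=1,
            **hp,
        )
        impl.fit(encode_numeric(X), y)
        return TrainedLearner(spec, impl, encode_numeric)
    if spec.kind == "gradient_boosting_categorical":
        cats = [c for c in ("treatment", "location") if c in X.columns]
        impl = HistGradientBoostingRegressor(
            random_state=spec.seed, categorical_features=cats or None, **hp
        )
        impl.fit(X, y)
        return TrainedLearner(spec, impl, _identity)
    # elm
    impl = elm_train(
        encode_numeric(X),
        y,
        hidden=hp.get("hidden", 100),
        activation=hp.get("activation", "sigmoid"),
        ridge_lambda=hp.get("ridge_lambda", 1e-3),
        seed=spec.seed,
    )
    return TrainedLearner(spec, impl, encode_numeric)


def train_base_learners(
    X: pd.DataFrame, y: np.ndarray, specs: list[BaseLearnerSpec]
) -> list[TrainedLearner]:
    if not specs:
        raise ValueError("specs must be non-empty")
    y = np.asarray(y, dtype=float)
    return [_fit_one(spec, X, y) for spec in specs]


@dataclass
class StackedEnsemble:
    base_models: list[TrainedLearner]
    meta_weights: np.ndarray  # one non-negative weight per base model
    intercept: float
    oof_folds: int
    oof_predictions: np.ndarray = field(default=None, repr=False)  # (n, n_models)
    oof_mse: np.ndarray = field(default=None, repr=False)  # per base model
    oof_stack_mse: float = np.nan


def stack_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    specs: list[BaseLearnerSpec],
    oof_folds: int = 5,
    seed: int = 0,
) -> StackedEnsemble:
    """Fit the stacked ensemble without leakage.

    Each base learner's out-of-fold predictions form the meta-matrix; the
    meta weights are non-negative least squares of (centered) y on the
    centered meta-matrix, with a free intercept.  Base models are then
    refit on all data.
    """
    if oof_folds < 2:
        raise ValueError("oof_folds must be >= 2")
    y = np.asarray(y, dtype=float)
    n = len(y)
    kf = KFold(n_splits=oof_folds, shuffle=True, random_state=seed)
    M = np.empty((n, len(specs)))
    for tr, te in kf.split(np.arange(n)):
        fold_models = train_base_learners(X.iloc[tr], y[tr], specs)
        for j, model in enumerate(fold_models):
            M[te, j] = model.predict(X.iloc[te])

    m_mean = M.mean(axis=0)
    y_mean = y.mean()
    w, _ = nnls(M - m_mean, y - y_mean)
    intercept = float(y_mean - m_mean @ w)

    base_models = train_base_learners(X, y, specs)
    oof_mse = ((M - y[:, None]) ** 2).mean(axis=0)
    stack_oof = M @ w + intercept
    return StackedEnsemble(
        base_models=base_models,
        meta_weights=w,
        intercept=intercept,
        oof_folds=oof_folds,
        oof_predictions=M,
        oof_mse=oof_mse,
        oof_stack_mse=float(np.mean((stack_oof - y) ** 2)),
    )


def stack_predict(model: StackedEnsemble, X: pd.DataFrame) -> np.ndarray:
    preds = np.column_stack([m.predict(X) for m in model.base_models])
    return preds @ model.meta_weights + model.intercept
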
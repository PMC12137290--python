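"""ELM closed form vs ridge oracle, base-learner training, NNLS stacking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

from fohem.features import FeatureMask, apply_features, encode_numeric
from fohem.learners import (
    BaseLearnerSpec,
    elm_predict,
    elm_train,
    default_specs,
    stack_fit,
    stack_predict,
    train_base_learners,
    _hidden,
)
from fohem.synthetic import default_config, generate


@pytest.fixture(scope="module")
def design(dataset225):
    X = apply_features(dataset225, FeatureMask.full(dataset225.feature_names), [])
    return X, dataset225.y


def test_elm_constant_target_absorbed_by_intercept():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 4))
    y = np.full(30, 3.7)
    model = elm_train(X, y, hidden=20, seed=1)
    np.testing.assert_allclose(elm_predict(model, X), y, atol=1e-8)


def test_elm_interpolation_regime():
    rng = np.random.default_rng(2)
    X = rng.uniform(-1, 1, size=(50, 3))
    y = np.sin(X[:, 0]) + X[:, 1] ** 2 - 0.5 * X[:, 2]
    model = elm_train(X, y, hidden=200, ridge_lambda=1e-8, seed=3)
    mse = float(np.mean((elm_predict(model, X) - y) ** 2))
    assert mse < 1e-6


def test_elm_matches_generic_ridge_oracle():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(80, 5))
    y = X @ rng.normal(size=5) + rng.normal(scale=0.1, size=80)
    lam = 0.37
    model = elm_train(X, y, hidden=40, ridge_lambda=lam, seed=5)
    Z = (X - model.feature_means) / model.feature_sds
    H = _hidden(model, Z)
    oracle = Ridge(alpha=lam, fit_intercept=True, solver="cholesky").fit(H, y)
    np.testing.assert_allclose(model.output_weights[:-1], oracle.coef_, atol=1e-8)
    assert model.output_weights[-1] == pytest.approx(oracle.intercept_, abs=1e-8)


def test_elm_determinism_and_prediction_contracts():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(40, 3))
    y = X.sum(axis=1)
    m1 = elm_train(X, y, hidden=30, seed=7)
    m2 = elm_train(X, y, hidden=30, seed=7)
    np.testing.assert_array_equal(m1.output_weights, m2.output_weights)
    batch = elm_predict(m1, X)
    rows = np.array([elm_predict(m1, X[i : i + 1])[0] for i in range(len(X))])
    np.testing.assert_allclose(batch, rows, atol=1e-12)
    perm = np.random.default_rng(8).permutation(len(X))
    np.testing.assert_allclose(elm_predict(m1, X[perm]), batch[perm], atol=1e-12)
    with pytest.raises(ValueError):
        elm_predict(m1, X[:, :2])
    with pytest.raises(ValueError):
        elm_train(X * np.nan, y)


def test_train_base_learners_contracts(design):
    X, y = design
    models = train_base_learners(X, y, default_specs(seed=0, n_trees=100))
    assert len(models) == 3
    for m in models:
        pred = m.predict(X)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.9, m.spec.kind
    again = train_base_learners(X, y, default_specs(seed=0, n_trees=100))
    for m1, m2 in zip(models, again):
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
    with pytest.raises(ValueError):
        BaseLearnerSpec("mystery_model")
    with pytest.raises(ValueError):
        train_base_learners(X, y, [])


def test_stack_perfect_base_learner_dominates(design, monkeypatch):
    # inject one oracle learner (predicts the target exactly) and one biased
    # learner; the NNLS combiner must hand all weight to the oracle
    X, _ = design
    y = 0.5 * X["total_biomass"].to_numpy() + 2.0

    class Fake:
        def __init__(self, offset):
            self.offset = offset

        def predict(self, Xq):
            return 0.5 * Xq["total_biomass"].to_numpy() + 2.0 + self.offset * np.sin(
                Xq["total_biomass"].to_numpy()
            )

    import fohem.learners as learners_mod

    monkeypatch.setattr(
        learners_mod,
        "train_base_learners",
        lambda Xq, yq, specs: [Fake(0.0), Fake(1.5)],
    )
    specs = default_specs(seed=0)[:2]
    ens = stack_fit(X, y, specs, oof_folds=5, seed=2)
    assert np.all(ens.meta_weights >= 0)
    assert ens.meta_weights[0] == pytest.approx(1.0, abs=1e-6)
    np.testing.assert_allclose(stack_predict(ens, X), y, atol=1e-6)


def test_stack_oof_mse_never_catastrophic(design):
    X, y = design
    ens = stack_fit(X, y, default_specs(seed=3, n_trees=100), oof_folds=5, seed=4)
    assert ens.oof_stack_mse <= 1.05 * ens.oof_mse.min()
    assert np.all(ens.meta_weights >= 0)


def test_stack_predict_deterministic(design):
    X, y = design
    e1 = stack_fit(X, y, default_specs(seed=5, n_trees=60), oof_folds=3, seed=6)
    e2 = stack_fit(X, y, default_specs(seed=5, n_trees=60), oof_folds=3, seed=6)
    np.testing.assert_array_equal(stack_predict(e1, X), stack_predict(e2, X))
    with pytest.raises(ValueError):
        stack_fit(X, y, default_specs(), oof_folds=1, seed=0)


def test_encode_numeric_keeps_all_category_levels(dataset225):
    sub = dataset225.subset(np.flatnonzero(dataset225.df["treatment"] == "SS")[:10])
    X = apply_features(sub, FeatureMask.full(sub.feature_names), [])
    full = apply_features(dataset225, FeatureMask.full(dataset225.feature_names), [])
    assert encode_numeric(X).shape[1] == encode_numeric(full).shape[1]
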
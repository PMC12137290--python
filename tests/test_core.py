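"""Blend-weight optimization, the full pipeline, and bundle round trips."""

import numpy as np
import pandas as pd
import pytest

from fohem.core import (
    GLOBAL_KEY,
    FOHEMConfig,
    WeightSet,
    closed_form_blend_weight,
    fohem_fit,
    fohem_predict,
    load_bundle,
    optimize_weights,
    save_bundle,
    weighted_combine,
)
from fohem.ga import GAConfig
from fohem.synthetic import default_config, generate


def _weight_ga(seed=0):
    return GAConfig(seed=seed, patience=20)


def test_weighted_combine_two_components_is_the_blend():
    rng = np.random.default_rng(0)
    y_fis, y_ens = rng.normal(size=(2, 30))
    w = 0.37
    blended = weighted_combine(np.vstack([y_fis, y_ens]), np.array([w, 1 - w]))
    np.testing.assert_allclose(blended, w * y_fis + (1 - w) * y_ens, atol=1e-15)


def test_weightset_simplex_invariant():
    with pytest.raises(ValueError):
        WeightSet("global", {GLOBAL_KEY: (0.6, 0.6)})
    with pytest.raises(ValueError):
        WeightSet("global", {GLOBAL_KEY: (-0.1, 1.1)})
    with pytest.raises(ValueError):
        WeightSet("global", {"SS/Khairpur": (0.5, 0.5)})  # no global fallback
    ws = WeightSet("global", {GLOBAL_KEY: (0.3, 0.7)})
    assert ws.for_group("anything") == (0.3, 0.7)


def test_closed_form_weight_is_the_quadratic_optimum():
    rng = np.random.default_rng(1)
    for _ in range(50):
        y = rng.normal(size=40)
        y_fis = rng.normal(size=40)
        y_ens = rng.normal(size=40)
        w_star = closed_form_blend_weight(y, y_fis, y_ens)
        grid = np.linspace(0, 1, 2001)
        mses = [np.mean((w * y_fis + (1 - w) * y_ens - y) ** 2) for w in grid]
        assert abs(w_star - grid[int(np.argmin(mses))]) <= 1e-3


def test_ga_weight_matches_closed_form():
    rng = np.random.default_rng(2)
    for seed in range(3):
        y = rng.normal(loc=8, size=60)
        y_fis = y + rng.normal(scale=0.5, size=60)
        y_ens = y + rng.normal(scale=0.3, size=60)
        groups = np.array(["SS/Khairpur"] * 60)
        ws = optimize_weights(y, y_fis, y_ens, groups, _weight_ga(seed), mode="global")
        w_star = closed_form_blend_weight(y, y_fis, y_ens)
        assert abs(ws.weights[GLOBAL_KEY][0] - w_star) <= 0.02


def test_perfect_fis_takes_all_weight():
    rng = np.random.default_rng(3)
    y = rng.normal(loc=8, size=80)
    y_ens = y + rng.normal(scale=1.0, size=80)
    groups = np.where(np.arange(80) < 40, "SM/Khairpur", "SS/Bahawalpur")
    ws = optimize_weights(y, y, y_ens, groups, _weight_ga(4), mode="per_group")
    for key, (w_fis, _) in ws.weights.items():
        assert w_fis >= 0.95, key


def test_identical_components_keep_simplex():
    y = np.arange(10.0)
    preds = y + 0.5
    ws = optimize_weights(y, preds, preds, ["SS/Khairpur"] * 10, _weight_ga(5))
    w_fis, w_ens = ws.weights[GLOBAL_KEY]
    assert w_fis >= 0 and w_ens >= 0
    assert w_fis + w_ens == pytest.approx(1.0, abs=1e-9)


def test_small_group_merged_with_warning():
    rng = np.random.default_rng(6)
    y = rng.normal(size=21)
    groups = np.array(["SS/Khairpur"] * 20 + ["SM/Khairpur"])
    with pytest.warns(UserWarning, match="merged into global"):
        ws = optimize_weights(
            y, y + 0.1, y - 0.1, groups, _weight_ga(7), mode="per_group"
        )
    assert "SM/Khairpur" not in ws.weights
    assert GLOBAL_KEY in ws.weights


def test_planted_blend_weight_recovery():
    # y is exactly 0.7*y_fis + 0.3*y_ens plus small noise; the recovered
    # global weight must sit near the planted value across seeds
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        y_fis = rng.normal(loc=8, scale=1.0, size=120)
        y_ens = rng.normal(loc=7, scale=1.0, size=120)
        y = 0.7 * y_fis + 0.3 * y_ens + rng.normal(scale=0.05, size=120)
        ws = optimize_weights(
            y, y_fis, y_ens, ["SM/Khairpur"] * 120, _weight_ga(seed), mode="global"
        )
        assert abs(ws.weights[GLOBAL_KEY][0] - 0.7) <= 0.05


def test_blend_validation_mse_dominates_both_endpoints():
    rng = np.random.default_rng(8)
    y = rng.normal(loc=8, size=60)
    y_fis = y + rng.normal(scale=0.6, size=60)
    y_ens = y + rng.normal(scale=0.4, size=60)
    w_star = closed_form_blend_weight(y, y_fis, y_ens)
    blend = w_star * y_fis + (1 - w_star) * y_ens
    mse = np.mean((blend - y) ** 2)
    assert mse <= np.mean((y_fis - y) ** 2) + 1e-9
    assert mse <= np.mean((y_ens - y) ** 2) + 1e-9


def test_fohem_predict_endpoints_and_midpoint(fitted_model, dataset225):
    sub = dataset225.subset(range(24))
    y_fis, y_ens = fitted_model.component_predictions(sub)
    model = fitted_model

    def with_weight(w):
        model.weights = WeightSet("global", {GLOBAL_KEY: (w, 1.0 - w)})
        return fohem_predict(model, sub)

    original = model.weights
    try:
        np.testing.assert_allclose(with_weight(1.0), y_fis, atol=1e-12)
        np.testing.assert_allclose(with_weight(0.0), y_ens, atol=1e-12)
        np.testing.assert_allclose(
            with_weight(0.5), 0.5 * y_fis + 0.5 * y_ens, atol=1e-12
        )
    finally:
        model.weights = original


def test_fohem_fit_rejects_tiny_datasets():
    tiny = generate(default_config(seed=1, n_records=20))
    with pytest.raises(ValueError, match="40"):
        fohem_fit(tiny, FOHEMConfig(seed=0))


def test_fohem_fit_deterministic(fast_config, dataset225):
    small = dataset225.subset(range(120))
    m1 = fohem_fit(small, fast_config)
    m2 = fohem_fit(small, fast_config)
    pd.testing.assert_frame_equal(m1.weights.to_frame(), m2.weights.to_frame())
    np.testing.assert_array_equal(m1.predict(small), m2.predict(small))
    assert m1.provenance["fis_features"] == m2.provenance["fis_features"]


def test_bundle_round_trip(tmp_path, fitted_model, dataset225):
    save_bundle(fitted_model, tmp_path / "bundle")
    assert (tmp_path / "bundle" / "manifest.json").exists()
    assert (tmp_path / "bundle" / "weights.csv").exists()
    assert (tmp_path / "bundle" / "fis.yaml").exists()
    back = load_bundle(tmp_path / "bundle")
    sub = dataset225.subset(range(30))
    np.testing.assert_allclose(
        back.predict(sub), fitted_model.predict(sub), atol=1e-12
    )


def test_stage_errors_are_prefixed(dataset225):
    bad = FOHEMConfig(seed=0, evaluator="tree", val_fraction=0.999)
    with pytest.raises(Exception, match="split|feature_selection"):
        fohem_fit(dataset225, bad)
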
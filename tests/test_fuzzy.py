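"""Mamdani engine: MF shapes, rule firing, centroid defuzzification, the
expert yield rule base, and cross-checks against the dense-grid oracle."""

import numpy as np
import pytest

from conftest import oracle_infer, random_rulebase

from fohem.fuzzy import (
    FuzzyRule,
    FuzzyRuleBase,
    FuzzySet,
    FuzzyVariable,
    NoRuleFiredError,
    TriangularMF,
    build_default_yield_fis,
    classify_yield,
    fis_predict,
    infer,
    load_rulebase,
    mf_eval,
    rule_strength,
    save_rulebase,
)
from fohem.synthetic import FeatureSpec, default_config, default_schema, generate


def test_triangle_point_values():
    mf = TriangularMF(0.0, 5.0, 10.0)
    assert mf_eval(mf, 5.0) == 1.0
    assert mf_eval(mf, 2.5) == 0.5
    assert mf_eval(mf, 12.0) == 0.0
    assert mf_eval(mf, -1.0) == 0.0


def test_triangle_random_exactness():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        a = float(rng.uniform(-10, 10))
        b = a + float(rng.uniform(0.1, 5))
        c = b + float(rng.uniform(0.1, 5))
        mf = TriangularMF(a, b, c)
        assert mf_eval(mf, b) == 1.0
        assert mf_eval(mf, a) == 0.0
        assert mf_eval(mf, c) == 0.0
        assert mf_eval(mf, (a + b) / 2) == pytest.approx(0.5)
        xs = rng.uniform(a - 2, c + 2, size=20)
        mus = mf_eval(mf, xs)
        assert np.all((mus >= 0) & (mus <= 1))


def test_shoulders_and_degenerate_segments():
    left = TriangularMF(0.0, 0.0, 5.0, left_shoulder=True)
    assert mf_eval(left, -100.0) == 1.0
    assert mf_eval(left, 2.5) == 0.5
    right = TriangularMF(5.0, 10.0, 10.0, right_shoulder=True)
    assert mf_eval(right, 100.0) == 1.0
    spike = TriangularMF(3.0, 3.0, 3.0)
    assert mf_eval(spike, 3.0) == 1.0
    assert mf_eval(spike, 3.1) == 0.0


def _two_var_base(and_op="min"):
    v1 = FuzzyVariable(
        "x1", (0.0, 10.0), (FuzzySet("s", TriangularMF(0.0, 5.0, 10.0)),)
    )
    v2 = FuzzyVariable(
        "x2", (0.0, 10.0), (FuzzySet("s", TriangularMF(0.0, 5.0, 10.0)),)
    )
    out = FuzzyVariable(
        "y", (0.0, 10.0), (FuzzySet("o", TriangularMF(7.5, 8.25, 9.0)),)
    )
    rule = FuzzyRule({"x1": "s", "x2": "s"}, "o")
    return FuzzyRuleBase([v1, v2], out, [rule], and_operator=and_op)


def test_rule_strength_min_product_and_single():
    base = _two_var_base("min")
    # memberships: x1=4 -> 0.8, x2=1.5 -> 0.3
    inputs = {"x1": 4.0, "x2": 1.5}
    assert rule_strength(base.rules[0], inputs, base) == pytest.approx(0.3)
    prod = _two_var_base("product")
    assert rule_strength(prod.rules[0], inputs, prod) == pytest.approx(0.24)
    single = FuzzyRule({"x1": "s"}, "o")
    assert rule_strength(single, {"x1": 3.5}, base) == pytest.approx(0.7)
    with pytest.raises(KeyError, match="x2"):
        rule_strength(base.rules[0], {"x1": 4.0}, base)


def test_infer_symmetric_consequents():
    base = _two_var_base()
    crisp, _ = infer(base, {"x1": 5.0, "x2": 5.0})  # fires at strength 1
    assert crisp == pytest.approx(8.25, abs=1e-3)

    out = FuzzyVariable(
        "y",
        (0.0, 10.0),
        (
            FuzzySet("lo", TriangularMF(6.0, 7.0, 8.0)),
            FuzzySet("hi", TriangularMF(8.0, 9.0, 10.0)),
        ),
    )
    v = FuzzyVariable("x1", (0.0, 10.0), (FuzzySet("s", TriangularMF(0.0, 5.0, 10.0)),))
    rules = [FuzzyRule({"x1": "s"}, "lo"), FuzzyRule({"x1": "s"}, "hi")]
    sym = FuzzyRuleBase([v], out, rules)
    crisp, _ = infer(sym, {"x1": 4.0})
    assert crisp == pytest.approx(8.0, abs=1e-3)


def test_infer_no_rule_fired():
    base = _two_var_base()
    with pytest.raises(NoRuleFiredError):
        infer(base, {"x1": 10.0, "x2": 10.0})  # zero membership at the feet


def test_infer_matches_dense_grid_oracle():
    rng = np.random.default_rng(123)
    checked = 0
    while checked < 100:
        base, inputs = random_rulebase(rng)
        try:
            expected = oracle_infer(base, inputs, n_grid=10_000)
        except RuntimeError:
            continue
        crisp, _ = infer(base, inputs)
        span = base.output_var.universe[1] - base.output_var.universe[0]
        assert abs(crisp - expected) <= 1e-3 * span
        checked += 1


def test_resolution_stability():
    rng = np.random.default_rng(5)
    for _ in range(20):
        base, inputs = random_rulebase(rng)
        try:
            c1, _ = infer(base, inputs)
        except NoRuleFiredError:
            continue
        base2 = FuzzyRuleBase(
            base.input_vars, base.output_var, base.rules, base.and_operator,
            resolution=base.resolution * 2,
        )
        c2, _ = infer(base2, inputs)
        span = base.output_var.universe[1] - base.output_var.universe[0]
        assert abs(c1 - c2) < 0.005 * span


def _spec(name):
    return {s.name: s for s in default_schema()}[name]


def test_default_fis_grid_and_categories():
    base = build_default_yield_fis([_spec("total_biomass"), _spec("M_residue_biomass")])
    assert len(base.rules) == 9
    medium = base.output_var.set("medium").mf
    assert (medium.a, medium.c) == (7.5, 9.0)
    # all-high inputs land in the high-yield support
    crisp, _ = infer(base, {"total_biomass": 20.0, "M_residue_biomass": 10000.0})
    assert crisp >= 9.0
    # all-low inputs land in the low-yield support
    crisp_lo, _ = infer(base, {"total_biomass": 0.0, "M_residue_biomass": 0.0})
    assert crisp_lo < 7.5
    with pytest.raises(ValueError):
        build_default_yield_fis([])


def test_worked_example_crisp_83_is_medium():
    assert classify_yield(8.3) == "medium"
    assert classify_yield(7.0) == "low"
    assert classify_yield(9.6) == "high"


def test_fis_predict_contracts(dataset225):
    base = build_default_yield_fis(
        [_spec("total_biomass"), _spec("M_residue_biomass"), _spec("transpiration")]
    )
    one = dataset225.subset([3] * 5)
    preds = fis_predict(base, one)
    assert np.all(preds == preds[0])
    batch = fis_predict(base, dataset225.subset(range(40)))
    lo, hi = base.output_var.universe
    assert np.all((batch >= lo) & (batch <= hi))
    # batch path agrees with the single-record reference path
    for i in range(10):
        row = dataset225.df.iloc[i]
        crisp, _ = infer(base, {v.name: row[v.name] for v in base.input_vars})
        assert batch[i] == pytest.approx(crisp, abs=1e-12)
    with pytest.raises(KeyError):
        fis_predict(
            base,
            generate(default_config(seed=1, n_records=8, features=(
                FeatureSpec("other", "soil", 0.0, 1.0, 0.0, noise_only=True),
            ))),
        )


def test_fis_predict_midpoint_fallback_warns():
    v = FuzzyVariable("LAI", (0.0, 7.0), (FuzzySet("s", TriangularMF(0.0, 0.5, 1.0)),))
    out = FuzzyVariable("yield", (0.0, 10.0), (FuzzySet("o", TriangularMF(4.0, 5.0, 6.0)),))
    base = FuzzyRuleBase([v], out, [FuzzyRule({"LAI": "s"}, "o")])
    data = generate(default_config(seed=2, n_records=16))
    with pytest.warns(UserWarning, match="no rule"):
        preds = fis_predict(base, data)
    misses = data.df["LAI"].to_numpy() > 1.0
    assert np.all(preds[misses] == 5.0)


def test_rulebase_yaml_round_trip(tmp_path):
    base = build_default_yield_fis([_spec("total_biomass"), _spec("M_residue_biomass")])
    path = tmp_path / "fis.yaml"
    save_rulebase(base, path)
    back = load_rulebase(path)
    assert back.and_operator == base.and_operator
    assert len(back.rules) == len(base.rules)
    for x, r in ((12.0, 5000.0), (3.0, 9000.0)):
        a, _ = infer(base, {"total_biomass": x, "M_residue_biomass": r})
        b, _ = infer(back, {"total_biomass": x, "M_residue_biomass": r})
        assert a == b
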
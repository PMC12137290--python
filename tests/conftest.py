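"""Shared fixtures: datasets, a fast pipeline config, and an independent
dense-grid Mamdani oracle used to cross-check the fuzzy engine."""

from __future__ import annotations

import numpy as np
import pytest

from fohem.core import FOHEMConfig, fohem_fit
from fohem.fuzzy import (
    FuzzyRule,
    FuzzyRuleBase,
    FuzzySet,
    FuzzyVariable,
    TriangularMF,
)
from fohem.ga import GAConfig
from fohem.synthetic import FeatureSpec, default_config, generate


@pytest.fixture(scope="session")
def dataset225():
    """The default 225-record synthetic intercropping dataset."""
    return generate(default_config(seed=42))


@pytest.fixture(scope="session")
def fast_config():
    """Desk-scale pipeline config: ridge feature fitness, smaller forests."""
    return FOHEMConfig(
        seed=7,
        evaluator="ridge",
        n_trees=80,
        feature_ga=GAConfig(population_size=20, max_generations=12, patience=5, seed=8),
    )


@pytest.fixture(scope="session")
def fitted_model(dataset225, fast_config):
    return fohem_fit(dataset225, fast_config)


# ---------------------------------------------------------------------------
# independent Mamdani oracle: scalar loops on a dense grid, no shared code
# with fohem.fuzzy beyond the dataclass fields it reads


def oracle_mf(a, b, c, left_shoulder, right_shoulder, x):
    if left_shoulder and x <= b:
        return 1.0
    if right_shoulder and x >= b:
        return 1.0
    if x == b:
        return 1.0
    if a <= x < b:
        return (x - a) / (b - a)
    if b < x <= c and c > b:
        return (c - x) / (c - b)
    return 0.0


def oracle_infer(base: FuzzyRuleBase, inputs: dict, n_grid: int = 10_000) -> float:
    """Brute-force centroid defuzzification on an n_grid-point universe."""
    lo, hi = base.output_var.universe
    xs = [lo + (hi - lo) * i / (n_grid - 1) for i in range(n_grid)]
    num = den = 0.0
    curves = []
    for rule in base.rules:
        degs = []
        for name, label in rule.antecedents.items():
            mf = base.variable(name).set(label).mf
            degs.append(
                oracle_mf(mf.a, mf.b, mf.c, mf.left_shoulder, mf.right_shoulder, inputs[name])
            )
        strength = min(degs) if base.and_operator == "min" else float(np.prod(degs))
        out_mf = base.output_var.set(rule.consequent).mf
        curves.append((strength, out_mf))
    fired = False
    for x in xs:
        mu = 0.0
        for strength, mf in curves:
            if strength <= 0:
                continue
            fired = True
            mu = max(
                mu,
                min(
                    strength,
                    oracle_mf(mf.a, mf.b, mf.c, mf.left_shoulder, mf.right_shoulder, x),
                ),
            )
        num += x * mu
        den += mu
    if not fired or den == 0.0:
        raise RuntimeError("no rule fired")
    return num / den


def random_rulebase(rng: np.random.Generator) -> tuple[FuzzyRuleBase, dict]:
    """A random 2-3 input rule base and an input point that fires >= 1 rule."""
    n_in = int(rng.integers(2, 4))
    input_vars = []
    for i in range(n_in):
        lo = float(rng.uniform(-5, 0))
        hi = lo + float(rng.uniform(5, 20))
        span = hi - lo
        cuts = np.sort(rng.uniform(0.2, 0.8, size=2)) * span + lo
        sets = (
            FuzzySet("low", TriangularMF(lo, lo, float(cuts[1]), left_shoulder=True)),
            FuzzySet("medium", TriangularMF(lo, float(cuts[0]), hi)),
            FuzzySet("high", TriangularMF(float(cuts[0]), hi, hi, right_shoulder=True)),
        )
        input_vars.append(FuzzyVariable(f"v{i}", (lo, hi), sets))
    out_lo, out_hi = 0.0, float(rng.uniform(5, 15))
    mid = rng.uniform(0.3, 0.7) * out_hi
    output = FuzzyVariable(
        "out",
        (out_lo, out_hi),
        (
            FuzzySet("low", TriangularMF(0.0, 0.0, mid, left_shoulder=True)),
            FuzzySet("medium", TriangularMF(0.0, mid, out_hi)),
            FuzzySet("high", TriangularMF(mid, out_hi, out_hi, right_shoulder=True)),
        ),
    )
    labels = ("low", "medium", "high")
    rules = []
    for _ in range(int(rng.integers(3, 8))):
        ante = {v.name: labels[rng.integers(0, 3)] for v in input_vars}
        rules.append(FuzzyRule(ante, labels[rng.integers(0, 3)]))
    op = "min" if rng.uniform() < 0.7 else "product"
    base = FuzzyRuleBase(input_vars, output, rules, and_operator=op)
    inputs = {v.name: float(rng.uniform(*v.universe)) for v in input_vars}
    return base, inputs


def planted_schema(n_informative: int = 5, n_noise: int = 15) -> list[FeatureSpec]:
    """Schema with a known answer: informative features carry descending
    effects, the rest are pure noise."""
    effects = [0.9, 0.7, 0.6, 0.5, 0.4][:n_informative]
    feats = [
        FeatureSpec(f"info_{i}", "soil", 0.0, 10.0, effects[i])
        for i in range(n_informative)
    ]
    feats += [
        FeatureSpec(f"noise_{i}", "soil", 0.0, 10.0, 0.0, noise_only=True)
        for i in range(n_noise)
    ]
    return feats
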
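"""Mamdani fuzzy inference with triangular membership functions.

A rule base maps crisp inputs through low/medium/high fuzzy sets: rule
antecedents are AND-combined (min by default, product selectable), each
consequent set is clipped at its rule's firing strength (Mamdani implication),
the clipped shapes are aggregated by pointwise max over a discretized output
universe, and the aggregate is defuzzified by its centroid.

The membership function is the triangle

    mu(x) = (x - a)/(b - a)  on [a, b),   (c - x)/(c - b)  on [b, c],   0 outside,

optionally shouldered so a boundary set saturates at 1 beyond its peak.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .synthetic import Dataset, FeatureSpec

logger = logging.getLogger(__name__)

__all__ = [
    "TriangularMF",
    "FuzzySet",
    "FuzzyVariable",
    "FuzzyRule",
    "FuzzyRuleBase",
    "NoRuleFiredError",
    "mf_eval",
    "rule_strength",
    "infer",
    "build_default_yield_fis",
    "fis_predict",
    "classify_yield",
    "save_rulebase",
    "load_rulebase",
]


class NoRuleFiredError(RuntimeError):
    """Every rule fired with strength exactly zero for the given inputs."""


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership function with feet ``a``, ``c`` and peak ``b``.

    ``left_shoulder`` keeps membership at 1 for x <= b (the set saturates
    leftward); ``right_shoulder`` likewise for x >= b.
    """

    a: float
    b: float
    c: float
    left_shoulder: bool = False
    right_shoulder: bool = False

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError(f"require a <= b <= c, got ({self.a}, {self.b}, {self.c})")

    def __call__(self, x) -> np.ndarray | float:
        return mf_eval(self, x)


def mf_eval(mf: TriangularMF, x) -> np.ndarray | float:
    """Evaluate a triangular MF; total on all of R, vectorized over ``x``."""
    scalar = np.ndim(x) == 0
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    mu = np.zeros_like(x_arr)
    a, b, c = mf.a, mf.b, mf.c
    if b > a:
        rising = (x_arr >= a) & (x_arr < b)
        mu[rising] = (x_arr[rising] - a) / (b - a)
    if c > b:
        falling = (x_arr >= b) & (x_arr <= c)
        mu[falling] = (c - x_arr[falling]) / (c - b)
    mu[x_arr == b] = 1.0  # covers degenerate a == b or b == c segments
    if mf.left_shoulder:
        mu[x_arr <= b] = 1.0
    if mf.right_shoulder:
        mu[x_arr >= b] = 1.0
    return float(mu[0]) if scalar else mu


@dataclass(frozen=True)
class FuzzySet:
    label: str
    mf: TriangularMF


@dataclass(frozen=True)
class FuzzyVariable:
    name: str
    universe: tuple[float, float]
    sets: tuple[FuzzySet, ...]

    def __post_init__(self) -> None:
        if len(self.sets) < 1:
            raise ValueError(f"variable {self.name!r} needs at least one fuzzy set")
        labels = [s.label for s in self.sets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"variable {self.name!r}: duplicate set labels")

    def set(self, label: str) -> FuzzySet:
        for s in self.sets:
            if s.label == label:
                return s
        raise KeyError(f"variable {self.name!r} has no set {label!r}")


@dataclass(frozen=True)
class FuzzyRule:
    """IF <var1> is <label1> AND <var2> is <label2> ... THEN yield is <consequent>."""

    antecedents: dict[str, str]
    consequent: str

    def __post_init__(self) -> None:
        if not self.antecedents:
            raise ValueError("rule needs at least one antecedent")


@dataclass
class FuzzyRuleBase:
    input_vars: list[FuzzyVariable]
    output_var: FuzzyVariable
    rules: list[FuzzyRule]
    and_operator: str = "min"  # or "product"
    resolution: int = 1000

    def __post_init__(self) -> None:
        if self.resolution < 100:
            raise ValueError("resolution must be >= 100")
        if self.and_operator not in ("min", "product"):
            raise ValueError("and_operator must be 'min' or 'product'")
        var_names = {v.name for v in self.input_vars}
        out_labels = {s.label for s in self.output_var.sets}
        for rule in self.rules:
            for name, label in rule.antecedents.items():
                if name not in var_names:
                    raise ValueError(f"rule references unknown variable {name!r}")
                self.variable(name).set(label)  # raises on unknown label
            if rule.consequent not in out_labels:
                raise ValueError(f"rule references unknown output set {rule.consequent!r}")

    def variable(self, name: str) -> FuzzyVariable:
        for v in self.input_vars:
            if v.name == name:
                return v
        raise KeyError(f"no input variable {name!r}")


def rule_strength(rule: FuzzyRule, inputs: dict[str, float], base: FuzzyRuleBase) -> float:
    """Firing strength: AND-combination of antecedent membership degrees."""
    degrees = []
    for name, label in rule.antecedents.items():
        if name not in inputs:
            raise KeyError(f"missing input variable {name!r}")
        degrees.append(mf_eval(base.variable(name).set(label).mf, inputs[name]))
    if base.and_operator == "min":
        return float(min(degrees))
    return float(np.prod(degrees))


def infer(base: FuzzyRuleBase, inputs: dict[str, float]) -> tuple[float, np.ndarray]:
    """Run Mamdani inference for one crisp input vector.

    Returns the centroid-defuzzified crisp output and the aggregated
    membership curve sampled at ``base.resolution`` points over the output
    universe.  Raises :class:`NoRuleFiredError` if every rule strength is 0.
    """
    if not base.rules:
        raise ValueError("rule base is empty")
    lo, hi = base.output_var.universe
    grid = np.linspace(lo, hi, base.resolution)
    aggregate = np.zeros_like(grid)
    any_fired = False
    for rule in base.rules:
        strength = rule_strength(rule, inputs, base)
        if strength <= 0.0:
            continue
        any_fired = True
        consequent = base.output_var.set(rule.consequent).mf
        clipped = np.minimum(mf_eval(consequent, grid), strength)
        aggregate = np.maximum(aggregate, clipped)
    if not any_fired:
        raise NoRuleFiredError("no rule fired for the given inputs")
    crisp = float(np.sum(grid * aggregate) / np.sum(aggregate))
    return crisp, aggregate


# ---------------------------------------------------------------------------
# default yield FIS construction

# breakpoints quoted from expert membership design: total biomass in tons,
# maize residue biomass in kg/ha
_KNOWN_BREAKPOINTS: dict[str, dict[str, TriangularMF]] = {
    "total_biomass": {
        "low": TriangularMF(0.0, 0.0, 10.0, left_shoulder=True),
        "medium": TriangularMF(5.0, 12.5, 20.0),
        "high": TriangularMF(15.0, 20.0, 20.0, right_shoulder=True),
    },
    "M_residue_biomass": {
        "low": TriangularMF(0.0, 0.0, 4000.0, left_shoulder=True),
        "medium": TriangularMF(2000.0, 5000.0, 8000.0),
        "high": TriangularMF(6000.0, 10000.0, 10000.0, right_shoulder=True),
    },
}

_KNOWN_UNIVERSES = {"total_biomass": (0.0, 20.0), "M_residue_biomass": (0.0, 10000.0)}

YIELD_UNIVERSE = (0.0, 10.0)

#: yield categories: low below 7.5 t/ha, medium 7.5-9, high 9-10
YIELD_SETS = (
    FuzzySet("low", TriangularMF(0.0, 0.0, 7.5, left_shoulder=True)),
    FuzzySet("medium", TriangularMF(7.5, 8.25, 9.0)),
    FuzzySet("high", TriangularMF(9.0, 10.0, 10.0, right_shoulder=True)),
)

_LEVELS = ("low", "medium", "high")


def _tertile_sets(low: float, high: float) -> dict[str, TriangularMF]:
    """Three overlapping sets over [low, high]: shoulders at the ends, a
    centered triangle in the middle — tertile-style breakpoints."""
    span = high - low
    return {
        "low": TriangularMF(low, low, low + span / 2, left_shoulder=True),
        "medium": TriangularMF(low + span / 6, low + span / 2, high - span / 6),
        "high": TriangularMF(low + span / 2, high, high, right_shoulder=True),
    }


def build_default_yield_fis(selected_features: list[FeatureSpec]) -> FuzzyRuleBase:
    """Expert-grid FIS over 2-4 selected features.

    Each input gets low/medium/high sets — expert breakpoints where known
    (total biomass, maize residue biomass), tertiles of the feature range
    otherwise.  The rule grid maps monotone level combinations to yield
    categories: all-high -> high, all-low -> low, everything mixed -> by the
    rounded mean level.
    """
    if not selected_features:
        raise ValueError("selected_features must be non-empty")
    if not 2 <= len(selected_features) <= 4:
        raise ValueError("build_default_yield_fis expects 2-4 features")

    input_vars = []
    for spec in selected_features:
        mfs = _KNOWN_BREAKPOINTS.get(spec.name) or _tertile_sets(spec.low, spec.high)
        universe = _KNOWN_UNIVERSES.get(spec.name, (spec.low, spec.high))
        input_vars.append(
            FuzzyVariable(
                spec.name,
                universe,
                tuple(FuzzySet(lbl, mfs[lbl]) for lbl in _LEVELS),
            )
        )

    output_var = FuzzyVariable("yield", YIELD_UNIVERSE, YIELD_SETS)

    rules = []
    names = [v.name for v in input_vars]
    combos = np.stack(
        np.meshgrid(*[np.arange(3)] * len(names), indexing="ij"), axis=-1
    ).reshape(-1, len(names))
    for combo in combos:
        # monotone mapping: mean input level, rounded half-up to a category
        level = int(np.floor(np.mean(combo) + 0.5))
        rules.append(
            FuzzyRule(
                antecedents={n: _LEVELS[c] for n, c in zip(names, combo)},
                consequent=_LEVELS[level],
            )
        )
    return FuzzyRuleBase(input_vars, output_var, rules)


def classify_yield(crisp: float, output_var: FuzzyVariable | None = None) -> str:
    """Category of a crisp yield value by argmax set membership."""
    var = output_var or FuzzyVariable("yield", YIELD_UNIVERSE, YIELD_SETS)
    degrees = {s.label: mf_eval(s.mf, crisp) for s in var.sets}
    return max(degrees, key=degrees.get)


def fis_predict(base: FuzzyRuleBase, data: Dataset) -> np.ndarray:
    """One crisp prediction per record; no-rule-fired rows get the output
    universe midpoint with a logged warning (pipelines stay total)."""
    names = [v.name for v in base.input_vars]
    for name in names:
        if name not in data.df.columns:
            raise KeyError(f"missing feature column {name!r}")
    lo, hi = base.output_var.universe
    midpoint = 0.5 * (lo + hi)
    grid = np.linspace(lo, hi, base.resolution)

    # vectorized Mamdani: strengths (n, R), clipped consequents (n, R, res)
    cols = {n: data.df[n].to_numpy(dtype=float) for n in names}
    strengths = np.empty((len(data), len(base.rules)))
    consequents = np.empty((len(base.rules), base.resolution))
    for r, rule in enumerate(base.rules):
        degs = np.stack(
            [
                mf_eval(base.variable(n).set(lbl).mf, cols[n])
                for n, lbl in rule.antecedents.items()
            ]
        )
        strengths[:, r] = degs.min(axis=0) if base.and_operator == "min" else degs.prod(axis=0)
        consequents[r] = mf_eval(base.output_var.set(rule.consequent).mf, grid)

    aggregate = np.minimum(strengths[:, :, None], consequents[None, :, :]).max(axis=1)
    mass = aggregate.sum(axis=1)
    fired = mass > 0
    out = np.full(len(data), midpoint)
    out[fired] = (aggregate[fired] * grid).sum(axis=1) / mass[fired]
    n_fallback = int((~fired).sum())
    if n_fallback:
        msg = f"{n_fallback} record(s) fired no rule; used universe midpoint {midpoint}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# serialization: rule bases as versionable, diffable YAML documents


def _mf_to_dict(mf: TriangularMF) -> dict:
    d = {"a": mf.a, "b": mf.b, "c": mf.c}
    if mf.left_shoulder:
        d["left_shoulder"] = True
    if mf.right_shoulder:
        d["right_shoulder"] = True
    return d


def _var_to_dict(var: FuzzyVariable) -> dict:
    return {
        "name": var.name,
        "universe": list(var.universe),
        "sets": [{"label": s.label, "mf": _mf_to_dict(s.mf)} for s in var.sets],
    }


def _var_from_dict(d: dict) -> FuzzyVariable:
    return FuzzyVariable(
        d["name"],
        tuple(d["universe"]),
        tuple(FuzzySet(s["label"], TriangularMF(**s["mf"])) for s in d["sets"]),
    )


def save_rulebase(base: FuzzyRuleBase, path) -> None:
    doc = {
        "and_operator": base.and_operator,
        "resolution": base.resolution,
        "inputs": [_var_to_dict(v) for v in base.input_vars],
        "output": _var_to_dict(base.output_var),
        "rules": [
            {"if": dict(r.antecedents), "then": r.consequent} for r in base.rules
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_rulebase(path) -> FuzzyRuleBase:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return FuzzyRuleBase(
        input_vars=[_var_from_dict(v) for v in doc["inputs"]],
        output_var=_var_from_dict(doc["output"]),
        rules=[FuzzyRule(r["if"], r["then"]) for r in doc["rules"]],
        and_operator=doc["and_operator"],
        resolution=doc["resolution"],
    )
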
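"""GA-driven feature selection and feature engineering.

Selection evolves a binary inclusion mask over the base features; fitness is
a cross-validated score minus a parsimony penalty proportional to mask size.
Engineering then evolves a second binary mask over a finite candidate pool
of transformed features (squares, log1p, pairwise interactions of the
features most correlated with yield); a transformation is retained only if
the engineered solution scores at least as well as the selected base set
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .ga import Chromosome, GAConfig, run_ga
from .synthetic import LOCATIONS, TREATMENTS, Dataset

__all__ = [
    "FeatureMask",
    "EngineeredFeature",
    "FeatureOptResult",
    "candidate_pool",
    "apply_features",
    "make_tree_cv_evaluator",
    "make_ridge_cv_evaluator",
    "ga_select_features",
    "ga_engineer_features",
]


@dataclass(frozen=True)
class FeatureMask:
    """Binary inclusion mask over the base numeric features."""

    names: tuple[str, ...]
    included: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.included):
            raise ValueError("names and included must align")

    @property
    def selected(self) -> list[str]:
        return [n for n, inc in zip(self.names, self.included) if inc]

    @classmethod
    def full(cls, names) -> "FeatureMask":
        names = tuple(names)
        return cls(names, (True,) * len(names))


@dataclass(frozen=True)
class EngineeredFeature:
    """One transformed feature: a square, log1p, or pairwise product."""

    kind: str  # square | log1p | product
    operands: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("square", "log1p", "product"):
            raise ValueError(f"unknown kind {self.kind!r}")
        n_ops = {"square": 1, "log1p": 1, "product": 2}[self.kind]
        if len(self.operands) != n_ops:
            raise ValueError(f"{self.kind} takes {n_ops} operand(s)")
        if self.kind == "product" and self.operands[0] == self.operands[1]:
            raise ValueError("product operands must be distinct")
        if not self.name:
            if self.kind == "square":
                derived = f"{self.operands[0]}^2"
            elif self.kind == "log1p":
                derived = f"log1p_{self.operands[0]}"
            else:
                derived = f"{self.operands[0]}_x_{self.operands[1]}"
            object.__setattr__(self, "name", derived)

    def compute(self, df: pd.DataFrame) -> np.ndarray:
        for op in self.operands:
            if op not in df.columns:
                raise KeyError(f"missing operand column {op!r}")
        if self.kind == "square":
            return df[self.operands[0]].to_numpy(dtype=float) ** 2
        if self.kind == "log1p":
            return np.log1p(df[self.operands[0]].to_numpy(dtype=float))
        return df[self.operands[0]].to_numpy(dtype=float) * df[
            self.operands[1]
        ].to_numpy(dtype=float)


@dataclass
class FeatureOptResult:
    mask: FeatureMask
    engineered: list[EngineeredFeature]
    fitness_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    cv_score: float = np.nan


def candidate_pool(data: Dataset, top_k: int = 8) -> list[EngineeredFeature]:
    """Squares and log1p of the top_k |corr-with-yield| features plus all
    their pairwise products; log1p only for features whose range is
    non-negative.  Deterministic given the data."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > len(data.schema):
        raise ValueError("top_k exceeds number of base features")
    y = data.y
    corrs = {}
    for spec in data.schema:
        x = data.df[spec.name].to_numpy(dtype=float)
        sd = x.std()
        corrs[spec.name] = abs(np.corrcoef(x, y)[0, 1]) if sd > 0 else 0.0
    ranked = sorted(corrs, key=lambda n: (-corrs[n], n))[:top_k]
    nonneg = {s.name for s in data.schema if s.low >= 0}
    pool: list[EngineeredFeature] = []
    for name in ranked:
        pool.append(EngineeredFeature("square", (name,)))
    for name in ranked:
        if name in nonneg:
            pool.append(EngineeredFeature("log1p", (name,)))
    for i, a in enumerate(ranked):
        for b in ranked[i + 1 :]:
            pool.append(EngineeredFeature("product", (a, b)))
    return pool


def apply_features(
    data: Dataset, mask: FeatureMask, engineered: list[EngineeredFeature]
) -> pd.DataFrame:
    """Design frame: base-selected columns (schema order), engineered columns
    (pool order), then treatment and location as categorical columns."""
    cols: dict[str, np.ndarray] = {}
    for name in mask.selected:
        if name not in data.df.columns:
            raise KeyError(f"missing feature column {name!r}")
        cols[name] = data.df[name].to_numpy(dtype=float)
    for feat in engineered:
        cols[feat.name] = feat.compute(data.df)
    X = pd.DataFrame(cols, index=data.df.index)
    X["treatment"] = pd.Categorical(data.df["treatment"], categories=TREATMENTS)
    X["location"] = pd.Categorical(data.df["location"], categories=LOCATIONS)
    return X


def encode_numeric(X: pd.DataFrame) -> np.ndarray:
    """One-hot encode the categorical columns; keep numeric columns as-is."""
    return pd.get_dummies(X, columns=[c for c in ("treatment", "location") if c in X]).to_numpy(
        dtype=float
    )


Evaluator = Callable[[pd.DataFrame], float]


def _cv_r2(model_factory, X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(X):
        model = model_factory()
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        ss_res = float(np.sum((y[te] - pred) ** 2))
        ss_tot = float(np.sum((y[te] - y[te].mean()) ** 2))
        scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return float(np.mean(scores))


def make_tree_cv_evaluator(
    data: Dataset, seed: int = 0, folds: int = 3, n_estimators: int = 30
) -> Evaluator:
    """Default fitness backbone: mean validation R^2 of a fast tree ensemble
    over a seeded internal k-fold split."""
    y = data.y

    def evaluator(X: pd.DataFrame) -> float:
        return _cv_r2(
            lambda: ExtraTreesRegressor(
                n_estimators=n_estimators, random_state=seed, n_jobs=1
            ),
            encode_numeric(X),
            y,
            folds,
            seed,
        )

    return evaluator


def make_ridge_cv_evaluator(
    data: Dataset, seed: int = 0, folds: int = 3, alpha: float = 1.0
) -> Evaluator:
    """Linear alternative: mean validation R^2 of standardized ridge
    regression.  Orders of magnitude faster than the tree evaluator and
    blind to nonlinearity it is not handed explicitly, which makes it the
    sharp tool for judging engineered transformations."""
    y = data.y

    def evaluator(X: pd.DataFrame) -> float:
        return _cv_r2(
            lambda: make_pipeline(StandardScaler(), Ridge(alpha=alpha)),
            encode_numeric(X),
            y,
            folds,
            seed,
        )

    return evaluator


def _run_masked_ga(
    n_genes: int,
    config: GAConfig,
    score_of_genes: Callable[[np.ndarray], float],
    parsimony: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Binary GA with zero-mask repair, fitness caching, and parsimony
    penalty.  Returns (best genes, history, raw score of best)."""
    rng_repair = np.random.default_rng(config.seed + 7919)
    cache: dict[tuple, float] = {}

    def repair(genes: np.ndarray) -> np.ndarray:
        if genes.sum() == 0:
            genes = genes.copy()
            genes[int(rng_repair.integers(0, n_genes))] = 1
        return genes

    def raw_score(genes: np.ndarray) -> float:
        key = tuple(int(g) for g in genes)
        if key not in cache:
            cache[key] = score_of_genes(np.asarray(key))
        return cache[key]

    def fitness(chrom: Chromosome) -> float:
        genes = repair(chrom.genes)
        return raw_score(genes) - parsimony * genes.sum() / n_genes

    def init(rng: np.random.Generator) -> Chromosome:
        return Chromosome("binary", repair(rng.integers(0, 2, size=n_genes)))

    result = run_ga(config, init, fitness)
    best_genes = repair(result.best.genes)
    return best_genes, result.history, raw_score(best_genes)


def ga_select_features(
    data: Dataset,
    config: GAConfig,
    evaluator: Evaluator | None = None,
    parsimony: float = 0.05,
) -> FeatureOptResult:
    """Evolve a binary feature-inclusion mask maximizing the cross-validated
    score minus a parsimony penalty (``parsimony * included / total``).
    All-zero candidate masks are repaired by activating one random gene."""
    evaluator = evaluator or make_tree_cv_evaluator(data, seed=config.seed)
    names = tuple(s.name for s in data.schema)

    def score_of_genes(genes: np.ndarray) -> float:
        mask = FeatureMask(names, tuple(bool(g) for g in genes))
        return evaluator(apply_features(data, mask, []))

    best, history, cv_score = _run_masked_ga(len(names), config, score_of_genes, parsimony)
    mask = FeatureMask(names, tuple(bool(g) for g in best))
    return FeatureOptResult(mask, [], history, cv_score)


def ga_engineer_features(
    data: Dataset,
    base_mask: FeatureMask,
    config: GAConfig,
    evaluator: Evaluator | None = None,
    top_k: int = 8,
    parsimony: float = 0.05,
) -> FeatureOptResult:
    """Evolve a subset of the engineered candidate pool on top of the
    selected base features.  The engineered list is kept only if its
    cross-validated score is at least that of the base mask alone."""
    evaluator = evaluator or make_tree_cv_evaluator(data, seed=config.seed)
    pool = candidate_pool(data, top_k=min(top_k, len(data.schema)))
    base_score = evaluator(apply_features(data, base_mask, []))

    def score_of_genes(genes: np.ndarray) -> float:
        chosen = [f for f, g in zip(pool, genes) if g]
        return evaluator(apply_features(data, base_mask, chosen))

    best, history, cv_score = _run_masked_ga(len(pool), config, score_of_genes, parsimony)
    engineered = [f for f, g in zip(pool, best) if g]
    if cv_score < base_score:
        return FeatureOptResult(base_mask, [], history, base_score)
    return FeatureOptResult(base_mask, engineered, history, cv_score)
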
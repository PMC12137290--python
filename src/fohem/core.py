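"""The fuzzy-optimized hybrid ensemble: FIS + stacked ensemble, GA-blended.

The final prediction is the convex combination

    Y_hat = w_fis * Y_FIS + w_ens * Y_ensemble,      w_fis + w_ens = 1,

with the blend weight optimized by a real-coded GA against validation MSE,
either globally or per treatment x location group.  The general N-component
weighted combination is implemented once (:func:`weighted_combine`); the
two-component blend is the N=2 case of that same code path.

``fohem_fit`` orchestrates the full pipeline: stratified fit/validation
split, GA feature selection and engineering, expert FIS construction over
the top selected features, stacked-ensemble training, GA weight
optimization on the held-out validation part, and a final ensemble refit on
all data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import fuzzy
from .features import (
    FeatureMask,
    FeatureOptResult,
    apply_features,
    ga_engineer_features,
    ga_select_features,
    make_ridge_cv_evaluator,
    make_tree_cv_evaluator,
)
from .fuzzy import build_default_yield_fis, fis_predict
from .ga import Chromosome, GAConfig, run_ga
from .learners import StackedEnsemble, default_specs, stack_fit, stack_predict
from .synthetic import Dataset

__all__ = [
    "GLOBAL_KEY",
    "WeightSet",
    "FOHEMConfig",
    "FOHEMModel",
    "weighted_combine",
    "closed_form_blend_weight",
    "optimize_weights",
    "fohem_fit",
    "fohem_predict",
    "numeric_model_fn",
    "save_bundle",
    "load_bundle",
]

GLOBAL_KEY = "__global__"


def weighted_combine(components: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """General N-component weighted sum: sum_i w_i * f_i(X).

    ``components`` has shape (n_components, n_records); ``weights`` shape
    (n_components,).  The two-component blend used everywhere else routes
    through this function.
    """
    components = np.asarray(components, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return weights @ components


@dataclass
class WeightSet:
    """Blend weights (w_fis, w_ens) per group, simplex-constrained.

    Always contains a global fallback under :data:`GLOBAL_KEY`.
    """

    mode: str  # "global" | "per_group"
    weights: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if GLOBAL_KEY not in self.weights:
            raise ValueError("WeightSet must contain a global fallback key")
        for key, (w_fis, w_ens) in self.weights.items():
            if w_fis < 0 or w_ens < 0 or abs(w_fis + w_ens - 1.0) > 1e-9:
                raise ValueError(
                    f"weights for {key!r} must be non-negative and sum to 1"
                )

    def for_group(self, key: str) -> tuple[float, float]:
        return self.weights.get(key, self.weights[GLOBAL_KEY])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": k, "w_fis": v[0], "w_ens": v[1]}
            for k, v in sorted(self.weights.items())
        ]
        return pd.DataFrame(rows)


def closed_form_blend_weight(y_true, y_fis, y_ens) -> float:
    """Exact minimizer of ||y - (w*y_fis + (1-w)*y_ens)||^2 over w in [0,1].

    The 1-D quadratic has optimum <y - y_ens, y_fis - y_ens> / ||y_fis -
    y_ens||^2, clamped to the unit interval; ties (identical component
    predictions) return 0.5.
    """
    y_true = np.asarray(y_true, dtype=float)
    d = np.asarray(y_fis, dtype=float) - np.asarray(y_ens, dtype=float)
    denom = float(d @ d)
    if denom == 0.0:
        return 0.5
    w = float((y_true - np.asarray(y_ens, dtype=float)) @ d / denom)
    return min(max(w, 0.0), 1.0)


def optimize_weights(
    y_true,
    y_fis,
    y_ens,
    groups,
    config: GAConfig,
    mode: str = "global",
) -> WeightSet:
    """GA-optimize the blend weight(s) against validation MSE.

    One real gene per group (bounds [0, 1]; w_fis = gene, w_ens = 1 - gene),
    plus a global gene, evolved jointly.  Groups with fewer than 2
    validation records are merged into the global key with a warning.
    """
    if mode not in ("global", "per_group"):
        raise ValueError("mode must be 'global' or 'per_group'")
    y_true = np.asarray(y_true, dtype=float)
    y_fis = np.asarray(y_fis, dtype=float)
    y_ens = np.asarray(y_ens, dtype=float)
    groups = np.asarray(groups)
    if not (len(y_true) == len(y_fis) == len(y_ens) == len(groups)):
        raise ValueError("all vectors must share one length")

    keys = [GLOBAL_KEY]
    if mode == "per_group":
        for key in pd.unique(groups):
            n_g = int((groups == key).sum())
            if n_g < 2:
                warnings.warn(
                    f"group {key!r} has {n_g} validation record(s); merged into global"
                )
            else:
                keys.append(str(key))

    # per-record gene index: global gene covers merged/unseen groups
    key_index = {k: i for i, k in enumerate(keys)}
    rec_gene = np.array([key_index.get(str(g), 0) for g in groups])
    if mode == "global":
        rec_gene[:] = 0

    bounds = np.tile([0.0, 1.0], (len(keys), 1))

    def fitness(chrom: Chromosome) -> float:
        w = chrom.genes[rec_gene]
        blend = w * y_fis + (1.0 - w) * y_ens
        return -float(np.mean((blend - y_true) ** 2))

    def init(rng: np.random.Generator) -> Chromosome:
        return Chromosome("real", rng.uniform(0.0, 1.0, size=len(keys)), bounds)

    result = run_ga(config, init, fitness)
    genes = np.clip(result.best.genes, 0.0, 1.0)
    weights = {k: (float(g), float(1.0 - g)) for k, g in zip(keys, genes)}
    if mode == "per_group" and not (rec_gene == 0).any():
        # no merged records constrain the fallback gene: pin the global
        # fallback to the exact 1-D optimum over all validation records
        w_g = closed_form_blend_weight(y_true, y_fis, y_ens)
        weights[GLOBAL_KEY] = (w_g, 1.0 - w_g)
    return WeightSet(mode=mode, weights=weights)


@dataclass(frozen=True)
class FOHEMConfig:
    """Pipeline configuration; the single ``seed`` fans out to every stage."""

    seed: int = 0
    feature_ga: GAConfig | None = None  # defaults set in fohem_fit
    weight_ga: GAConfig | None = None
    evaluator: str = "tree"  # "tree" | "ridge" feature-fitness backbone
    top_k: int = 8
    parsimony: float = 0.05
    n_trees: int = 300
    oof_folds: int = 5
    fis_n_features: int = 3
    val_fraction: float = 0.2
    weight_mode: str = "auto"  # "auto" | "global" | "per_group"
    min_records: int = 40


@dataclass
class FOHEMModel:
    fis: fuzzy.FuzzyRuleBase
    ensemble: StackedEnsemble
    weights: WeightSet
    feature_artifacts: FeatureOptResult
    config: FOHEMConfig
    provenance: dict = field(default_factory=dict)

    def predict(self, data: Dataset) -> np.ndarray:
        return fohem_predict(self, data)

    def component_predictions(self, data: Dataset) -> tuple[np.ndarray, np.ndarray]:
        y_fis = fis_predict(self.fis, data)
        X = apply_features(data, self.feature_artifacts.mask, self.feature_artifacts.engineered)
        y_ens = stack_predict(self.ensemble, X)
        return y_fis, y_ens


def fohem_predict(model: FOHEMModel, data: Dataset) -> np.ndarray:
    """Per-record convex blend with that record's group weights (global
    fallback for unseen groups)."""
    y_fis, y_ens = model.component_predictions(data)
    groups = data.groups.to_numpy()
    known = set(model.weights.weights)
    if model.weights.mode == "per_group":
        unseen = sorted(set(groups) - known)
        if unseen:
            warnings.warn(f"unseen group(s) {unseen}; using global fallback weights")
    w = np.array([model.weights.for_group(g)[0] for g in groups])
    out = np.empty(len(data))
    for i in range(len(data)):
        out[i] = weighted_combine(
            np.array([[y_fis[i]], [y_ens[i]]]), np.array([w[i], 1.0 - w[i]])
        )[0]
    return out


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"{name}: {exc}") from exc
            return False

    return _StageContext()


class _StageError(RuntimeError):
    pass


def _pick_fis_features(data: Dataset, mask: FeatureMask, k: int):
    """FIS inputs: the GA-selected features most correlated with yield."""
    y = data.y
    selected = mask.selected
    if len(selected) < 2:  # FIS needs at least two inputs
        selected = [s.name for s in data.schema]
    scores = {}
    for name in selected:
        x = data.df[name].to_numpy(dtype=float)
        scores[name] = abs(np.corrcoef(x, y)[0, 1]) if x.std() > 0 else 0.0
    top = sorted(scores, key=lambda n: (-scores[n], n))[: max(2, min(k, 4))]
    by_name = {s.name: s for s in data.schema}
    return [by_name[n] for n in top]


def fohem_fit(data: Dataset, config: FOHEMConfig | None = None) -> FOHEMModel:
    """Run the full pipeline and return a fitted hybrid model.

    Stages: (1) seeded 80/20 fit/validation split stratified by treatment x
    location; (2) GA feature selection then engineering on the fit part;
    (3) expert FIS over the top selected features; (4) stacked-ensemble
    training on the engineered matrix; (5) GA weight optimization on the
    validation part; (6) ensemble refit on all records.
    """
    config = config or FOHEMConfig()
    if len(data) < config.min_records:
        raise ValueError(
            f"need at least {config.min_records} records, got {len(data)}"
        )
    seed = config.seed
    feature_ga = config.feature_ga or GAConfig(
        population_size=24, max_generations=14, patience=6, seed=seed + 1
    )
    weight_ga = config.weight_ga or GAConfig(seed=seed + 2, patience=15)
    provenance: dict = {"seed": seed}

    with _stage("split"):
        idx = np.arange(len(data))
        fit_idx, val_idx = train_test_split(
            idx,
            test_size=config.val_fraction,
            random_state=seed,
            stratify=data.groups,
        )
        fit_part, val_part = data.subset(fit_idx), data.subset(val_idx)
        provenance["n_fit"], provenance["n_val"] = len(fit_idx), len(val_idx)

    with _stage("feature_selection"):
        make_eval = make_ridge_cv_evaluator if config.evaluator == "ridge" else make_tree_cv_evaluator
        evaluator = make_eval(fit_part, seed=seed + 3)
        sel = ga_select_features(
            fit_part, feature_ga, evaluator=evaluator, parsimony=config.parsimony
        )

    with _stage("feature_engineering"):
        eng_ga = GAConfig(
            population_size=feature_ga.population_size,
            max_generations=feature_ga.max_generations,
            patience=feature_ga.patience,
            seed=seed + 4,
        )
        artifacts = ga_engineer_features(
            fit_part,
            sel.mask,
            eng_ga,
            evaluator=evaluator,
            top_k=config.top_k,
            parsimony=config.parsimony,
        )
        provenance["selection_history"] = sel.fitness_history.tolist()
        provenance["engineering_history"] = artifacts.fitness_history.tolist()
        provenance["cv_score"] = artifacts.cv_score

    with _stage("fis"):
        fis_specs = _pick_fis_features(fit_part, artifacts.mask, config.fis_n_features)
        fis = build_default_yield_fis(fis_specs)
        provenance["fis_features"] = [s.name for s in fis_specs]

    with _stage("ensemble"):
        specs = default_specs(seed=seed + 5, n_trees=config.n_trees)
        X_fit = apply_features(fit_part, artifacts.mask, artifacts.engineered)
        ensemble = stack_fit(
            X_fit, fit_part.y, specs, oof_folds=config.oof_folds, seed=seed + 6
        )

    with _stage("weights"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # no-rule fallbacks are expected here
            y_fis_val = fis_predict(fis, val_part)
        X_val = apply_features(val_part, artifacts.mask, artifacts.engineered)
        y_ens_val = stack_predict(ensemble, X_val)
        if config.weight_mode == "auto":
            counts = val_part.groups.value_counts()
            mode = "per_group" if (counts >= 10).all() and len(counts) > 1 else "global"
        else:
            mode = config.weight_mode
        weights = optimize_weights(
            val_part.y, y_fis_val, y_ens_val, val_part.groups, weight_ga, mode=mode
        )
        provenance["weight_mode"] = mode
        provenance["closed_form_global_w"] = closed_form_blend_weight(
            val_part.y, y_fis_val, y_ens_val
        )

    with _stage("refit"):
        X_all = apply_features(data, artifacts.mask, artifacts.engineered)
        ensemble = stack_fit(
            X_all, data.y, specs, oof_folds=config.oof_folds, seed=seed + 6
        )

    return FOHEMModel(
        fis=fis,
        ensemble=ensemble,
        weights=weights,
        feature_artifacts=artifacts,
        config=config,
        provenance=provenance,
    )


def numeric_model_fn(model: FOHEMModel, template: Dataset):
    """Adapter for the interpretability estimators: a callable over the
    numeric feature matrix (template's schema order) that rebuilds a dataset
    with the template's treatment/location/yield columns and returns the
    hybrid prediction.  Matrices with a different row count (perturbation
    samples around one instance) reuse the template's first row as the
    categorical context."""
    names = template.feature_names

    def fn(Xm: np.ndarray) -> np.ndarray:
        Xm = np.asarray(Xm, dtype=float)
        if len(Xm) == len(template.df):
            df = template.df.copy().reset_index(drop=True)
        else:
            df = template.df.iloc[[0] * len(Xm)].copy().reset_index(drop=True)
        df[names] = Xm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return fohem_predict(model, Dataset(df, template.schema))

    return fn


# ---------------------------------------------------------------------------
# model bundle: inspectable text artifacts + pickled fitted learners


def save_bundle(model: FOHEMModel, bundle_dir) -> None:
    """Write a bundle directory: JSON manifest and feature artifacts, the
    FIS as YAML, the weight table as CSV, fitted learners via joblib."""
    bundle = Path(bundle_dir)
    bundle.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    manifest = {
        "format": "fohem-bundle-v1",
        "config": cfg,
        "provenance": model.provenance,
    }
    (bundle / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    fuzzy.save_rulebase(model.fis, bundle / "fis.yaml")
    model.weights.to_frame().to_csv(bundle / "weights.csv", index=False)
    features_doc = {
        "names": list(model.feature_artifacts.mask.names),
        "included": [bool(b) for b in model.feature_artifacts.mask.included],
        "engineered": [
            {"kind": f.kind, "operands": list(f.operands), "name": f.name}
            for f in model.feature_artifacts.engineered
        ],
        "cv_score": model.feature_artifacts.cv_score,
    }
    (bundle / "features.json").write_text(json.dumps(features_doc, indent=2))
    hist = model.provenance.get("selection_history", [])
    pd.DataFrame(
        {"generation": np.arange(1, len(hist) + 1), "best_fitness": hist}
    ).to_csv(bundle / "selection_history.csv", index=False)
    joblib.dump(
        {"ensemble": model.ensemble, "weights": model.weights, "config": model.config,
         "feature_artifacts": model.feature_artifacts, "provenance": model.provenance},
        bundle / "model.joblib",
    )


def load_bundle(bundle_dir) -> FOHEMModel:
    bundle = Path(bundle_dir)
    blob = joblib.load(bundle / "model.joblib")
    fis = fuzzy.load_rulebase(bundle / "fis.yaml")
    return FOHEMModel(
        fis=fis,
        ensemble=blob["ensemble"],
        weights=blob["weights"],
        feature_artifacts=blob["feature_artifacts"],
        config=blob["config"],
        provenance=blob["provenance"],
    )
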
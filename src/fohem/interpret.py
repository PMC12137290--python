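"""Model-agnostic interpretability: global importance and local surrogates.

Three transparent estimators cover the roles black-box explainer packages
usually play for tabular regressors:

* permutation importance — increase in MSE when one column is permuted;
* sampling Shapley values — Monte-Carlo average marginal contribution over
  random feature orderings with background imputation (satisfies the
  efficiency identity up to Monte-Carlo error);
* a local sparse-linear surrogate — ridge fit to the model's outputs on
  proximity-weighted Gaussian perturbations around one instance.

All operate on numeric matrices and a ``model_fn(X) -> predictions``
callable, so they apply to any fitted predictor in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceReport",
    "LocalExplanation",
    "permutation_importance",
    "shapley_sampling",
    "local_surrogate",
]


@dataclass
class ImportanceReport:
    """Per-feature global importance, sorted descending by mean."""

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    direction: np.ndarray  # sign context: corr(x_j, model prediction)
    method: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "importance": self.mean,
                "sd": self.sd,
                "direction": self.direction,
            }
        )


@dataclass
class LocalExplanation:
    instance_index: int
    features: list[str]
    contributions: np.ndarray
    intercept: float
    fidelity_r2: float


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def permutation_importance(
    model_fn, X, y, repeats: int = 10, seed: int = 0
) -> ImportanceReport:
    """importance_j = mean over repeats of MSE(y, f(X with column j permuted))
    minus the baseline MSE(y, f(X)); seeded permutations."""
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(Xm) != len(y):
        raise ValueError("X and y lengths differ")
    rng = np.random.default_rng(seed)
    baseline_pred = np.asarray(model_fn(Xm), dtype=float)
    baseline = float(np.mean((y - baseline_pred) ** 2))
    deltas = np.empty((len(names), repeats))
    for j in range(len(names)):
        for r in range(repeats):
            Xp = Xm.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xm)), j]
            deltas[j, r] = float(np.mean((y - model_fn(Xp)) ** 2)) - baseline
    with np.errstate(invalid="ignore"):
        direction = np.array(
            [
                np.corrcoef(Xm[:, j], baseline_pred)[0, 1]
                if Xm[:, j].std() > 0 and baseline_pred.std() > 0
                else 0.0
                for j in range(len(names))
            ]
        )
    order = np.argsort(-deltas.mean(axis=1), kind="stable")
    return ImportanceReport(
        features=[names[i] for i in order],
        mean=deltas.mean(axis=1)[order],
        sd=deltas.std(axis=1, ddof=1)[order],
        direction=direction[order],
        method="permutation",
        seed=seed,
    )


def shapley_sampling(
    model_fn, X_background, x_instance, n_samples: int = 200, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo Shapley contributions for one instance.

    Each sample draws a random feature ordering and a background row; the
    contribution of feature j is the change in f when j switches from the
    background value to the instance value, given the features before it in
    the ordering already switched.  Contributions sum to
    f(x) - mean_b f(b) exactly for each sampled pair, hence the efficiency
    identity holds up to the Monte-Carlo error on the background mean.
    """
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50")
    Xb, _ = _as_matrix(X_background)
    x = np.asarray(x_instance, dtype=float).ravel()
    if Xb.shape[1] != len(x):
        raise ValueError("background and instance dimension mismatch")
    rng = np.random.default_rng(seed)
    d = len(x)
    contrib = np.zeros(d)
    for _ in range(n_samples):
        order = rng.permutation(d)
        z = Xb[rng.integers(0, len(Xb))].copy()
        prev = float(model_fn(z[None, :])[0])
        for j in order:
            z[j] = x[j]
            cur = float(model_fn(z[None, :])[0])
            contrib[j] += cur - prev
            prev = cur
    return contrib / n_samples


def local_surrogate(
    model_fn,
    x_instance,
    X_stats,
    n_perturb: int = 500,
    kernel_width: float | None = None,
    sparsity_k: int = 8,
    seed: int = 0,
) -> LocalExplanation:
    """Sparse linear surrogate of the model around one instance.

    Gaussian perturbations around x (per-feature sd from ``X_stats``),
    proximity-weighted by exp(-d^2 / kernel_width^2) with distances on
    sd-scaled coordinates, ridge fit restricted to the ``sparsity_k``
    features with the largest weighted correlation to the model output.
    Zero-sd features are held fixed and get zero contribution.
    """
    if n_perturb < 100:
        raise ValueError("n_perturb must be >= 100")
    Xs, names = _as_matrix(X_stats)
    x = np.asarray(x_instance, dtype=float).ravel()
    d = len(x)
    if Xs.shape[1] != d:
        raise ValueError("X_stats and instance dimension mismatch")
    sds = Xs.std(axis=0)
    live = sds > 0
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)
    rng = np.random.default_rng(seed)

    P = np.tile(x, (n_perturb, 1))
    P[:, live] = P[:, live] + rng.normal(size=(n_perturb, int(live.sum()))) * sds[live]
    f = np.asarray(model_fn(P), dtype=float)

    scaled = (P[:, live] - x[live]) / sds[live]
    dist2 = (scaled**2).sum(axis=1)
    w = np.exp(-dist2 / kernel_width**2)

    # weighted correlation screen -> sparse support
    wsum = w.sum()
    fw_mean = (w * f).sum() / wsum
    corr = np.zeros(d)
    for j in np.flatnonzero(live):
        xw_mean = (w * P[:, j]).sum() / wsum
        cov = (w * (P[:, j] - xw_mean) * (f - fw_mean)).sum() / wsum
        vx = (w * (P[:, j] - xw_mean) ** 2).sum() / wsum
        vf = (w * (f - fw_mean) ** 2).sum() / wsum
        corr[j] = cov / np.sqrt(vx * vf) if vx > 0 and vf > 0 else 0.0
    k = min(sparsity_k, int(live.sum()))
    support = np.argsort(-np.abs(corr), kind="stable")[:k]

    # weighted ridge on the support (tiny penalty: stability, not shrinkage)
    A = np.column_stack([P[:, support], np.ones(n_perturb)])
    sw = np.sqrt(w)
    G = (A * sw[:, None]).T @ (A * sw[:, None]) + 1e-8 * np.eye(k + 1)
    coef = np.linalg.solve(G, (A * sw[:, None]).T @ (f * sw))
    pred = A @ coef
    ss_res = float((w * (f - pred) ** 2).sum())
    ss_tot = float((w * (f - fw_mean) ** 2).sum())
    fidelity = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    contributions = np.zeros(d)
    contributions[support] = coef[:-1]
    return LocalExplanation(
        instance_index=-1,
        features=names,
        contributions=contributions,
        intercept=float(coef[-1]),
        fidelity_r2=float(fidelity),
    )
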
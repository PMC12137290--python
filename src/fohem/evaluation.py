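"""Regression metrics, k-fold cross-validation, and per-group reporting.

Group keys are treatment x location; reports are ordered deterministically
(treatments SS, SM, 2M2S, 2M3S; locations alphabetical) with the pooled
overall report last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .synthetic import TREATMENTS, Dataset, kfold_split

__all__ = ["MetricReport", "CVReport", "metrics", "cross_validate", "group_report"]


@dataclass(frozen=True)
class MetricReport:
    mse: float
    mae: float
    rmse: float
    r2: float | None
    n: int
    group: str | None = None

    def as_dict(self) -> dict:
        return {
            "group": self.group or "overall",
            "n": self.n,
            "MSE": self.mse,
            "MAE": self.mae,
            "RMSE": self.rmse,
            "R2": self.r2,
        }


@dataclass(frozen=True)
class CVReport:
    per_fold: list[MetricReport]
    mean_r2: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": i + 1, "MSE": r.mse, "MAE": r.mae, "RMSE": r.rmse, "R2": r.r2}
            for i, r in enumerate(self.per_fold)
        ]
        rows.append({"fold": "mean", "MSE": None, "MAE": None, "RMSE": None, "R2": self.mean_r2})
        return pd.DataFrame(rows)


def metrics(y_true, y_pred, group: str | None = None) -> MetricReport:
    """MSE, MAE, RMSE and R^2 (1 - SS_res/SS_tot about the mean of y_true).

    R^2 is reported as None with a warning when y_true has zero variance or
    fewer than 2 points.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValueError("non-finite values in inputs")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if len(y_true) < 2 or ss_tot == 0.0:
        warnings.warn("R^2 undefined (zero variance or n < 2); reported as missing")
        r2 = None
    else:
        r2 = float(1.0 - np.sum(err**2) / ss_tot)
    return MetricReport(mse, mae, rmse, r2, len(y_true), group)


FitFn = Callable[[Dataset, int], Callable[[Dataset], np.ndarray]]


def cross_validate(data: Dataset, fit_fn: FitFn, k: int = 5, seed: int = 0) -> CVReport:
    """Seeded k-fold CV of any predictor contract.

    ``fit_fn(train_data, fold_seed)`` must return a ``predict(dataset)``
    callable; fold seeds are ``seed + fold_index`` so every fold is
    independently reproducible.
    """
    folds = kfold_split(data, k, seed)
    per_fold: list[MetricReport] = []
    for i, (tr, te) in enumerate(folds):
        try:
            predict = fit_fn(data.subset(tr), seed + i)
            pred = predict(data.subset(te))
        except Exception as exc:  # annotate with fold index
            raise RuntimeError(f"fold {i}: {exc}") from exc
        per_fold.append(metrics(data.subset(te).y, pred))
    r2s = [r.r2 for r in per_fold if r.r2 is not None]
    return CVReport(per_fold, float(np.mean(r2s)) if r2s else np.nan)


def group_report(data: Dataset, y_pred) -> list[MetricReport]:
    """One report per observed treatment x location group, then the overall
    pooled report; singleton groups get metrics without R^2."""
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_pred) != len(data):
        raise ValueError("prediction length mismatch")
    reports: list[MetricReport] = []
    groups = data.groups.to_numpy()
    locations = sorted(set(data.df["location"]))
    for treatment in TREATMENTS:
        for location in locations:
            key = f"{treatment}/{location}"
            idx = np.flatnonzero(groups == key)
            if len(idx) == 0:
                continue
            reports.append(metrics(data.y[idx], y_pred[idx], group=key))
    reports.append(metrics(data.y, y_pred, group=None))
    return reports


def report_frame(reports: list[MetricReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])
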
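"""Permutation feature importance and partial dependence.

Importance of a feature is the increase in the model's MSE when that
feature's column is randomly shuffled across the evaluation rows —
breaking its connection to ΔΔG‡ while leaving its marginal distribution
intact.  Replicated shuffles give a mean and standard deviation per
feature.  Partial dependence averages the model's prediction over the
table while sweeping one feature over a grid between its observed bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import DataError, MoleculeRole, ReactionFeatureTable
from .evaluation import mse
from .regressors import TrainedRegressor


@dataclass
class ImportanceResult:
    per_feature: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_replications: int = 0
    baseline_mse: float = 0.0

    def to_frame(self, roles: dict[str, MoleculeRole] | None = None) -> pd.DataFrame:
        rows = [
            {
                "feature": name,
                "role": roles[name].value if roles else "",
                "mean": m,
                "std": s,
            }
            for name, (m, s) in self.per_feature.items()
        ]
        return pd.DataFrame(rows).sort_values("mean", ascending=False, kind="stable")


@dataclass
class PartialDependenceCurve:
    feature_name: str
    grid: np.ndarray
    averaged_prediction: np.ndarray

    @property
    def range(self) -> float:
        return float(self.averaged_prediction.max() - self.averaged_prediction.min())


def permutation_importance(
    model: TrainedRegressor,
    table: ReactionFeatureTable,
    n_replications: int = 100,
    seed: int = 0,
) -> ImportanceResult:
    """Mean/std MSE increase per feature over seeded shuffle replications."""
    if table.target is None:
        raise DataError("importance needs a labeled table")
    if table.n_reactions < 2:
        raise DataError("shuffling a single row is the identity")
    X = table.column_matrix(model.feature_names)
    y = table.target
    baseline = mse(y, model.predict_matrix(X))

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    result: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(model.feature_names):
        deltas = np.empty(n_replications)
        for r in range(n_replications):
            Xp = X.copy()
            Xp[:, j] = X[rng.permutation(n), j]
            deltas[r] = mse(y, model.predict_matrix(Xp)) - baseline
        result[name] = (float(deltas.mean()), float(deltas.std(ddof=1)))
    return ImportanceResult(
        per_feature=result, n_replications=n_replications, baseline_mse=baseline
    )


def top_features(
    result: ImportanceResult,
    roles: dict[str, MoleculeRole] | None = None,
    role_filter: MoleculeRole | None = None,
    k: int = 4,
) -> list[str]:
    """Top-k features by mean importance (desc), ties broken by name (asc)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    names = list(result.per_feature)
    if role_filter is not None:
        if roles is None:
            raise ValueError("role_filter requires a feature-role mapping")
        names = [n for n in names if roles[n] is MoleculeRole(role_filter)]
    names.sort(key=lambda n: (-result.per_feature[n][0], n))
    return names[:k]


def partial_dependence(
    model: TrainedRegressor,
    table: ReactionFeatureTable,
    feature_name: str,
    grid_size: int = 20,
) -> PartialDependenceCurve:
    """Average prediction as the named feature sweeps its observed range."""
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if feature_name not in model.feature_names:
        raise DataError(f"feature {feature_name!r} not used by the model")
    X = table.column_matrix(model.feature_names)
    j = model.feature_names.index(feature_name)
    lo, hi = X[:, j].min(), X[:, j].max()
    if lo == hi:
        raise DataError(f"feature {feature_name!r} is constant; no range to sweep")
    grid = np.linspace(lo, hi, grid_size)
    avg = np.empty(grid_size)
    for g, value in enumerate(grid):
        Xg = X.copy()
        Xg[:, j] = value
        avg[g] = model.predict_matrix(Xg).mean()
    return PartialDependenceCurve(feature_name=feature_name, grid=grid, averaged_prediction=avg)
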
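"""Monte-Carlo cross-validation, MSE/R², and two-sample z comparisons.

Performance of a learner is summarized by the mean and standard deviation
of validation MSE and R² over repeated random 80/20 train/validation
splits (Monte-Carlo CV, 100 replications by default).  Two learners are
compared with one-sided two-sample z-tests on those replication summaries
at the 0.05 level (critical value 1.64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import regressors
from .core_data import DataError, FeatureView, ReactionFeatureTable
from .regressors import HyperparameterSetting, RegressorKind

#: one-sided critical value at the 0.05 significance level
Z_CRITICAL_05 = 1.64


def mse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared deviation between actual and predicted values."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    return float(np.mean((a - p) ** 2))


def r_squared(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (may be negative)."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("actual values are constant; R² undefined")
    ss_res = float(np.sum((a - p) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class CVResult:
    """Aggregate of one learner's Monte-Carlo CV replications."""

    kind: RegressorKind
    view: FeatureView
    n_replications: int
    mse_mean: float
    mse_std: float
    r2_mean: float
    r2_std: float
    per_replication: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_replication, columns=["mse", "r2"])


@dataclass
class ZTestResult:
    """One-sided two-sample z-test outcome."""

    z: float
    critical: float
    reject: bool
    direction: str  # which sample is claimed better: "a" or "b"


def two_sample_z(mean1: float, std1: float, mean2: float, std2: float, n: int) -> float:
    """(mean1 − mean2) / sqrt(std1²/n + std2²/n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if std1 < 0 or std2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if std1 == 0 and std2 == 0:
        raise DataError("both standard deviations are zero")
    return (mean1 - mean2) / math.sqrt(std1**2 / n + std2**2 / n)


def compare_models(
    result_a: CVResult, result_b: CVResult, alpha: float = 0.05
) -> tuple[ZTestResult, ZTestResult]:
    """Is model *a* better than *b*?  Returns (MSE test, R² test).

    Lower MSE is better (reject when z ≤ −1.64); higher R² is better
    (reject when z ≥ 1.64).
    """
    if result_a.n_replications != result_b.n_replications:
        raise ValueError("CV results have different replication counts")
    if alpha != 0.05:
        raise NotImplementedError("only the 0.05 level (critical 1.64) is supported")
    n = result_a.n_replications
    z_mse = two_sample_z(result_a.mse_mean, result_a.mse_std,
                         result_b.mse_mean, result_b.mse_std, n)
    z_r2 = two_sample_z(result_a.r2_mean, result_a.r2_std,
                        result_b.r2_mean, result_b.r2_std, n)
    return (
        ZTestResult(z=z_mse, critical=Z_CRITICAL_05, reject=z_mse <= -Z_CRITICAL_05,
                    direction="a"),
        ZTestResult(z=z_r2, critical=Z_CRITICAL_05, reject=z_r2 >= Z_CRITICAL_05,
                    direction="a"),
    )


def monte_carlo_cv(
    kind: RegressorKind,
    table: ReactionFeatureTable,
    hp: HyperparameterSetting,
    view: FeatureView = FeatureView.ALL,
    n_replications: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> CVResult:
    """Repeated random-subsampling validation of one learner.

    Each replication draws an independent uniform random split with
    ``floor(train_fraction·n)`` training rows, fits on the training rows
    and scores MSE and R² on the held-out rows.  Aggregates use ddof=1.
    Fully reproducible from ``seed`` (a master SeedSequence spawns one
    child per replication).
    """
    if table.target is None:
        raise DataError("Monte-Carlo CV needs a labeled table")
    n = table.n_reactions
    if n < 5:
        raise DataError("Monte-Carlo CV needs at least 5 reactions")
    n_train = int(math.floor(train_fraction * n))
    if n_train < 2 or n_train >= n:
        raise DataError("train fraction leaves an empty split")

    children = np.random.SeedSequence(seed).spawn(n_replications)
    scores: list[tuple[float, float]] = []
    for child in children:
        rng = np.random.default_rng(child)
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        sub_train = ReactionFeatureTable(
            reaction_ids=[table.reaction_ids[i] for i in tr],
            features=table.features[tr],
            feature_names=table.feature_names,
            feature_roles=table.feature_roles,
            target=table.target[tr],
            source_label=table.source_label,
        )
        model = regressors.fit(kind, sub_train, hp, view=view, seed=rep_seed)
        sub_val = ReactionFeatureTable(
            reaction_ids=[table.reaction_ids[i] for i in va],
            features=table.features[va],
            feature_names=table.feature_names,
            feature_roles=table.feature_roles,
            target=table.target[va],
            source_label=table.source_label,
        )
        pred = model.predict(sub_val)
        scores.append((mse(sub_val.target, pred), r_squared(sub_val.target, pred)))

    arr = np.asarray(scores)
    return CVResult(
        kind=RegressorKind(kind),
        view=FeatureView(view),
        n_replications=n_replications,
        mse_mean=float(arr[:, 0].mean()),
        mse_std=float(arr[:, 0].std(ddof=1)),
        r2_mean=float(arr[:, 1].mean()),
        r2_std=float(arr[:, 1].std(ddof=1)),
        per_replication=[(float(m), float(r)) for m, r in scores],
    )
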
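"""Uniform contract over the five base learners.

Each learner tunes exactly one key hyperparameter: the l1 penalty ``alpha``
for LASSO, the minimum split size for the decision tree, the number of
trees for the random forest, the number of boosting iterations for
gradient boosting, and the l2 regularization ``C`` for SVR.  Scale
sensitive learners (LASSO, SVR) see z-scored inputs using training
statistics; tree ensembles consume raw features.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .core_data import FeatureView, ReactionFeatureTable, SchemaError, DataError, subset_by_view

_ARCHIVE_SCHEMA = 1


class ConfigurationError(ValueError):
    """Hyperparameter does not match the learner kind or is out of range."""


class RegressorKind(str, enum.Enum):
    LASSO = "lasso"
    DECISION_TREE = "decision_tree"
    RANDOM_FOREST = "random_forest"
    GRADIENT_BOOSTING = "gradient_boosting"
    SVR = "svr"


#: hyperparameter name tuned for each learner kind
HYPERPARAMETER_NAME = {
    RegressorKind.LASSO: "alpha",
    RegressorKind.DECISION_TREE: "min_split",
    RegressorKind.RANDOM_FOREST: "num_trees",
    RegressorKind.GRADIENT_BOOSTING: "num_iter",
    RegressorKind.SVR: "C",
}

#: learners whose inputs are standardized before fitting
_STANDARDIZED = {RegressorKind.LASSO, RegressorKind.SVR}

#: fixed non-tuned settings (conventional defaults)
GB_LEARNING_RATE = 0.1
SVR_EPSILON = 0.1


@dataclass(frozen=True)
class HyperparameterSetting:
    """The single tuned hyperparameter of one learner."""

    name: str
    value: float

    def __post_init__(self) -> None:
        if self.name in ("min_split", "num_trees", "num_iter"):
            v = self.value
            if v != int(v):
                raise ConfigurationError(f"{self.name} must be an integer, got {v}")
            lo = 2 if self.name == "min_split" else 1
            if v < lo:
                raise ConfigurationError(f"{self.name} must be >= {lo}")
        elif self.name in ("alpha", "C"):
            if self.value <= 0:
                raise ConfigurationError(f"{self.name} must be positive")
        else:
            raise ConfigurationError(f"unknown hyperparameter {self.name!r}")

    def for_kind(self, kind: RegressorKind) -> None:
        expected = HYPERPARAMETER_NAME[RegressorKind(kind)]
        if self.name != expected:
            raise ConfigurationError(
                f"{RegressorKind(kind).value} expects hyperparameter "
                f"{expected!r}, got {self.name!r}"
            )


def default_setting(kind: RegressorKind, value: float) -> HyperparameterSetting:
    return HyperparameterSetting(HYPERPARAMETER_NAME[RegressorKind(kind)], value)


def _make_estimator(kind: RegressorKind, hp: HyperparameterSetting, seed: int):
    if kind is RegressorKind.LASSO:
        return Lasso(alpha=hp.value, max_iter=50_000)
    if kind is RegressorKind.DECISION_TREE:
        return DecisionTreeRegressor(min_samples_split=int(hp.value), random_state=seed)
    if kind is RegressorKind.RANDOM_FOREST:
        return RandomForestRegressor(n_estimators=int(hp.value), random_state=seed)
    if kind is RegressorKind.GRADIENT_BOOSTING:
        return GradientBoostingRegressor(
            n_estimators=int(hp.value), learning_rate=GB_LEARNING_RATE, random_state=seed
        )
    if kind is RegressorKind.SVR:
        return SVR(kernel="rbf", C=hp.value, gamma="scale", epsilon=SVR_EPSILON)
    raise ConfigurationError(f"unknown kind {kind!r}")


@dataclass
class TrainedRegressor:
    """A fitted learner plus everything needed to reproduce its predictions.

    Stores the feature view and ordered feature names it was trained on and
    the per-feature standardization statistics (identity for tree learners).
    """

    kind: RegressorKind
    hyperparameter: HyperparameterSetting
    view: FeatureView
    feature_names: list[str]
    estimator: object
    scale_mean: np.ndarray
    scale_std: np.ndarray
    seed: int

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_mean) / self.scale_std

    def predict(self, table: ReactionFeatureTable) -> np.ndarray:
        """One ΔΔG‡ prediction per row; extra columns are ignored."""
        X = table.column_matrix(self.feature_names)
        return self.predict_matrix(X)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict from a raw matrix already ordered as ``feature_names``."""
        if X.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return np.asarray(self.estimator.predict(self._transform(X)), dtype=float)

    def save(self, path) -> None:
        joblib.dump(
            {
                "schema": _ARCHIVE_SCHEMA,
                "kind": self.kind.value,
                "hyperparameter": (self.hyperparameter.name, self.hyperparameter.value),
                "view": self.view.value,
                "feature_names": self.feature_names,
                "estimator": self.estimator,
                "scale_mean": self.scale_mean,
                "scale_std": self.scale_std,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedRegressor":
        blob = joblib.load(path)
        if blob.get("schema") != _ARCHIVE_SCHEMA:
            raise ConfigurationError(f"unsupported model archive schema {blob.get('schema')}")
        return cls(
            kind=RegressorKind(blob["kind"]),
            hyperparameter=HyperparameterSetting(*blob["hyperparameter"]),
            view=FeatureView(blob["view"]),
            feature_names=list(blob["feature_names"]),
            estimator=blob["estimator"],
            scale_mean=np.asarray(blob["scale_mean"]),
            scale_std=np.asarray(blob["scale_std"]),
            seed=int(blob["seed"]),
        )


def fit(
    kind: RegressorKind,
    table: ReactionFeatureTable,
    hp: HyperparameterSetting,
    view: FeatureView = FeatureView.ALL,
    seed: int = 0,
) -> TrainedRegressor:
    """Fit one base learner on the table restricted to the given view.

    Deterministic given ``seed``.  LASSO and SVR inputs are z-scored with
    training statistics; features constant in training carry std treated
    as 1 so the transform stays finite.
    """
    kind = RegressorKind(kind)
    hp.for_kind(kind)
    if table.target is None:
        raise DataError("training table has no target")
    if table.n_reactions < 2:
        raise DataError("need at least 2 training reactions")
    sub = subset_by_view(table, FeatureView(view))
    X, y = sub.features, sub.target

    if kind in _STANDARDIZED:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])

    est = _make_estimator(kind, hp, seed)
    est.fit((X - mean) / std, y)
    return TrainedRegressor(
        kind=kind,
        hyperparameter=hp,
        view=FeatureView(view),
        feature_names=list(sub.feature_names),
        estimator=est,
        scale_mean=mean,
        scale_std=std,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Forward step-wise linear regression baseline
# ---------------------------------------------------------------------------

def stepwise_lr_baseline(
    table: ReactionFeatureTable,
    max_features: int = 20,
    collinearity_r: float = 0.3,
    val_fraction: float = 0.2,
    seed: int = 0,
):
    """Greedy forward-selected linear regression comparison baseline.

    At each step the candidate feature giving the lowest validation MSE is
    added; candidates correlated with an already-selected feature beyond
    ``|r| > collinearity_r`` are excluded.  Selection stops when no
    candidate improves validation MSE or ``max_features`` is reached.
    Returns ``(selected_feature_names, fitted LinearRegression, val_mse)``.

    This is a plain documented baseline for context, not a reproduction of
    any published stepwise procedure.
    """
    if table.target is None:
        raise DataError("baseline needs a labeled table")
    rng = np.random.default_rng(seed)
    n = table.n_reactions
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X, y = table.features, table.target
    names = table.feature_names

    selected: list[int] = []
    best_mse = np.inf
    model = None
    while len(selected) < max_features:
        best_j, best_j_mse, best_j_model = None, best_mse, None
        for j in range(len(names)):
            if j in selected:
                continue
            if any(
                abs(np.corrcoef(X[:, j], X[:, s])[0, 1]) > collinearity_r
                for s in selected
            ):
                continue
            cols = selected + [j]
            m = LinearRegression().fit(X[np.ix_(tr_idx, cols)], y[tr_idx])
            mse = float(np.mean((m.predict(X[np.ix_(val_idx, cols)]) - y[val_idx]) ** 2))
            if mse < best_j_mse:
                best_j, best_j_mse, best_j_model = j, mse, m
        if best_j is None:
            break
        selected.append(best_j)
        best_mse, model = best_j_mse, best_j_model
    return [names[j] for j in selected], model, best_mse
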
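"""Bayesian optimization of each learner's single key hyperparameter.

One fixed 80/20 train/validation split is drawn from the seed; the
objective is the validation MSE of a fit at the proposed hyperparameter.
A Gaussian-process surrogate with expected-improvement acquisition drives
the search: the first quarter of the budget is a space-filling design
(including the space midpoint), the remainder acquisition-driven.
Integer-valued parameters are optimized on a continuous relaxation and
rounded at evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from . import regressors
from .core_data import FeatureView, ReactionFeatureTable, DataError
from .evaluation import mse
from .regressors import (
    ConfigurationError,
    HYPERPARAMETER_NAME,
    HyperparameterSetting,
    RegressorKind,
)

_N_CANDIDATES = 512  # acquisition maximized over this dense 1-d grid


@dataclass(frozen=True)
class SearchSpace:
    """Bounds and scale for one hyperparameter."""

    hyperparameter_name: str
    lower: float
    upper: float
    scale: str = "linear"  # "linear" | "log"
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ConfigurationError("lower bound must be below upper bound")
        if self.scale not in ("linear", "log"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.scale == "log" and self.lower <= 0:
            raise ConfigurationError("log scale requires a positive lower bound")

    # internal <-> external coordinates --------------------------------
    def to_internal(self, x: float) -> float:
        return math.log(x) if self.scale == "log" else x

    def to_external(self, u: float) -> float:
        x = math.exp(u) if self.scale == "log" else u
        x = min(max(x, self.lower), self.upper)
        return float(round(x)) if self.integer_valued else float(x)


#: default search spaces per learner kind; ranges bracket the optima the
#: tuned models typically land on for CPA-style feature tables
DEFAULT_SPACES: dict[RegressorKind, SearchSpace] = {
    RegressorKind.LASSO: SearchSpace("alpha", 1e-4, 1.0, "log"),
    RegressorKind.SVR: SearchSpace("C", 0.1, 10.0, "log"),
    RegressorKind.DECISION_TREE: SearchSpace("min_split", 2, 20, "linear", True),
    RegressorKind.GRADIENT_BOOSTING: SearchSpace("num_iter", 10, 200, "linear", True),
    RegressorKind.RANDOM_FOREST: SearchSpace("num_trees", 10, 200, "linear", True),
}


@dataclass
class TuningResult:
    best_setting: HyperparameterSetting
    best_validation_mse: float
    evaluation_trace: list[tuple[HyperparameterSetting, float]] = field(default_factory=list)
    budget: int = 0
    seed: int = 0


def _initial_design(space: SearchSpace, k: int) -> list[float]:
    """k space-filling points in internal coordinates, midpoint first."""
    lo, hi = space.to_internal(space.lower), space.to_internal(space.upper)
    mid = 0.5 * (lo + hi)
    pts = [mid]
    if k > 1:
        pts.extend(np.linspace(lo, hi, k - 1).tolist())
    # dedupe while preserving order
    seen, out = set(), []
    for p in pts:
        key = round(p, 12)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out[:k]


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    imp = best - mu
    z = imp / sigma
    return imp * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def optimize_scalar(
    objective,
    space: SearchSpace,
    budget: int,
    rng: np.random.Generator,
) -> list[tuple[HyperparameterSetting, float]]:
    """GP/expected-improvement minimization of a 1-d objective.

    ``objective`` maps an internal coordinate to a
    ``(HyperparameterSetting, score)`` pair.  The first ⌈budget/4⌉
    evaluations are a space-filling design (midpoint first), the rest
    maximize expected improvement of a Gaussian-process surrogate over a
    dense candidate grid.  Returns the full evaluation trace.
    """
    if budget < 5:
        raise ConfigurationError("budget must be at least 5 evaluations")
    lo, hi = space.to_internal(space.lower), space.to_internal(space.upper)
    us: list[float] = []
    trace: list[tuple[HyperparameterSetting, float]] = []

    for u in _initial_design(space, max(2, math.ceil(budget / 4))):
        hp, score = objective(u)
        us.append(u)
        trace.append((hp, score))

    while len(trace) < budget:
        X = np.asarray(us).reshape(-1, 1)
        y = np.asarray([s for _, s in trace])
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * Matern(
                length_scale=(hi - lo) / 4,
                length_scale_bounds=(1e-3 * (hi - lo), 10 * (hi - lo)),
                nu=2.5,
            )
            + WhiteKernel(1e-6, (1e-10, 1e1))
        )
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            # surrogate hyperparameters pinned at their bounds are fine here
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, y)
        cand = np.linspace(lo, hi, _N_CANDIDATES)
        mu, sigma = gp.predict(cand.reshape(-1, 1), return_std=True)
        ei = _expected_improvement(mu, sigma, y.min())
        # never re-evaluate an already-seen point; tiny jitter breaks ties
        ei += 1e-12 * rng.standard_normal(ei.size)
        order = np.argsort(-ei)
        u_next = None
        for idx in order:
            if all(abs(cand[idx] - u) > 1e-9 for u in us):
                u_next = float(cand[idx])
                break
        if u_next is None:
            u_next = float(rng.uniform(lo, hi))
        hp, score = objective(u_next)
        us.append(u_next)
        trace.append((hp, score))
    return trace


def bayes_optimize(
    kind: RegressorKind,
    table: ReactionFeatureTable,
    view: FeatureView = FeatureView.ALL,
    space: SearchSpace | None = None,
    budget: int = 25,
    seed: int = 0,
) -> TuningResult:
    """Minimize validation MSE over one hyperparameter.

    Returns the argmin over the full evaluation trace; reproducible from
    ``seed`` (split, surrogate restarts and candidate jitter all derive
    from it).
    """
    kind = RegressorKind(kind)
    if space is None:
        space = DEFAULT_SPACES[kind]
    if space.hyperparameter_name != HYPERPARAMETER_NAME[kind]:
        raise ConfigurationError(
            f"space tunes {space.hyperparameter_name!r} but "
            f"{kind.value} expects {HYPERPARAMETER_NAME[kind]!r}"
        )
    if table.target is None:
        raise DataError("tuning needs a labeled table")

    rng = np.random.default_rng(seed)
    n = table.n_reactions
    perm = rng.permutation(n)
    n_val = max(1, int(round(0.2 * n)))
    va, tr = perm[:n_val], perm[n_val:]
    train = ReactionFeatureTable(
        reaction_ids=[table.reaction_ids[i] for i in tr],
        features=table.features[tr],
        feature_names=table.feature_names,
        feature_roles=table.feature_roles,
        target=table.target[tr],
    )
    val = ReactionFeatureTable(
        reaction_ids=[table.reaction_ids[i] for i in va],
        features=table.features[va],
        feature_names=table.feature_names,
        feature_roles=table.feature_roles,
        target=table.target[va],
    )
    fit_seed = int(rng.integers(2**31))

    def objective(u: float) -> tuple[HyperparameterSetting, float]:
        hp = HyperparameterSetting(space.hyperparameter_name, space.to_external(u))
        model = regressors.fit(kind, train, hp, view=view, seed=fit_seed)
        return hp, mse(val.target, model.predict(val))

    trace = optimize_scalar(objective, space, budget, rng)
    best_i = int(np.argmin([s for _, s in trace]))
    return TuningResult(
        best_setting=trace[best_i][0],
        best_validation_mse=trace[best_i][1],
        evaluation_trace=trace,
        budget=budget,
        seed=seed,
    )
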
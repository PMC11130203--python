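"""Gaussian-mixture density routing among three enantioselectivity predictors.

The composite model guards its three regressors with two Gaussian mixture
densities fitted (via EM) to the training distribution of a handful of
key descriptors: one over the top nucleophile features, one over the top
imine features.  For a new set of reactions, the average log-likelihood
of those features under each fitted mixture measures how similar the new
molecules are to the training ones.  Routing rule (threshold 1.0, strict):

* nucleophile similarity low                → LASSO (all features) —
  a simple linear model generalizes best far from the training data;
* nucleophile high, imine similarity low    → nucleophile-focused random
  forest (trained without imine features);
* both high                                 → the overall SVR.

Component counts are chosen by scanning K and minimizing the Bayesian
information criterion BIC = −2·logL + p·ln(n).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from . import regressors
from .core_data import (
    DataError,
    FeatureView,
    MoleculeRole,
    ReactionFeatureTable,
    SchemaError,
)
from .evaluation import mse, r_squared
from .regressors import HyperparameterSetting, RegressorKind, TrainedRegressor

# EM fitting constants (configurable through fit_gmm arguments)
RIDGE = 1e-6
EM_TOL = 1e-4
EM_MAX_ITER = 200
EM_RESTARTS = 5

#: average log-likelihood above which a test set counts as "similar"
DEFAULT_THRESHOLD = 1.0

#: key-feature defaults: top-4 by permutation importance of the
#: nucleophile-focused RF and of the overall SVR respectively
DEFAULT_NUCLEOPHILE_FEATURES = ["H-X-Nu", "H-X-CNu", "Nu", "Polarizability"]
DEFAULT_IMINE_FEATURES = ["C", "N", "SL", "LUMO"]


class RoutedPredictor(str, enum.Enum):
    OVERALL_SVR = "overall_svr"
    NUCLEOPHILE_RF = "nucleophile_rf"
    LASSO = "lasso"


@dataclass
class GaussianMixtureDensity:
    """A fitted K-component full-covariance Gaussian mixture.

    Fitting standardizes each feature with its own mean/std from the fit
    data; log-likelihoods are reported in the original units, i.e. the
    standardized-space density minus the log-Jacobian Σⱼ log(stdⱼ) of the
    transform (a fixed convention; routing compares likelihoods computed
    under the same convention).
    """

    n_components: int
    weights: np.ndarray            # (K,)
    means: np.ndarray              # (K, d) in standardized space
    covariances: np.ndarray        # (K, d, d) in standardized space
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    fit_log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = False
    seed: int = 0

    @property
    def d(self) -> int:
        return len(self.feature_names)

    @property
    def n_parameters(self) -> int:
        K, d = self.n_components, self.d
        return (K - 1) + K * d + K * d * (d + 1) // 2

    def _log_jacobian(self) -> float:
        return float(np.sum(np.log(self.scale_std)))

    def log_densities(self, X: np.ndarray) -> np.ndarray:
        """Per-row mixture log density (original units)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise DataError(f"expected {self.d}-column data, got shape {X.shape}")
        Z = (X - self.scale_mean) / self.scale_std
        comp = _component_log_pdfs(Z, self.means, self.covariances)
        return logsumexp(comp + np.log(self.weights), axis=1) - self._log_jacobian()

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "feature_names": self.feature_names,
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "fit_log_likelihood_trace": self.fit_log_likelihood_trace,
            "converged": self.converged,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, blob: dict) -> "GaussianMixtureDensity":
        return cls(
            n_components=int(blob["n_components"]),
            weights=np.asarray(blob["weights"]),
            means=np.asarray(blob["means"]),
            covariances=np.asarray(blob["covariances"]),
            feature_names=list(blob["feature_names"]),
            scale_mean=np.asarray(blob["scale_mean"]),
            scale_std=np.asarray(blob["scale_std"]),
            fit_log_likelihood_trace=list(blob["fit_log_likelihood_trace"]),
            converged=bool(blob["converged"]),
            seed=int(blob["seed"]),
        )


def _component_log_pdfs(Z: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(n, K) matrix of N(z; μₖ, Σₖ) log densities via Cholesky."""
    n, d = Z.shape
    K = means.shape[0]
    out = np.empty((n, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        diff = Z - means[k]
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out


def _em_once(
    Z: np.ndarray,
    n_components: int,
    seed: int,
    ridge: float,
    tol: float,
    max_iter: int,
    log_jacobian: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """One EM run from a k-means initialization; returns params + trace."""
    n, d = Z.shape
    km = KMeans(n_clusters=n_components, n_init=1, random_state=seed).fit(Z)
    means = km.cluster_centers_.copy()
    labels = km.labels_
    weights = np.array(
        [max(np.sum(labels == k), 1) for k in range(n_components)], dtype=float
    )
    weights /= weights.sum()
    covs = np.empty((n_components, d, d))
    for k in range(n_components):
        pts = Z[labels == k]
        if pts.shape[0] > 1:
            covs[k] = np.cov(pts, rowvar=False, ddof=0)
        else:
            covs[k] = np.eye(d)
        covs[k][np.diag_indices(d)] += ridge

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        comp = _component_log_pdfs(Z, means, covs)
        weighted = comp + np.log(weights)
        row_ll = logsumexp(weighted, axis=1)
        avg_ll = float(row_ll.mean()) - log_jacobian
        if trace and avg_ll - trace[-1] < tol:
            trace.append(avg_ll)
            converged = True
            break
        trace.append(avg_ll)
        resp = np.exp(weighted - row_ll[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-10)
        weights = nk / n
        means = (resp.T @ Z) / nk[:, None]
        for k in range(n_components):
            diff = Z - means[k]
            covs[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            covs[k][np.diag_indices(d)] += ridge
    return weights, means, covs, trace, converged


def fit_gmm(
    data: np.ndarray,
    feature_names: list[str],
    n_components: int,
    seed: int = 0,
    ridge: float = RIDGE,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    restarts: int = EM_RESTARTS,
) -> GaussianMixtureDensity:
    """Fit a full-covariance GMM by EM, best of seeded restarts.

    Features are standardized with the fit data's own mean/std (constant
    features get std treated as 1); each covariance carries a diagonal
    ridge so it stays positive-definite.  Convergence: improvement of the
    average log-likelihood below ``tol``.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise DataError("data shape does not match feature names")
    n, d = X.shape
    if n_components < 1 or n_components > n:
        raise DataError(f"n_components must be in [1, {n}]")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    Z = (X - mean) / std
    log_jac = float(np.sum(np.log(std)))

    rng = np.random.SeedSequence(seed)
    best = None
    for child in rng.spawn(restarts):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            w, m, c, trace, conv = _em_once(
                Z, n_components, sub_seed, ridge, tol, max_iter, log_jac
            )
        except np.linalg.LinAlgError as exc:
            raise DataError(f"singular covariance during EM: {exc}") from exc
        if best is None or trace[-1] > best[3][-1]:
            best = (w, m, c, trace, conv)
    w, m, c, trace, conv = best
    return GaussianMixtureDensity(
        n_components=n_components,
        weights=w,
        means=m,
        covariances=c,
        feature_names=list(feature_names),
        scale_mean=mean,
        scale_std=std,
        fit_log_likelihood_trace=trace,
        converged=conv,
        seed=seed,
    )


def avg_log_likelihood(gmm: GaussianMixtureDensity, data: np.ndarray) -> float:
    """Mean per-row mixture log density of the data (original units)."""
    return float(gmm.log_densities(data).mean())


def bic(gmm: GaussianMixtureDensity, data: np.ndarray) -> float:
    """−2·(total log-likelihood) + p·ln(n), p = (K−1) + K·d + K·d·(d+1)/2."""
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise DataError("BIC needs at least 2 rows")
    total_ll = float(gmm.log_densities(X).sum())
    return -2.0 * total_ll + gmm.n_parameters * np.log(n)


def select_components(
    data: np.ndarray,
    feature_names: list[str],
    k_max: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, list[float]]:
    """Scan K = 1..k_max, return (argmin-BIC K, BIC curve).

    Ties go to the smaller K.  A K whose fit fails numerically is skipped
    (recorded as NaN in the curve).
    """
    X = np.asarray(data, dtype=float)
    if k_max < 1 or k_max > X.shape[0]:
        raise DataError("k_max must be in [1, n_rows]")
    children = np.random.SeedSequence(seed).spawn(k_max)
    curve: list[float] = []
    for k, child in zip(range(1, k_max + 1), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            gmm = fit_gmm(X, feature_names, k, seed=sub_seed, **fit_kwargs)
            curve.append(bic(gmm, X))
        except DataError:
            curve.append(float("nan"))
    finite = [(b, k + 1) for k, b in enumerate(curve) if np.isfinite(b)]
    if not finite:
        raise DataError("every component count failed to fit")
    best_k = min(finite)[1]
    return best_k, curve


# ---------------------------------------------------------------------------
# Composite model
# ---------------------------------------------------------------------------

@dataclass
class RoutingDecision:
    imine_avg_loglik: float
    nucleophile_avg_loglik: float
    imine_high: bool
    nucleophile_high: bool
    chosen: RoutedPredictor

    def to_dict(self) -> dict:
        return {
            "imine_avg_loglik": self.imine_avg_loglik,
            "nucleophile_avg_loglik": self.nucleophile_avg_loglik,
            "imine_high": self.imine_high,
            "nucleophile_high": self.nucleophile_high,
            "chosen": self.chosen.value,
        }


#: default hyperparameters of the three guarded predictors (the tuned
#: settings of the corresponding standalone models)
DEFAULT_COMPOSITE_SETTINGS: dict[RoutedPredictor, HyperparameterSetting] = {
    RoutedPredictor.OVERALL_SVR: HyperparameterSetting("C", 9.99),
    RoutedPredictor.NUCLEOPHILE_RF: HyperparameterSetting("num_trees", 28),
    RoutedPredictor.LASSO: HyperparameterSetting("alpha", 0.016),
}


@dataclass
class CompositeModel:
    overall_svr: TrainedRegressor
    nucleophile_rf: TrainedRegressor
    lasso_all: TrainedRegressor
    nucleophile_gmm: GaussianMixtureDensity
    imine_gmm: GaussianMixtureDensity
    threshold: float = DEFAULT_THRESHOLD

    def predictor(self, which: RoutedPredictor) -> TrainedRegressor:
        return {
            RoutedPredictor.OVERALL_SVR: self.overall_svr,
            RoutedPredictor.NUCLEOPHILE_RF: self.nucleophile_rf,
            RoutedPredictor.LASSO: self.lasso_all,
        }[RoutedPredictor(which)]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.overall_svr.save(directory / "overall_svr.joblib")
        self.nucleophile_rf.save(directory / "nucleophile_rf.joblib")
        self.lasso_all.save(directory / "lasso_all.joblib")
        for name, gmm in (("nucleophile_gmm", self.nucleophile_gmm),
                          ("imine_gmm", self.imine_gmm)):
            (directory / f"{name}.json").write_text(json.dumps(gmm.to_dict()))
        manifest = {
            "schema": 1,
            "threshold": self.threshold,
            "nucleophile_features": self.nucleophile_gmm.feature_names,
            "imine_features": self.imine_gmm.feature_names,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "CompositeModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        return cls(
            overall_svr=TrainedRegressor.load(directory / "overall_svr.joblib"),
            nucleophile_rf=TrainedRegressor.load(directory / "nucleophile_rf.joblib"),
            lasso_all=TrainedRegressor.load(directory / "lasso_all.joblib"),
            nucleophile_gmm=GaussianMixtureDensity.from_dict(
                json.loads((directory / "nucleophile_gmm.json").read_text())
            ),
            imine_gmm=GaussianMixtureDensity.from_dict(
                json.loads((directory / "imine_gmm.json").read_text())
            ),
            threshold=float(manifest["threshold"]),
        )


def _check_role(table: ReactionFeatureTable, names: list[str], role: MoleculeRole) -> None:
    for name in names:
        if name not in table.feature_roles:
            raise SchemaError(f"feature {name!r} not in table")
        if table.feature_roles[name] is not role:
            raise SchemaError(f"feature {name!r} is not a {role.value} descriptor")


def build_composite(
    table: ReactionFeatureTable,
    settings: dict | None = None,
    nucleophile_feature_names: list[str] | None = None,
    imine_feature_names: list[str] | None = None,
    k_max: int = 20,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> CompositeModel:
    """Train the three guarded predictors and fit both key-feature GMMs.

    The GMM component counts are chosen by :func:`select_components` on
    the training rows.  Predictor hyperparameters default to the tuned
    settings of the standalone models.
    """
    if table.target is None:
        raise DataError("composite training needs a labeled table")
    nucleophile_feature_names = list(
        nucleophile_feature_names or DEFAULT_NUCLEOPHILE_FEATURES
    )
    imine_feature_names = list(imine_feature_names or DEFAULT_IMINE_FEATURES)
    _check_role(table, nucleophile_feature_names, MoleculeRole.NUCLEOPHILE)
    _check_role(table, imine_feature_names, MoleculeRole.IMINE)
    hp = dict(DEFAULT_COMPOSITE_SETTINGS)
    if settings:
        hp.update({RoutedPredictor(k): v for k, v in settings.items()})

    ss = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss]
    svr = regressors.fit(
        RegressorKind.SVR, table, hp[RoutedPredictor.OVERALL_SVR],
        view=FeatureView.ALL, seed=seeds[0],
    )
    rf = regressors.fit(
        RegressorKind.RANDOM_FOREST, table, hp[RoutedPredictor.NUCLEOPHILE_RF],
        view=FeatureView.EXCLUDE_IMINE, seed=seeds[1],
    )
    lasso = regressors.fit(
        RegressorKind.LASSO, table, hp[RoutedPredictor.LASSO],
        view=FeatureView.ALL, seed=seeds[2],
    )

    nu_data = table.column_matrix(nucleophile_feature_names)
    im_data = table.column_matrix(imine_feature_names)
    nu_k, _ = select_components(nu_data, nucleophile_feature_names, k_max, seed=seeds[3])
    im_k, _ = select_components(im_data, imine_feature_names, k_max, seed=seeds[4])
    nu_gmm = fit_gmm(nu_data, nucleophile_feature_names, nu_k, seed=seeds[3])
    im_gmm = fit_gmm(im_data, imine_feature_names, im_k, seed=seeds[4])
    return CompositeModel(
        overall_svr=svr,
        nucleophile_rf=rf,
        lasso_all=lasso,
        nucleophile_gmm=nu_gmm,
        imine_gmm=im_gmm,
        threshold=threshold,
    )


def route(composite: CompositeModel, test_table: ReactionFeatureTable) -> RoutingDecision:
    """One set-level routing decision for a whole test table."""
    if test_table.n_reactions == 0:
        raise DataError("cannot route an empty test set")
    nu_ll = avg_log_likelihood(
        composite.nucleophile_gmm,
        test_table.column_matrix(composite.nucleophile_gmm.feature_names),
    )
    im_ll = avg_log_likelihood(
        composite.imine_gmm,
        test_table.column_matrix(composite.imine_gmm.feature_names),
    )
    return _decide(composite.threshold, nu_ll, im_ll)


def _decide(threshold: float, nu_ll: float, im_ll: float) -> RoutingDecision:
    nu_high = nu_ll > threshold
    im_high = im_ll > threshold
    if not nu_high:
        chosen = RoutedPredictor.LASSO
    elif not im_high:
        chosen = RoutedPredictor.NUCLEOPHILE_RF
    else:
        chosen = RoutedPredictor.OVERALL_SVR
    return RoutingDecision(
        imine_avg_loglik=im_ll,
        nucleophile_avg_loglik=nu_ll,
        imine_high=im_high,
        nucleophile_high=nu_high,
        chosen=chosen,
    )


def predict_composite(
    composite: CompositeModel,
    test_table: ReactionFeatureTable,
    per_reaction: bool = False,
) -> tuple[np.ndarray, RoutingDecision | list[RoutingDecision]]:
    """Route, then predict with the chosen model.

    By default the decision is made once for the whole test set (each
    reaction-type group gets a single predictor).  With
    ``per_reaction=True`` every row is routed on its own likelihoods.
    """
    if not per_reaction:
        decision = route(composite, test_table)
        model = composite.predictor(decision.chosen)
        return model.predict(test_table), decision

    nu = composite.nucleophile_gmm.log_densities(
        test_table.column_matrix(composite.nucleophile_gmm.feature_names)
    )
    im = composite.imine_gmm.log_densities(
        test_table.column_matrix(composite.imine_gmm.feature_names)
    )
    decisions = [_decide(composite.threshold, n, i) for n, i in zip(nu, im)]
    preds = np.empty(test_table.n_reactions)
    for which in RoutedPredictor:
        idx = [r for r, d in enumerate(decisions) if d.chosen is which]
        if idx:
            preds[idx] = composite.predictor(which).predict(test_table)[idx]
    return preds, decisions


def routing_report(
    composite: CompositeModel, test_table: ReactionFeatureTable
) -> dict:
    """JSON-ready report: decision plus per-set MSE/R² when labeled."""
    preds, decision = predict_composite(composite, test_table)
    report = {
        "source_label": test_table.source_label,
        "n_reactions": test_table.n_reactions,
        "decision": decision.to_dict(),
        "predictions": preds.tolist(),
    }
    if test_table.target is not None:
        report["mse"] = mse(test_table.target, preds)
        report["r2"] = r_squared(test_table.target, preds)
    return report
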
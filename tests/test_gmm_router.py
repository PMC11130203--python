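import math

import numpy as np
import pytest
from scipy import stats

from enantioselect.core_data import DataError, SchemaError
from enantioselect.gmm_router import (
    CompositeModel,
    GaussianMixtureDensity,
    RoutedPredictor,
    _decide,
    avg_log_likelihood,
    bic,
    build_composite,
    fit_gmm,
    predict_composite,
    route,
    routing_report,
    select_components,
)
from enantioselect.synthetic_data import SyntheticSpec, generate


def two_cluster_data(seed=0, n=400, d=2, sep=5.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    a = rng.standard_normal((half, d)) - sep
    b = rng.standard_normal((n - half, d)) + sep
    return np.vstack([a, b])


class TestFitGmm:
    def test_single_component_matches_closed_form(self):
        # K=1 EM converges in one step to the sample mean/covariance; the
        # average log-likelihood has an exact Gaussian closed form.
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 3)) * np.array([1.0, 2.0, 0.5]) + 1.0
        gmm = fit_gmm(X, ["a", "b", "c"], 1, seed=0)
        mean = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=0)
        oracle = stats.multivariate_normal(mean, cov, allow_singular=False)
        mine = avg_log_likelihood(gmm, X)
        # ridge 1e-6 on the standardized diagonal perturbs at ~1e-6
        assert mine == pytest.approx(float(oracle.logpdf(X).mean()), abs=1e-4)

    def test_one_dimensional_single_gaussian_exact_value(self):
        rng = np.random.default_rng(2)
        x = (3.0 + 0.7 * rng.standard_normal(1000)).reshape(-1, 1)
        gmm = fit_gmm(x, ["f"], 1, seed=0)
        mu, sd = x.mean(), x.std()
        expected = -0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5
        assert avg_log_likelihood(gmm, x) == pytest.approx(expected, abs=1e-4)

    def test_em_trace_is_monotone_nondecreasing(self):
        X = two_cluster_data(seed=3, sep=1.5)
        for k in (2, 3, 4):
            gmm = fit_gmm(X, ["x", "y"], k, seed=4)
            trace = gmm.fit_log_likelihood_trace
            assert all(b - a >= -1e-7 for a, b in zip(trace, trace[1:]))
            assert gmm.converged
            assert avg_log_likelihood(gmm, X) == pytest.approx(trace[-1], abs=1e-8)

    def test_well_separated_clusters_recovered(self):
        X = two_cluster_data(seed=5, n=600, sep=5.0)
        gmm = fit_gmm(X, ["x", "y"], 2, seed=6)
        # undo the fit-time standardization to compare in original units
        found = np.sort(
            (gmm.means * gmm.scale_std + gmm.scale_mean)[:, 0]
        )
        np.testing.assert_allclose(found, [-5.0, 5.0], atol=0.15)
        np.testing.assert_allclose(np.sort(gmm.weights), [0.5, 0.5], atol=0.05)

    def test_far_point_has_tiny_likelihood(self):
        X = two_cluster_data(seed=7)
        gmm = fit_gmm(X, ["x", "y"], 2, seed=8)
        inside = avg_log_likelihood(gmm, X)
        outlier = avg_log_likelihood(gmm, np.array([[50.0, -50.0]]))
        assert outlier < inside - 50

    def test_one_dimensional_density_integrates_to_one(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-2, 0.5, 300), rng.normal(3, 1.0, 300)])
        gmm = fit_gmm(x.reshape(-1, 1), ["f"], 2, seed=10)
        grid = np.linspace(-15, 15, 20001).reshape(-1, 1)
        dens = np.exp(gmm.log_densities(grid))
        assert np.trapezoid(dens, grid[:, 0]) == pytest.approx(1.0, abs=1e-4)

    def test_deterministic_and_serializable(self):
        X = two_cluster_data(seed=11, n=200)
        a = fit_gmm(X, ["x", "y"], 2, seed=12)
        b = fit_gmm(X, ["x", "y"], 2, seed=12)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.means, b.means)
        back = GaussianMixtureDensity.from_dict(a.to_dict())
        np.testing.assert_allclose(back.log_densities(X), a.log_densities(X),
                                   rtol=1e-12)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(DataError):
            fit_gmm(np.ones((10, 2)), ["only_one"], 1)
        with pytest.raises(DataError):
            fit_gmm(np.ones((5, 2)), ["a", "b"], 6)
        with pytest.raises(DataError):
            fit_gmm(np.ones((5, 2)), ["a", "b"], 0)


class TestBic:
    def test_parameter_count_formula(self):
        X = two_cluster_data(seed=13, n=100, d=3)
        for k in (1, 2, 4):
            gmm = fit_gmm(X, ["a", "b", "c"], k, seed=0)
            assert gmm.n_parameters == (k - 1) + k * 3 + k * 3 * 4 // 2

    def test_matches_independent_oracle(self):
        X = two_cluster_data(seed=14, n=300)
        gmm = fit_gmm(X, ["x", "y"], 2, seed=15)
        total_ll = float(gmm.log_densities(X).sum())
        oracle = -2.0 * total_ll + gmm.n_parameters * math.log(300)
        assert bic(gmm, X) == pytest.approx(oracle, rel=1e-12)

    def test_close_to_sklearn_reference_fit(self):
        from sklearn.mixture import GaussianMixture

        X = two_cluster_data(seed=16, n=500)
        gmm = fit_gmm(X, ["x", "y"], 2, seed=17)
        sk = GaussianMixture(2, covariance_type="full", n_init=5,
                             random_state=0, reg_covar=1e-6).fit(X)
        # sklearn fits in original units; both should reach the same optimum
        assert avg_log_likelihood(gmm, X) == pytest.approx(
            float(sk.score(X)), abs=0.02
        )
        assert bic(gmm, X) == pytest.approx(float(sk.bic(X)), rel=2e-3)

    def test_select_components_single_gaussian(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((300, 2))
        k, curve = select_components(X, ["x", "y"], k_max=5, seed=19)
        assert k == 1
        assert len(curve) == 5

    def test_select_components_recovers_three_clusters(self):
        rng = np.random.default_rng(20)
        X = np.vstack([
            rng.standard_normal((200, 2)) * 0.3 + c
            for c in ([-4, 0], [0, 4], [4, 0])
        ])
        k, curve = select_components(X, ["x", "y"], k_max=6, seed=21)
        assert k == 3
        assert curve[2] == min(b for b in curve if np.isfinite(b))

    def test_bic_needs_rows_and_kmax_bounds(self):
        X = two_cluster_data(seed=22, n=50)
        gmm = fit_gmm(X, ["x", "y"], 1, seed=0)
        with pytest.raises(DataError):
            bic(gmm, X[:1])
        with pytest.raises(DataError):
            select_components(X, ["x", "y"], k_max=0)


class TestRoutingRule:
    @pytest.mark.parametrize(
        "nu,im,expected",
        [
            (5.0, 5.0, RoutedPredictor.OVERALL_SVR),
            (5.0, -2.0, RoutedPredictor.NUCLEOPHILE_RF),
            (-2.0, 5.0, RoutedPredictor.LASSO),
            (-2.0, -2.0, RoutedPredictor.LASSO),
            # exactly at the threshold is *not* high (strict >)
            (1.0, 5.0, RoutedPredictor.LASSO),
            (5.0, 1.0, RoutedPredictor.NUCLEOPHILE_RF),
        ],
    )
    def test_decision_table(self, nu, im, expected):
        decision = _decide(1.0, nu, im)
        assert decision.chosen is expected
        assert decision.nucleophile_high == (nu > 1.0)
        assert decision.imine_high == (im > 1.0)


@pytest.fixture(scope="module")
def composite(small_pair_mod):
    train, _ = small_pair_mod
    return build_composite(train, k_max=10, seed=0)


@pytest.fixture(scope="module")
def small_pair_mod():
    return generate(SyntheticSpec(seed=7, n_train=120, n_test=20,
                                  cluster_count_per_role=6))


class TestComposite:
    def test_components_have_expected_views(self, composite):
        assert composite.overall_svr.kind.value == "svr"
        assert composite.nucleophile_rf.kind.value == "random_forest"
        assert composite.lasso_all.kind.value == "lasso"
        assert len(composite.nucleophile_rf.feature_names) == 260
        assert len(composite.overall_svr.feature_names) == 282
        assert composite.nucleophile_gmm.feature_names == [
            "H-X-Nu", "H-X-CNu", "Nu", "Polarizability"
        ]
        assert composite.imine_gmm.feature_names == ["C", "N", "SL", "LUMO"]

    def test_in_distribution_routes_to_svr(self, composite, small_pair_mod):
        _, test = small_pair_mod
        decision = route(composite, test)
        assert decision.chosen is RoutedPredictor.OVERALL_SVR
        assert decision.nucleophile_avg_loglik > 1.0
        assert decision.imine_avg_loglik > 1.0

    def test_imine_shift_routes_to_nucleophile_rf(self, composite):
        _, shifted = generate(SyntheticSpec(seed=7, n_train=120, n_test=20,
                                            cluster_count_per_role=6,
                                            shift_kind="imine_shift"))
        decision = route(composite, shifted)
        assert decision.chosen is RoutedPredictor.NUCLEOPHILE_RF

    def test_nucleophile_shift_routes_to_lasso(self, composite):
        _, shifted = generate(SyntheticSpec(seed=7, n_train=120, n_test=20,
                                            cluster_count_per_role=6,
                                            shift_kind="nucleophile_shift"))
        decision = route(composite, shifted)
        assert decision.chosen is RoutedPredictor.LASSO

    def test_set_prediction_matches_chosen_predictor(self, composite, small_pair_mod):
        _, test = small_pair_mod
        preds, decision = predict_composite(composite, test)
        direct = composite.predictor(decision.chosen).predict(test)
        np.testing.assert_array_equal(preds, direct)

    def test_per_reaction_routing_agrees_rowwise(self, composite, small_pair_mod):
        _, test = small_pair_mod
        preds, decisions = predict_composite(composite, test, per_reaction=True)
        assert len(decisions) == test.n_reactions
        for r, d in enumerate(decisions):
            row = composite.predictor(d.chosen).predict(test)[r]
            assert preds[r] == row

    def test_build_is_deterministic(self, small_pair_mod):
        train, test = small_pair_mod
        a = build_composite(train, k_max=6, seed=3)
        b = build_composite(train, k_max=6, seed=3)
        pa, _ = predict_composite(a, test)
        pb, _ = predict_composite(b, test)
        np.testing.assert_array_equal(pa, pb)

    def test_save_load_round_trip(self, composite, small_pair_mod, tmp_path):
        _, test = small_pair_mod
        composite.save(tmp_path / "model")
        loaded = CompositeModel.load(tmp_path / "model")
        pa, da = predict_composite(composite, test)
        pb, db = predict_composite(loaded, test)
        np.testing.assert_array_equal(pa, pb)
        assert da.chosen is db.chosen
        assert loaded.threshold == composite.threshold

    def test_routing_report_contains_scores_when_labeled(self, composite, small_pair_mod):
        import json

        _, test = small_pair_mod
        report = routing_report(composite, test)
        json.dumps(report)  # must be JSON-serializable as-is
        assert report["n_reactions"] == 20
        assert report["decision"]["chosen"] == "overall_svr"
        assert report["mse"] >= 0
        assert report["r2"] <= 1

    def test_unlabeled_train_and_wrong_role_features_rejected(self, small_pair_mod):
        train, _ = small_pair_mod
        with pytest.raises(SchemaError):
            build_composite(train, nucleophile_feature_names=["C"])
        unlabeled = generate(SyntheticSpec(seed=7, n_train=120, n_test=20,
                                           cluster_count_per_role=6))[0]
        unlabeled.target = None
        with pytest.raises(DataError):
            build_composite(unlabeled)
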
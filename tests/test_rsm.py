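"""Response-surface fitting, fit statistics, prediction and optimisation."""

import numpy as np
import pytest

from sfeperf import datasets
from sfeperf.design import build_ccd
from sfeperf.exceptions import RankDeficiencyError
from sfeperf.rsm import (
    ResponseSurfaceRegressor,
    anova,
    fit_model,
    model_terms,
    optimize_response,
    predict_at,
)


@pytest.fixture(scope="module")
def yield_fit(table, frame):
    # module-scoped copies of the two published fits
    est = fit_model(table, frame["yield_pct"], "2fi")
    anova(est, table, frame["yield_pct"].to_numpy())
    return est


@pytest.fixture(scope="module")
def sol_fit(table, frame):
    est = fit_model(table, frame["solubility_e3"], "quadratic")
    anova(est, table, frame["solubility_e3"].to_numpy())
    return est


# reuse session fixtures at module scope
@pytest.fixture(scope="module")
def table():
    return datasets.load_design_table()


@pytest.fixture(scope="module")
def frame():
    return datasets.load_design_response()


class TestFitStatistics:
    def test_yield_2fi_matches_published_statistics(self, yield_fit):
        assert yield_fit.r2_ == pytest.approx(0.9529, abs=0.05)
        assert yield_fit.adj_r2_ == pytest.approx(0.9312, abs=0.05)
        assert yield_fit.pred_r2_ == pytest.approx(0.8932, abs=0.05)
        coefs = dict(zip(yield_fit.terms_, yield_fit.coef_))
        assert coefs["A"] == pytest.approx(3.20, abs=0.15)
        assert coefs["AC"] == pytest.approx(2.11, abs=0.15)

    def test_solubility_quadratic_matches_published_r2(self, sol_fit):
        assert sol_fit.r2_ == pytest.approx(0.8621, abs=0.05)

    def test_model_f_tests_significant(self, yield_fit, sol_fit):
        assert yield_fit.f_pvalue_ < 0.0001
        assert sol_fit.f_pvalue_ < 0.05

    def test_pressure_and_water_drive_both_responses(self, yield_fit, sol_fit):
        for est in (yield_fit, sol_fit):
            assert est.term_pvalues_["A"] < 0.05
            assert est.term_pvalues_["C"] < 0.05
            assert est.term_pvalues_["AC"] < 0.05

    def test_r2_matches_independent_residual_sum(self, yield_fit, table, frame):
        # recompute R^2 from the coefficients alone, bypassing statsmodels
        y = frame["yield_pct"].to_numpy()
        pred = yield_fit.predict(table.coded_matrix())
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert yield_fit.r2_ == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_r2_ordering(self, yield_fit, sol_fit):
        for est in (yield_fit, sol_fit):
            assert est.pred_r2_ <= est.adj_r2_ <= est.r2_

    def test_constant_response_flagged_degenerate(self, table):
        est = fit_model(table, np.full(20, 3.14), "2fi")
        assert est.degenerate_response_
        assert np.isnan(est.r2_)
        assert est.coef_ == pytest.approx(np.zeros(6), abs=1e-9)

    def test_rank_deficient_matrix_names_terms(self, table):
        X = table.coded_matrix().copy()
        X[:, 1] = X[:, 0]  # B duplicates A
        est = ResponseSurfaceRegressor(order="linear")
        with pytest.raises(RankDeficiencyError) as err:
            est.fit(X, np.arange(20.0))
        assert set(err.value.collinear_terms) & {"A", "B"}


class TestLackOfFit:
    def test_pure_error_df_from_center_replicates(self, yield_fit, table, frame):
        lof = yield_fit.lack_of_fit_
        assert lof.available
        assert lof.df_pure_error == 5  # six centre replicates

    def test_yield_lack_of_fit_not_significant(self, yield_fit):
        # published p = 0.4441: the 2FI model is adequate for yield
        assert yield_fit.lack_of_fit_.p_value > 0.05

    def test_solubility_lack_of_fit_significant(self, sol_fit):
        # published p = 0.0050
        assert sol_fit.lack_of_fit_.p_value < 0.05

    def test_no_replicates_reported_unavailable(self, factors):
        design = build_ccd(factors, n_center=1)
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(design))
        est = fit_model(design, y, "linear")
        lof = est.anova_(design.coded_matrix(), y)
        assert not lof.available
        assert "replicat" in lof.reason


class TestPrediction:
    def test_published_comparison_points(self, sol_fit, table):
        # the two operating points compared across assessment methods
        assert predict_at(sol_fit, (24, 68.8, 29.8), table.factors) == pytest.approx(
            1.89, abs=0.3
        )
        assert predict_at(sol_fit, (21, 65, 33), table.factors) == pytest.approx(
            1.30, abs=0.3
        )

    def test_center_prediction_is_intercept(self, sol_fit, table):
        assert predict_at(sol_fit, (21, 65, 20), table.factors) == pytest.approx(
            sol_fit.intercept_
        )

    def test_design_point_predictions_are_ols_fitted_values(
        self, yield_fit, table, frame
    ):
        # hat-matrix identity: predict at design points == X beta
        y = frame["yield_pct"].to_numpy()
        X = table.coded_matrix()
        pred = yield_fit.predict(X)
        resid = y - pred
        assert resid == pytest.approx(yield_fit.residuals_, abs=1e-9)

    def test_outside_design_region_warns(self, sol_fit, table):
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_at(sol_fit, (30, 65, 20), table.factors)


class TestSyntheticRecovery:
    def test_noiseless_coefficients_recovered_exactly(self, factors):
        design = build_ccd(factors, n_center=6)
        truth = (1.0, 3.2, 1.1, 3.1, -0.05, 2.1, 0.8)
        spec = datasets.SyntheticSpec(design, "2fi", truth, noise_sd=0.0, seed=0)
        resp = datasets.generate_response(spec)
        est = fit_model(design, resp["value"], "2fi")
        fitted = np.concatenate([[est.intercept_], est.coef_])
        assert fitted == pytest.approx(np.array(truth), abs=1e-9)

    def test_coefficient_rmse_monotone_in_noise(self, factors):
        design = build_ccd(factors, n_center=6)
        truth = np.array([1.0, 3.2, 1.1, 3.1, -0.05, 2.1, 0.8])
        rmses = []
        for sigma in (0.5, 0.1, 0.01):
            errs = []
            for seed in range(50):
                spec = datasets.SyntheticSpec(
                    design, "2fi", tuple(truth), noise_sd=sigma, seed=seed
                )
                est = fit_model(design, datasets.generate_response(spec)["value"], "2fi")
                fitted = np.concatenate([[est.intercept_], est.coef_])
                errs.append(np.sqrt(np.mean((fitted - truth) ** 2)))
            rmses.append(np.mean(errs))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_null_response_term_rejection_near_alpha(self, factors):
        # pure-noise responses: each term should reject at roughly the 5% level
        design = build_ccd(factors, n_center=6)
        rng = np.random.default_rng(12345)
        rejections = []
        for _ in range(100):
            y = rng.normal(size=len(design))
            est = fit_model(design, y, "2fi")
            rejections.extend(p < 0.05 for p in est.term_pvalues_.values())
        rate = np.mean(rejections)
        assert 0.01 < rate < 0.12


class TestOptimize:
    def test_concave_toy_quadratic_analytic_argmax(self, toy_factors):
        # -A^2 - B^2 - C^2 + 2A has its maximum at coded (1, 0, 0)
        est = ResponseSurfaceRegressor(order="quadratic")
        design = build_ccd(toy_factors, n_center=1)
        X = design.coded_matrix()
        beta = (0.0, 2.0, 0, 0, 0, 0, 0, -1.0, -1.0, -1.0)
        spec = datasets.SyntheticSpec(design, "quadratic", beta, 0.0, 0)
        est.fit(X, datasets.generate_response(spec)["value"].to_numpy())
        opt, val = optimize_response(est, toy_factors, bounds=[(-1.5, 1.5)] * 3)
        assert opt == pytest.approx([1.0, 0.0, 0.0], abs=1e-5)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_oracle_on_random_quadratics(self, toy_factors):
        design = build_ccd(toy_factors, n_center=1)
        rng = np.random.default_rng(7)
        grid_axis = np.linspace(-1.5, 1.5, 51)
        G = np.array(np.meshgrid(grid_axis, grid_axis, grid_axis)).reshape(3, -1).T
        for _ in range(5):
            beta = tuple(rng.normal(size=10))
            spec = datasets.SyntheticSpec(design, "quadratic", beta, 0.0, 0)
            est = ResponseSurfaceRegressor(order="quadratic").fit(
                design.coded_matrix(),
                datasets.generate_response(spec)["value"].to_numpy(),
            )
            _, val = optimize_response(est, toy_factors, bounds=[(-1.5, 1.5)] * 3)
            grid_best = est.predict(G).max()
            assert val >= grid_best - 1e-6

    def test_2fi_maximum_lands_on_boundary(self, toy_factors):
        design = build_ccd(toy_factors, n_center=1)
        spec = datasets.SyntheticSpec(
            design, "2fi", (0.0, 1.0, 0.5, -0.5, 0, 0, 0), 0.0, 0
        )
        est = ResponseSurfaceRegressor(order="2fi").fit(
            design.coded_matrix(),
            datasets.generate_response(spec)["value"].to_numpy(),
        )
        opt, _ = optimize_response(est, toy_factors, bounds=[(-1, 1)] * 3)
        coded = opt  # toy factors have center 0, step 1
        assert np.max(np.abs(coded)) == pytest.approx(1.0, abs=1e-6)


def test_model_terms_enumeration():
    assert model_terms("linear") == ["A", "B", "C"]
    assert model_terms("2fi") == ["A", "B", "C", "AB", "AC", "BC"]
    assert model_terms("quadratic")[-3:] == ["A^2", "B^2", "C^2"]
    with pytest.raises(ValueError):
        model_terms("cubic")
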
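"""Location-scale fitting, BIC selection, centiles and prevalence."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from tractlat.fp import FPSpec
from tractlat.model import (
    FitOptions,
    centile_curves,
    fit_location_scale,
    prevalence_right,
    select_model,
)
from tractlat.simulate import example_truth, make_cohort_design, simulate_li_observations

from conftest import make_constant_model

PHI_1 = 0.8413447460685429  # standard normal CDF at 1
Z_975 = 1.959963984540054   # standard normal quantile at 0.975


class TestFitting:
    def test_intercept_only_matches_closed_form_mle(self, iid_table):
        m = fit_location_scale(iid_table, FPSpec(()), FPSpec(()),
                               FitOptions(sex_term=False))
        y = iid_table.li.to_numpy()
        assert m.converged
        assert m.mu_intercept == pytest.approx(y.mean(), abs=1e-8)
        # ML scale estimate uses divisor n
        assert np.exp(m.sigma_intercept) == pytest.approx(
            np.sqrt(np.mean((y - y.mean()) ** 2)), abs=1e-8
        )
        assert m.loglik >= -1e308

    def test_duplicated_data_doubles_loglik(self, iid_table):
        opts = FitOptions(sex_term=False)
        m1 = fit_location_scale(iid_table, FPSpec((1.0,)), FPSpec(()), opts)
        doubled = pd.concat([iid_table, iid_table], ignore_index=True)
        m2 = fit_location_scale(doubled, FPSpec((1.0,)), FPSpec(()), opts)
        assert m2.loglik == pytest.approx(2 * m1.loglik, abs=1e-6)
        assert m2.mu_intercept == pytest.approx(m1.mu_intercept, abs=1e-8)
        np.testing.assert_allclose(m2.mu_fp, m1.mu_fp, atol=1e-10)

    def test_loglik_matches_generic_optimizer(self):
        # independent oracle: multi-start Nelder-Mead + BFGS on the same
        # unpenalized likelihood (small n, two cohorts, fixed effects)
        rng = np.random.default_rng(7)
        n = 150
        ages = rng.uniform(0.0, 100.0, n)
        df = pd.DataFrame(
            {"subject_id": "s", "age_years": ages,
             "sex": rng.choice(["female", "male"], n),
             "cohort_id": rng.choice(["c0", "c1"], n), "handedness": "right",
             "li": rng.normal(0.02 + 3e-4 * ages, 0.05)}
        )
        m = fit_location_scale(df, FPSpec((1.0,)), FPSpec((1.0,)),
                               FitOptions(cohort_mode="fixed"))
        y = df.li.to_numpy()
        a = ages + 1.0
        male = (df.sex == "male").to_numpy(float)
        c1 = (df.cohort_id == "c1").to_numpy(float)
        X = np.column_stack([np.ones(n), a, male, c1])

        def nll(theta):
            mu = X @ theta[:4]
            eta = X @ theta[4:]
            return -np.sum(-0.5 * np.log(2 * np.pi) - eta
                           - 0.5 * (y - mu) ** 2 * np.exp(-2 * eta))

        best = np.inf
        for s in range(4):
            r = np.random.default_rng(s)
            x0 = np.concatenate(
                [r.normal(0, 0.02, 4), [np.log(0.05 * r.uniform(0.5, 2))],
                 r.normal(0, 0.001, 3)]
            )
            nm = optimize.minimize(nll, x0, method="Nelder-Mead",
                                   options=dict(maxiter=20000, fatol=1e-12, xatol=1e-10))
            polished = optimize.minimize(nll, nm.x, method="BFGS",
                                         options=dict(gtol=1e-10, maxiter=2000))
            best = min(best, polished.fun)
        assert m.loglik == pytest.approx(-best, abs=1e-6)

    def test_bic_parameter_count_hand_tally(self):
        # 3 cohorts (ridge: one offset each), both sexes, FP orders 2 and 1:
        # k = (1 + 2 + 1 + 3) + (1 + 1 + 1 + 3) = 13
        rng = np.random.default_rng(3)
        n = 600
        df = pd.DataFrame(
            {"subject_id": "s", "age_years": rng.uniform(0, 100, n),
             "sex": rng.choice(["female", "male"], n),
             "cohort_id": rng.choice(["c0", "c1", "c2"], n), "handedness": "right",
             "li": rng.normal(0.0, 0.05, n)}
        )
        m = fit_location_scale(df, FPSpec((0.0, 1.0)), FPSpec((1.0,)),
                               FitOptions(tau2_mu=1e-4, tau2_sigma=1e-3))
        assert m.k == 13
        assert m.bic == pytest.approx(-2 * m.loglik + 13 * np.log(n))
        assert len(m.mu_cohorts) == 3 and len(m.sigma_cohorts) == 3

    def test_age_shift_reparameterization_invariance(self, iid_table):
        # adding c to all ages while subtracting c from age_offset leaves the
        # fitted curves unchanged (spec (1) spans the same linear space)
        opts1 = FitOptions(sex_term=False, age_offset=1.0)
        opts2 = FitOptions(sex_term=False, age_offset=-4.0)
        shifted = iid_table.assign(age_years=iid_table.age_years + 5.0)
        m1 = fit_location_scale(iid_table, FPSpec((1.0,)), FPSpec((1.0,)), opts1)
        m2 = fit_location_scale(shifted, FPSpec((1.0,)), FPSpec((1.0,)), opts2)
        grid = np.linspace(0.0, 100.0, 50)
        mu1, s1 = m1.predict(grid, "female")
        mu2, s2 = m2.predict(grid + 5.0, "female")
        np.testing.assert_allclose(mu1, mu2, atol=1e-8)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_loglik_never_below_intercept_only(self, iid_table):
        opts = FitOptions(sex_term=False)
        base = fit_location_scale(iid_table, FPSpec(()), FPSpec(()), opts)
        rich = fit_location_scale(iid_table, FPSpec((0.0, 1.0)), FPSpec((1.0,)), opts)
        assert rich.loglik >= base.loglik - 1e-9

    def test_singular_and_degenerate_inputs(self, iid_table):
        with pytest.raises(ValueError, match="single sex"):
            fit_location_scale(iid_table, FPSpec(()), FPSpec(()),
                               FitOptions(sex_term=True))
        with pytest.raises(ValueError, match="exceed"):
            fit_location_scale(iid_table.head(4), FPSpec((1.0,)), FPSpec((1.0,)),
                               FitOptions(sex_term=False))

    def test_model_serialization_round_trip(self, iid_table):
        from tractlat.model import NormativeModel

        m = fit_location_scale(iid_table, FPSpec((1.0,)), FPSpec(()),
                               FitOptions(sex_term=False))
        clone = NormativeModel.from_dict(m.to_dict())
        grid = np.linspace(0, 100, 20)
        np.testing.assert_allclose(clone.predict(grid)[0], m.predict(grid)[0])
        assert clone.bic == m.bic


@pytest.fixture(scope="module")
def small_obs():
    subjects = make_cohort_design(1, 600, seed=40)
    truth = example_truth("recovery", sorted(subjects.cohort_id.unique()), seed=40)
    return simulate_li_observations(subjects, truth, "AF", "FA", seed=41)


class TestSelection:
    def test_best_model_has_minimal_bic_in_report(self, small_obs):
        result = select_model(small_obs, power_set=(0.0, 1.0), max_order=2)
        converged = result.report[result.report.converged]
        assert result.model.bic == pytest.approx(converged.bic.min())
        assert len(result.report) >= 2 * 5  # both stages recorded

    def test_direct_bic_comparison(self, small_obs):
        # the candidate with smaller −2*loglik + k*ln(n) must win
        r = select_model(small_obs, power_set=(0.0, 1.0), max_order=1)
        rows = r.report[r.report.converged]
        best_row = rows.loc[rows.bic.idxmin()]
        assert r.model.bic == pytest.approx(best_row.bic)
        np.testing.assert_allclose(
            rows.bic, -2 * rows.loglik + rows.k * np.log(r.model.n)
        )

    def test_staged_never_beats_full_grid(self, small_obs):
        staged = select_model(small_obs, power_set=(0.0, 1.0), max_order=2,
                              strategy="staged")
        full = select_model(small_obs, power_set=(0.0, 1.0), max_order=2,
                            strategy="full_grid")
        assert full.model.bic <= staged.model.bic + 1e-9

    def test_quadratic_truth_beats_forced_intercept_only(self):
        # curve recovery (not exact spec identity): the selected model's
        # median RMSE vs truth is smaller than the intercept-only fit's
        subjects = make_cohort_design(10, 500, seed=42)
        cids = sorted(subjects.cohort_id.unique())
        truth = example_truth("quadratic", cids, seed=42)
        obs = simulate_li_observations(subjects, truth, "AF", "FA", seed=43)
        selected = select_model(obs).model
        flat = fit_location_scale(obs, FPSpec(()), FPSpec(()), FitOptions())
        grid = np.linspace(0.0, 100.0, 200)
        mu_truth, _ = truth.mu_sigma(grid)
        rmse_sel = np.sqrt(np.mean((selected.predict(grid, "female")[0] - mu_truth) ** 2))
        rmse_flat = np.sqrt(np.mean((flat.predict(grid, "female")[0] - mu_truth) ** 2))
        assert rmse_sel < rmse_flat


class TestCentilesAndPrevalence:
    def test_standard_normal_quantiles(self):
        model = make_constant_model(mu=0.0, sigma=1.0)
        chart = centile_curves(model, np.linspace(0, 100, 11),
                               levels=(2.5, 50.0, 97.5), context="female",
                               tract="AF", feature="FA")
        np.testing.assert_allclose(chart.values[:, 2], Z_975, rtol=1e-9)
        np.testing.assert_allclose(chart.values[:, 0], -Z_975, rtol=1e-9)

    def test_median_equals_mu_and_band_symmetry(self):
        model = make_constant_model(mu=0.012, sigma=0.04)
        chart = centile_curves(model, np.linspace(0, 100, 7), context="female",
                               tract="AF", feature="FA")
        np.testing.assert_allclose(chart.median(), 0.012, atol=1e-15)
        upper = chart.values[:, chart.level_index(97.5)] - chart.median()
        lower = chart.median() - chart.values[:, chart.level_index(2.5)]
        np.testing.assert_allclose(upper, lower, atol=1e-12)

    def test_centiles_strictly_increase_across_levels(self, iid_table):
        m = fit_location_scale(iid_table, FPSpec((1.0,)), FPSpec((1.0,)),
                               FitOptions(sex_term=False))
        chart = centile_curves(m, context="female", tract="AF", feature="FA")
        assert (np.diff(chart.values, axis=1) > 0).all()

    def test_extrapolation_flagged(self):
        model = make_constant_model(age_range=(10.0, 60.0))
        with pytest.warns(UserWarning, match="support"):
            chart = centile_curves(model, np.linspace(0, 100, 5), context="female",
                                   tract="AF", feature="FA")
        assert chart.meta["extrapolated"]

    def test_prevalence_values(self):
        ages = np.array([10.0, 50.0])
        assert prevalence_right(make_constant_model(0.0, 0.05), ages) == pytest.approx(
            [50.0, 50.0]
        )
        np.testing.assert_allclose(
            prevalence_right(make_constant_model(0.05, 0.05), ages), 100 * PHI_1,
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            prevalence_right(make_constant_model(-0.05, 0.05), ages),
            100 * (1 - PHI_1), rtol=1e-9,
        )

    def test_sex_average_context_averages_quantiles(self):
        model = make_constant_model(mu=0.0, sigma=0.05, sex_effect=0.02)
        mu_avg, _ = model.predict(np.array([30.0]), "average")
        assert mu_avg[0] == pytest.approx(0.01)
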
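"""G-formula estimation: coefficient recovery on family-matched data,
counterfactual simulation behaviour, natural-course diagnostic, bootstrap and
intervention grids."""

import numpy as np
import pytest

from icufluid import (
    GFormulaSpec,
    InterventionSpec,
    NATURAL_COURSE,
    ValidationError,
    bootstrap_ci,
    fit_gformula,
    generate_cohort,
    intervention_grid,
    natural_course_check,
    simulate_risk,
    true_counterfactual_risk,
)
from icufluid.gformula import GFormulaError, observed_cumulative_incidence
from icufluid.schema import PersonDayTable
from conftest import single_phenotype_dgp

# Hazard minimised at -750 mL.  The covariate feedback is disabled
# (alpha2=0) so the total-effect optimum coincides with the hazard optimum,
# and the natural fluid distribution is centred near -750 mL so range
# strategies genuinely straddle it.
U_SHAPE = dict(
    intercept=-4.8, theta_fluid=0.6, theta_fluid2=0.4,
    covar_ar=(0.6, 0.85, 0.0, 1.0),
    treat_model=(-1400.0, 150.0, 1200.0),
)


@pytest.fixture(scope="module")
def ushape_fit():
    specs, traj = single_phenotype_dgp(**U_SHAPE)
    baseline, persondays = generate_cohort(specs, traj, n=5000, seed=100)
    return specs, traj, fit_gformula(baseline, persondays), baseline, persondays


class TestFit:
    def test_recovers_dgp_coefficients_within_3_se(self):
        # full confounded DGP: fluid feeds back into next-day severity
        specs, traj = single_phenotype_dgp(
            intercept=-4.8, theta_fluid=0.6, theta_fluid2=0.4
        )
        baseline, persondays = generate_cohort(specs, traj, n=5000, seed=104)
        fit = fit_gformula(baseline, persondays)
        hz = specs[0].hazard_coefs
        alpha0, alpha1, alpha2, sigma_L = traj.covar_ar
        beta0, betaL, sigma_A = traj.treat_model

        cov = fit.covariate_models["severity"]
        truth_cov = {"const": alpha0, "lag_severity": alpha1, "lag_fluid_l": alpha2, "day": 0.0}
        for name, true_val in truth_cov.items():
            i = cov.names.index(name)
            assert abs(cov.params[i] - true_val) < 3 * cov.bse[i], name
        assert cov.resid_sd == pytest.approx(sigma_L, rel=0.05)

        tr = fit.treatment_model
        truth_tr = {"const": beta0, "severity": betaL, "day": 0.0}
        for name, true_val in truth_tr.items():
            i = tr.names.index(name)
            assert abs(tr.params[i] - true_val) < 3 * tr.bse[i], name
        assert tr.resid_sd == pytest.approx(sigma_A, rel=0.05)

        hzm = fit.hazard_model
        truth_hz = {
            "const": hz.intercept,
            "severity": hz.theta_covar,
            "fluid_l": hz.theta_fluid,
            "fluid_l2": hz.theta_fluid2,
            "day": hz.theta_day,
        }
        for name, true_val in truth_hz.items():
            i = hzm.names.index(name)
            assert abs(hzm.params[i] - true_val) < 3 * hzm.bse[i], name

    def test_permuted_treatment_has_null_hazard_coefficients(self):
        specs, traj = single_phenotype_dgp(**U_SHAPE)
        baseline, persondays = generate_cohort(specs, traj, n=4000, seed=101)
        df = persondays.df.copy()
        rng = np.random.default_rng(0)
        df["fluid_balance"] = rng.permutation(df["fluid_balance"].to_numpy())
        fit = fit_gformula(baseline, PersonDayTable(df))
        hzm = fit.hazard_model
        for name in ("fluid_l", "fluid_l2"):
            i = hzm.names.index(name)
            assert abs(hzm.params[i]) < 3 * hzm.bse[i], name

    def test_constant_covariate_recovered_by_intercept(self):
        specs, traj = single_phenotype_dgp(
            intercept=-3.0, theta_covar=0.0,
            covar_ar=(5.0, 0.0, 0.0, 0.05),  # L_t ~= 5 with negligible noise
        )
        baseline, persondays = generate_cohort(specs, traj, n=1000, seed=5)
        fit = fit_gformula(baseline, persondays)
        cov = fit.covariate_models["severity"]
        X = np.zeros(len(cov.params))
        X[cov.names.index("const")] = 1.0
        # at any lag value the prediction is the constant
        X[cov.names.index("lag_severity")] = 5.0
        assert cov.predict(X[None, :])[0] == pytest.approx(5.0, abs=0.01)

    def test_zero_events_raises(self):
        specs, traj = single_phenotype_dgp(intercept=-50.0, discharge_prob=0.0)
        baseline, persondays = generate_cohort(specs, traj, n=300, seed=0)
        with pytest.raises(GFormulaError, match="hazard"):
            fit_gformula(baseline, persondays)


class TestSimulate:
    def test_forced_negative_intercept_gives_zero_risk(self, ushape_fit):
        _, _, fit, _, _ = ushape_fit
        crippled = GFormulaSpec(horizon=fit.spec.horizon)
        import copy

        f2 = copy.deepcopy(fit)
        f2.hazard_model.params[:] = 0.0
        f2.hazard_model.params[f2.hazard_model.names.index("const")] = -50.0
        est = simulate_risk(f2, NATURAL_COURSE, n_mc=2000, seed=0)
        assert est.point < 1e-10

    def test_null_treatment_coefficients_make_grid_flat(self, ushape_fit):
        _, _, fit, _, _ = ushape_fit
        import copy

        f2 = copy.deepcopy(fit)
        for name in ("fluid_l", "fluid_l2"):
            f2.hazard_model.params[f2.hazard_model.names.index(name)] = 0.0
        # fluid must be inert through the covariate pathway as well
        cov = f2.covariate_models["severity"]
        cov.params[cov.names.index("lag_fluid_l")] = 0.0
        risks = [
            simulate_risk(f2, InterventionSpec(c, c), n_mc=4000, seed=1).point
            for c in (-2000.0, 0.0, 2000.0)
        ]
        assert max(risks) - min(risks) < 0.01

    def test_cumulative_risk_monotone_in_unit_interval(self, ushape_fit):
        _, _, fit, _, _ = ushape_fit
        est = simulate_risk(fit, InterventionSpec(-1000, 500), n_mc=3000, seed=2)
        c = est.cumulative
        assert (np.diff(c) >= -1e-12).all()
        assert (c >= 0).all() and (c <= 1).all()
        assert est.point == c[-1]

    def test_mc_se_shrinks_with_root_n(self, ushape_fit):
        _, _, fit, _, _ = ushape_fit
        se1 = simulate_risk(fit, NATURAL_COURSE, n_mc=4000, seed=3).mc_se
        se2 = simulate_risk(fit, NATURAL_COURSE, n_mc=16000, seed=4).mc_se
        assert se1 / se2 == pytest.approx(2.0, rel=0.25)

    def test_estimates_match_oracle_on_family_data(self, ushape_fit):
        specs, traj, fit, _, _ = ushape_fit
        for iv in (NATURAL_COURSE, InterventionSpec(-1000, -500), InterventionSpec(0, 1000)):
            est = simulate_risk(fit, iv, n_mc=20000, seed=5)
            oracle = true_counterfactual_risk(specs, traj, iv, n_mc=100000, seed=6)
            assert abs(est.point - oracle) <= 0.02, iv.label

    def test_degenerate_clamp_risk_convex_in_level(self, ushape_fit):
        _, _, fit, _, _ = ushape_fit
        levels = [-1500.0, -750.0, 0.0, 750.0, 1500.0]
        risks = [
            simulate_risk(fit, InterventionSpec(a, a), n_mc=20000, seed=7).point
            for a in levels
        ]
        for i in range(1, len(levels) - 1):
            assert risks[i] <= 0.5 * (risks[i - 1] + risks[i + 1]) + 0.005


class TestNaturalCourse:
    def test_self_consistency_on_family_data(self, ushape_fit):
        _, _, fit, _, persondays = ushape_fit
        sim, obs, gap = natural_course_check(fit, persondays, n_mc=20000, seed=8)
        assert gap <= 0.02

    def test_rare_event_data_gives_near_zero_curves(self):
        # hazard ~ 3e-4/day: both curves hug zero (truly zero events cannot
        # be fit at all -- the hazard model refuses, tested separately)
        specs, traj = single_phenotype_dgp(intercept=-8.0, theta_covar=0.0, discharge_prob=0.0)
        baseline, persondays = generate_cohort(specs, traj, n=8000, seed=9)
        with pytest.warns(UserWarning, match="events"):
            fit = fit_gformula(baseline, persondays)
        sim, obs, gap = natural_course_check(fit, persondays, n_mc=2000, seed=10)
        assert obs[-1] < 0.01 and sim[-1] < 0.02

    def test_observed_incidence_matches_km_logic(self, ushape_fit):
        _, _, _, _, persondays = ushape_fit
        obs = observed_cumulative_incidence(persondays, 7)
        assert (np.diff(obs) >= 0).all() and obs[-1] <= 1.0


class TestBootstrap:
    def test_two_replicates_give_ordered_interval(self, ushape_fit):
        _, _, _, baseline, persondays = ushape_fit
        est = bootstrap_ci(
            baseline, persondays, InterventionSpec(-1000, 500),
            n_boot=2, n_mc=500, seed=11,
        )
        assert est.ci_lower <= est.point <= est.ci_upper

    def test_identical_seed_identical_interval(self, ushape_fit):
        _, _, _, baseline, persondays = ushape_fit
        kw = dict(n_boot=5, n_mc=500, seed=12)
        e1 = bootstrap_ci(baseline, persondays, NATURAL_COURSE, **kw)
        e2 = bootstrap_ci(baseline, persondays, NATURAL_COURSE, **kw)
        assert (e1.ci_lower, e1.ci_upper) == (e2.ci_lower, e2.ci_upper)


class TestGrid:
    def test_grid_enumerates_valid_pairs_plus_natural(self, ushape_fit):
        _, _, fit, _, _ = ushape_fit
        bounds = [-3000, -2500, -2000, -1500, -1000, -500, 0, 500, 1000, 1500]
        grid = intervention_grid(fit, bounds, bounds, n_mc=200, seed=13)
        assert len(grid) == 55 + 1  # C(10,2) + 10 diagonal + natural course
        assert np.isinf(grid.iloc[0]["lower"]) and np.isinf(grid.iloc[0]["upper"])

    def test_empty_grid_rejected(self, ushape_fit):
        _, _, fit, _, _ = ushape_fit
        with pytest.raises(ValidationError):
            intervention_grid(fit, [500.0], [-500.0], n_mc=100, seed=0)

    def test_argmin_range_contains_dgp_optimum(self, ushape_fit):
        # hazard minimised at -750 mL by construction
        _, _, fit, _, _ = ushape_fit
        bounds = list(np.arange(-3000.0, 1501.0, 500.0))
        grid = intervention_grid(fit, bounds, bounds, n_mc=20000, seed=14, include_natural=False)
        ranges = grid[grid["lower"] < grid["upper"]]  # fixed-dose cells excluded
        best = ranges.loc[ranges["risk"].idxmin()]
        assert best["lower"] <= -750.0 <= best["upper"]
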
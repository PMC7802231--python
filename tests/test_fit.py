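import numpy as np
import pandas as pd
import pytest

from idfrail.fit import (
    bspline_start,
    cox_breslow_start,
    fit_model,
    select_bspline_model,
    smooth_log_hazard,
    wald_joint_test,
    wald_table,
    weibull_start,
)
from idfrail.hazards import BSplineHazardParams, bspline_basis
from idfrail.likelihood import BaselineSpec, LikelihoodEvaluator, ModelSpec
from idfrail.simulate import reference_design, simulate_dataset


@pytest.fixture(scope="module")
def medium():
    design = reference_design(n=1500, seed=23)
    df, _ = simulate_dataset(design)
    return design, df


@pytest.fixture(scope="module")
def weib_fit(medium):
    design, df = medium
    return fit_model(df, design.model_spec())


def exponential_data(n=600, kappa=0.25, seed=5):
    """Event-free-at-entry survivors of a pure death process (no illness)."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / kappa, size=n)
    c = 8.0
    y = np.minimum(t, c)
    d = (t <= c).astype(int)
    y = np.maximum(y, 1e-6)
    return pd.DataFrame(
        dict(L=0.0, y1=y, delta1=0, y2=y, delta2=d, x=rng.integers(0, 2, n) * 1.0)
    )


class TestWeibullStart:
    def test_exponential_closed_form(self):
        df = exponential_data()
        spec = ModelSpec.weibull([[], [], []], frailty=False)
        xi, beta = weibull_start(df, 2, spec)
        events = df["delta2"].sum()
        exposure = df["y2"].sum()
        # profile out alpha ~ 1; kappa-hat should track the exponential MLE
        assert np.exp(xi[1]) == pytest.approx(events / exposure, rel=0.1)
        assert beta.size == 0

    def test_duplication_invariance(self, medium):
        design, df = medium
        spec = design.model_spec()
        xi1, b1 = weibull_start(df, 1, spec)
        xi2, b2 = weibull_start(pd.concat([df, df], ignore_index=True), 1, spec)
        np.testing.assert_allclose(xi1, xi2, atol=1e-5)
        np.testing.assert_allclose(b1, b2, atol=1e-5)

    def test_recovers_truth_without_frailty(self):
        # with theta = 0 the univariate transition-2 model is correctly
        # specified, so the starting values should land near the truth
        from dataclasses import replace

        design = replace(reference_design(n=2500, seed=29), log_theta=None)
        df, _ = simulate_dataset(design)
        spec = design.model_spec()
        xi, beta = weibull_start(df, 2, spec)
        assert xi[0] == pytest.approx(design.log_alpha[1], abs=0.25)
        assert xi[1] == pytest.approx(design.log_kappa[1], abs=0.8)
        assert beta[0] == pytest.approx(design.beta[1], abs=0.3)

    def test_no_events_error(self):
        df = exponential_data()
        df["delta1"] = 0
        df["delta2"] = 0
        spec = ModelSpec.weibull(["x"])
        with pytest.raises(ValueError, match="transition 2"):
            weibull_start(df, 2, spec)


class TestCoxBreslowStart:
    def test_no_covariate_breslow_equals_nelson_aalen(self, medium):
        design, df = medium
        spec = ModelSpec.weibull([[], [], []])
        _, (times, cumhaz) = cox_breslow_start(df, 1, spec)
        # independent truncation-adjusted Nelson-Aalen
        L = df["L"].to_numpy()
        y = df["y1"].to_numpy()
        d = df["delta1"].to_numpy().astype(bool)
        incr = []
        for t in times:
            n_risk = np.sum((L < t) & (y >= t))
            incr.append(np.sum(d & (y == t)) / n_risk)
        np.testing.assert_allclose(cumhaz, np.cumsum(incr), rtol=1e-12)

    def test_beta_approximates_log_rate_ratio(self):
        rng = np.random.default_rng(17)
        n = 2000
        x = np.repeat([0.0, 1.0], n // 2)
        rate = 0.2 * np.exp(0.7 * x)
        t = rng.exponential(1.0 / rate)
        c = 10.0
        y = np.maximum(np.minimum(t, c), 1e-9)
        df = pd.DataFrame(
            dict(L=0.0, y1=y, delta1=0, y2=y, delta2=(t <= c).astype(int), x=x)
        )
        spec = ModelSpec.weibull(["x"])
        beta, _ = cox_breslow_start(df, 2, spec)
        # closed-form exponential log rate ratio
        lrr = np.log(
            (df.delta2[x == 1].sum() / y[x == 1].sum())
            / (df.delta2[x == 0].sum() / y[x == 0].sum())
        )
        assert beta[0] == pytest.approx(lrr, abs=0.1)

    def test_subject_order_invariance(self, medium):
        design, df = medium
        spec = design.model_spec()
        b1, _ = cox_breslow_start(df, 1, spec)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b2, _ = cox_breslow_start(shuffled, 1, spec)
        np.testing.assert_allclose(b1, b2, atol=1e-8)


class TestSmoothLogHazard:
    def test_constant_hazard_line(self):
        t = np.linspace(0.5, 10, 40)
        grid, logh = smooth_log_hazard(t, 0.4 * t)
        assert len(grid) == 101
        assert np.max(np.abs(logh - np.log(0.4))) < 0.02

    def test_quadratic_cumhaz(self):
        t = np.linspace(0.5, 6, 60)
        grid, logh = smooth_log_hazard(t, t**2)
        inner = slice(15, -15)
        np.testing.assert_allclose(
            logh[inner], np.log(2 * grid[inner]), atol=0.05
        )

    def test_too_few_events(self):
        with pytest.raises(ValueError, match="Weibull"):
            smooth_log_hazard(np.array([1.0, 2, 3, 3]), np.array([0.1, 0.2, 0.3, 0.3]))


class TestBsplineStart:
    BASE = BaselineSpec(
        "bspline", degree=2, boundary_knots=(0.0, 10.0), interior_knots=(3.0, 6.0)
    )

    def test_exact_spline_recovery(self):
        rng = np.random.default_rng(2)
        truth = rng.normal(size=self.BASE.n_params)
        p = BSplineHazardParams(2, (0.0, 10.0), (3.0, 6.0), truth)
        grid = np.linspace(0, 10, 80)
        target = bspline_basis(grid, 2, p) @ truth
        eta = bspline_start(grid, target, self.BASE)
        np.testing.assert_allclose(eta, truth, atol=1e-8)

    def test_constant_target(self):
        grid = np.linspace(0, 10, 50)
        eta = bspline_start(grid, np.full(50, -1.3), self.BASE)
        p = BSplineHazardParams(2, (0.0, 10.0), (3.0, 6.0), eta)
        fitted = bspline_basis(grid, 2, p) @ eta
        np.testing.assert_allclose(fitted, -1.3, atol=1e-8)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(0, 10, 70)
        target = np.sin(grid / 3.0) - 1.0 + 0.05 * rng.standard_normal(70)
        eta = bspline_start(grid, target, self.BASE)
        p = BSplineHazardParams(2, (0.0, 10.0), (3.0, 6.0), np.zeros(5))
        D = bspline_basis(grid, 2, p)
        eta_ne = np.linalg.solve(D.T @ D, D.T @ target)
        np.testing.assert_allclose(eta, eta_ne, atol=1e-9)

    def test_rank_deficient_grid(self):
        grid = np.linspace(0.0, 2.0, 30)  # never enters the last segments
        with pytest.raises(ValueError, match="rank"):
            bspline_start(grid, np.zeros(30), self.BASE)


class TestFitModel:
    def test_no_frailty_exponential_closed_form(self):
        df = exponential_data(n=800)
        # give transition 1 (and 3) events so all transitions are identifiable
        df.loc[:40, "delta1"] = 1
        df.loc[:40, "y2"] = df.loc[:40, "y1"] + 0.5
        df.loc[:40, "delta2"] = 0
        df.loc[:15, "delta2"] = 1
        spec = ModelSpec.weibull([[], [], []], frailty=False)
        # fix the shapes at 1 (exponential) by fitting free and checking the
        # transition-2 rate against the closed-form cause-specific MLE
        fit = fit_model(df, spec)
        assert fit.converged
        names = fit.parameter_names
        m2 = (df.delta1 == 0) & (df.delta2 == 1)
        exposure = df.y1.sum()  # everyone at risk of transition 2 until y1
        kappa_mle = m2.sum() / exposure
        alpha2 = np.exp(fit.phi[names.index("log_alpha2")])
        kappa2 = np.exp(fit.phi[names.index("log_kappa2")])
        assert alpha2 == pytest.approx(1.0, abs=0.15)
        assert kappa2 == pytest.approx(kappa_mle, rel=0.25)

    def test_loglik_never_below_start(self, weib_fit, medium):
        design, df = medium
        ev = LikelihoodEvaluator(df, design.model_spec())
        assert weib_fit.loglik >= ev.total_loglik(weib_fit.start) - 1e-8

    def test_parameter_recovery_within_4_se(self, weib_fit, medium):
        design, _ = medium
        truth = design.true_parameters().to_array()
        z = np.abs(weib_fit.phi - truth) / weib_fit.se
        assert np.all(z < 4.0), dict(zip(weib_fit.parameter_names, z))

    def test_gradient_small_at_optimum(self, weib_fit):
        assert weib_fit.converged
        assert weib_fit.grad_norm < 1e-4 * (1 + abs(weib_fit.loglik))

    def test_refit_from_optimum_is_fixed_point(self, weib_fit, medium):
        design, df = medium
        refit = fit_model(df, design.model_spec(), start=weib_fit.phi)
        np.testing.assert_allclose(refit.phi, weib_fit.phi, atol=2e-3)
        assert refit.loglik == pytest.approx(weib_fit.loglik, abs=1e-6)

    def test_time_rescaling_covariance(self, medium):
        """Multiplying all times by c leaves beta and theta unchanged and
        rescales Weibull kappa by c^-alpha (alpha unchanged)."""
        design, df = medium
        fit1 = fit_model(df, design.model_spec(), compute_covariance=False)
        c = 5.0
        df5 = df.copy()
        for col in ("L", "y1", "y2"):
            df5[col] = df5[col] * c
        spec5 = ModelSpec.weibull(["x"], time_scale=c)
        fit5 = fit_model(df5, spec5, compute_covariance=False)
        np.testing.assert_allclose(fit5.phi, fit1.phi, atol=2e-3)
        # and fitting the c-scaled data with time_scale 1: kappa -> kappa c^-alpha
        spec_raw = ModelSpec.weibull(["x"])
        fit_raw = fit_model(df5, spec_raw, compute_covariance=False)
        names = fit1.parameter_names
        for k in (1, 2, 3):
            ia = names.index(f"log_alpha{k}")
            ik = names.index(f"log_kappa{k}")
            assert fit_raw.phi[ia] == pytest.approx(fit1.phi[ia], abs=0.02)
            expected_lk = fit1.phi[ik] - np.exp(fit1.phi[ia]) * np.log(c)
            assert fit_raw.phi[ik] == pytest.approx(expected_lk, abs=0.05)
        for nm in ("beta1_x", "beta2_x", "beta3_x", "log_theta"):
            j = names.index(nm)
            assert fit_raw.phi[j] == pytest.approx(fit1.phi[j], abs=0.02)

    def test_nonfinite_start_rejected(self, medium):
        design, df = medium
        bad = np.full(10, 60.0)
        with pytest.raises(ValueError, match="starting"):
            fit_model(df, design.model_spec(), start=bad)


class TestWaldInference:
    def test_closed_form_hr(self, weib_fit):
        table = wald_table(weib_fit)
        # verify the HR transform against the textbook formula on one row
        row = table[table.parameter == "beta2_x"].iloc[0]
        assert row.hr == pytest.approx(np.exp(row.estimate))
        assert row.hr_lower == pytest.approx(np.exp(row.estimate - 1.959964 * row.se), rel=1e-6)
        # frozen closed-form example: beta=0.5, se=0.1, 95% Wald
        z = 1.959964
        assert np.exp(0.5) == pytest.approx(1.64872, abs=1e-4)
        assert np.exp(0.5 - z * 0.1) == pytest.approx(1.35527, abs=1e-4)
        assert np.exp(0.5 + z * 0.1) == pytest.approx(2.00573, abs=1e-4)

    def test_matches_delta_method(self, weib_fit):
        table = wald_table(weib_fit)
        for _, row in table.iterrows():
            if "hr" in row and np.isfinite(row.get("hr", np.nan)):
                se_hr = row.hr * row.se  # delta method on exp
                width_ratio = (row.hr_upper - row.hr_lower) / (2 * 1.959964 * se_hr)
                # exp CI is wider than the symmetric delta CI but comparable
                assert 0.9 < width_ratio < 1.2

    def test_single_contrast_equals_z_squared(self, weib_fit):
        j = weib_fit.parameter_names.index("beta2_x")
        C = np.zeros((1, len(weib_fit.phi)))
        C[0, j] = 1.0
        chi2, df, p = wald_joint_test(weib_fit, C)
        t = wald_table(weib_fit)
        z = t[t.parameter == "beta2_x"].z.iloc[0]
        assert chi2 == pytest.approx(z**2, rel=1e-10)
        assert df == 1

    def test_zero_row_rejected(self, weib_fit):
        C = np.zeros((1, len(weib_fit.phi)))
        with pytest.raises(ValueError, match="zero"):
            wald_joint_test(weib_fit, C)

    def test_joint_test_null_rate(self):
        """2-df Wald test on two null covariates rejects at ~5%."""
        rng = np.random.default_rng(77)
        rejections = 0
        R = 40
        for r in range(R):
            design = reference_design(n=400, seed=3000 + r)
            df, _ = simulate_dataset(design)
            df["z1"] = rng.standard_normal(len(df))
            df["z2"] = rng.standard_normal(len(df))
            spec = ModelSpec.weibull(
                [["x", "z1", "z2"], ["x"], ["x"]], frailty=False
            )
            fit = fit_model(df, spec)
            names = fit.parameter_names
            C = np.zeros((2, len(fit.phi)))
            C[0, names.index("beta1_z1")] = 1.0
            C[1, names.index("beta1_z2")] = 1.0
            _, _, p = wald_joint_test(fit, C)
            rejections += p < 0.05
        # binomial(40, 0.05): reject between 0 and 7 times with prob > 0.999
        assert rejections <= 7


class TestSplineSelection:
    def test_single_candidate_returned(self, medium):
        _, df = medium
        best, fits = select_bspline_model(
            df, ["x"], candidates=[((1, 1, 1), (1, 1, 1))], compute_covariance=False
        )
        assert len(fits) == 1 and best is list(fits.values())[0]

    def test_tie_breaks_to_fewest_parameters(self, medium):
        _, df = medium
        best, fits = select_bspline_model(
            df,
            ["x"],
            candidates=[((1, 1, 1), (1, 1, 1)), ((1, 1, 1), (2, 2, 2))],
            compute_covariance=False,
        )
        lls = {k: f.loglik for k, f in fits.items()}
        key_best = max(lls, key=lambda k: lls[k])
        assert best.loglik == pytest.approx(lls[key_best])


class TestNumericalDerivatives:
    def test_hessian_recovers_analytic_quadratic(self):
        from idfrail.fit import _numerical_hessian

        Q = np.array([[4.0, 1.0, 0.5], [1.0, 3.0, -0.2], [0.5, -0.2, 2.0]])
        b = np.array([0.3, -1.0, 2.0])
        f = lambda x: 0.5 * x @ Q @ x + b @ x
        H = _numerical_hessian(f, np.array([0.7, -0.2, 1.4]))
        np.testing.assert_allclose(H, Q, rtol=1e-5, atol=1e-5)

    def test_gradient_matches_analytic(self):
        from idfrail.fit import _numerical_gradient

        f = lambda x: np.sin(x[0]) + x[1] ** 3
        g = _numerical_gradient(f, np.array([0.4, 1.2]))
        np.testing.assert_allclose(g, [np.cos(0.4), 3 * 1.2**2], rtol=1e-6)
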
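"""Penalized-spline logistic mixed model: basis, PIRLS, smoothing, quintiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from omegadose.gamm import (
    GammConvergenceError,
    _assemble,
    _bernoulli_loglik,
    _penalty_matrix,
    _pirls,
    DoseResponseFit,
    build_basis,
    fit_gamm,
    fit_quintiles,
    quintile_assign,
    select_smoothing,
    smooth_wald_test,
)


def sim_logit(n, f, seed=0, covariate=False):
    rng = np.random.default_rng(seed)
    z = rng.normal(0.5, 0.8, n)
    eta = f(z)
    cov = None
    if covariate:
        g = rng.choice(["a", "b"], size=n)
        eta = eta + 0.4 * (g == "b")
        cov = pd.DataFrame({"g": g})
    y = (rng.random(n) < expit(eta)).astype(float)
    return z, y, cov


class TestBasis:
    def test_partition_of_unity(self, rng):
        x = rng.uniform(-1, 3, 500)
        basis = build_basis(x, n_basis=10)
        B = basis.design(x)
        assert B.shape == (500, 10)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_reproduces_cubic_polynomial(self, rng):
        x = rng.uniform(0, 1, 400)
        basis = build_basis(x, n_basis=10)
        B = basis.design(x)
        y = 2.0 - x + 3 * x**2 - 0.5 * x**3
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        assert np.max(np.abs(B @ coef - y)) < 1e-9

    def test_evaluation_clips_outside_range(self, rng):
        x = rng.uniform(0, 1, 100)
        basis = build_basis(x, n_basis=8)
        lo, hi = basis.range
        np.testing.assert_allclose(basis.design([lo - 5.0]), basis.design([lo]))
        np.testing.assert_allclose(basis.design([hi + 5.0]), basis.design([hi]))

    def test_quantile_knots_invariant_to_input_order(self, rng):
        x = rng.uniform(0, 1, 300)
        a = build_basis(x, n_basis=10)
        b = build_basis(x[::-1], n_basis=10)
        np.testing.assert_array_equal(a.knots, b.knots)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_basis([0.0, 1.0, 2.0], n_basis=10)

    def test_penalty_null_space_is_exactly_linear(self, rng):
        """Second-order penalty vanishes on linear functions, even with unequal knots."""
        x = rng.lognormal(0.5, 0.7, 400)
        basis = build_basis(np.log(x), n_basis=10)
        S = basis.penalty()
        t = basis.greville()
        for coefs in (np.ones_like(t), t, 3.0 - 2.0 * t):
            assert coefs @ S @ coefs == pytest.approx(0.0, abs=1e-10)
        # and it is positive on a genuinely curved coefficient vector
        assert t**2 @ S @ t**2 > 1e-6

    def test_coefficients_linear_in_greville_sites_give_linear_function(self, rng):
        x = rng.lognormal(0.5, 0.7, 400)
        basis = build_basis(np.log(x), n_basis=10)
        t = basis.greville()
        lo, hi = basis.range
        grid = np.linspace(lo, hi, 50)
        vals = basis.design(grid) @ (0.7 + 1.3 * t)
        np.testing.assert_allclose(vals, 0.7 + 1.3 * grid, atol=1e-10)


class TestPirls:
    def test_matches_generic_optimizer_of_same_objective(self):
        """Inner fit agrees with BFGS on the penalized log-likelihood."""
        z, y, cov = sim_logit(800, lambda z: -1.0 + 0.3 * (z - 0.5) ** 2, covariate=True)
        basis = build_basis(z, n_basis=8)
        X, _, _, Sc, sl_f, sl_s, sl_c, _ = _assemble(z, cov, None, basis)
        P = _penalty_matrix(X.shape[1], sl_s, sl_c, Sc, lam=2.0, sigma2_u=1e-300)

        def objective(b):
            return -_bernoulli_loglik(y, X @ b) + 0.5 * b @ P @ b

        def gradient(b):
            from scipy.special import expit

            return -X.T @ (y - expit(X @ b)) + P @ b

        beta_pirls, *_ = _pirls(X, y, P)
        res = minimize(objective, np.zeros(X.shape[1]), jac=gradient, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 2000})
        assert np.max(np.abs(beta_pirls - res.x)) < 1e-6
        assert objective(beta_pirls) <= res.fun + 1e-9

    def test_penalized_deviance_decreases_with_iterations(self):
        z, y, _ = sim_logit(600, lambda z: -1.0 + 0.5 * z)
        basis = build_basis(z, n_basis=8)
        X, _, _, Sc, sl_f, sl_s, sl_c, _ = _assemble(z, None, None, basis)
        P = _penalty_matrix(X.shape[1], sl_s, sl_c, Sc, lam=1.0, sigma2_u=1e-300)
        devs = []
        for k in range(1, 7):
            beta, _, loglik, *_ = _pirls(X, y, P, max_iter=k)
            devs.append(-2 * loglik + beta @ P @ beta)
        assert all(b <= a + 1e-9 for a, b in zip(devs, devs[1:]))


class TestFitGamm:
    def test_input_validation(self):
        z = np.linspace(0, 1, 50)
        y = np.zeros(50)
        y[::2] = 1
        with pytest.raises(ValueError, match="binary"):
            fit_gamm(z, z, None, None, lam=1.0, sigma2_u=0.0, n_basis=6)
        with pytest.raises(ValueError, match="lam"):
            fit_gamm(z, y, None, None, lam=0.0, sigma2_u=0.0, n_basis=6)
        with pytest.raises(ValueError, match="sigma2_u"):
            fit_gamm(z, y, None, None, lam=1.0, sigma2_u=-1.0, n_basis=6)

    def test_smooth_sums_to_zero_over_sample(self):
        z, y, _ = sim_logit(1000, lambda z: -1.0 + 0.4 * (z - 0.5) ** 2)
        fit = fit_gamm(z, y, None, None, lam=1.0, sigma2_u=0.0)
        assert abs(fit.spline_values(z).sum()) < 1e-8

    def test_heavy_penalty_reduces_smooth_to_line(self):
        """lam -> infinity leaves only the penalty null space: a straight line."""
        z, y, _ = sim_logit(2000, lambda z: -1.0 + 0.6 * z, seed=1)
        fit = fit_gamm(z, y, None, None, lam=1e8, sigma2_u=0.0)
        grid = np.linspace(*fit.basis.range, 60)
        vals = fit.spline_values(grid)
        # second differences on an equally spaced grid vanish for a line
        assert np.max(np.abs(np.diff(vals, n=2))) < 1e-4 * max(np.ptp(vals), 1.0)
        # and the effective degrees of freedom collapse toward the null space
        assert fit.edf_smooth < 1.2

    def test_vanishing_variance_component_recovers_fixed_effects_fit(self):
        z, y, cov = sim_logit(2000, lambda z: -1.2 + 0.3 * z, seed=2, covariate=True)
        centres = np.random.default_rng(3).integers(1, 6, size=2000)
        with_re = fit_gamm(z, y, cov, centres, lam=5.0, sigma2_u=1e-10)
        without = fit_gamm(z, y, cov, None, lam=5.0, sigma2_u=0.0)
        k = without.beta.shape[0]
        assert np.max(np.abs(with_re.beta[:k] - without.beta)) < 1e-6
        assert np.max(np.abs(with_re.random_intercepts)) < 1e-6

    def test_random_intercepts_shrink_with_smaller_variance(self):
        rng = np.random.default_rng(4)
        z, y, _ = sim_logit(3000, lambda z: -1.0 + 0.0 * z, seed=4)
        centres = rng.integers(1, 9, size=3000)
        y = (rng.random(3000) < expit(-1.0 + 0.8 * (centres % 2))).astype(float)
        tight = fit_gamm(z, y, None, centres, lam=5.0, sigma2_u=0.01)
        loose = fit_gamm(z, y, None, centres, lam=5.0, sigma2_u=1.0)
        assert np.abs(tight.random_intercepts).max() < np.abs(loose.random_intercepts).max()

    def test_separation_is_flagged(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, 400)
        y = (z > 0).astype(float)  # perfectly separable in z
        fit = fit_gamm(z, y, None, None, lam=0.01, sigma2_u=0.0)
        assert fit.separation

    def test_save_load_round_trip(self, tmp_path):
        z, y, cov = sim_logit(800, lambda z: -1.0 + 0.3 * z, covariate=True)
        centres = np.random.default_rng(0).integers(1, 4, size=800)
        fit = fit_gamm(z, y, cov, centres, lam=2.0, sigma2_u=0.1)
        fit.save(tmp_path / "fit")
        back = DoseResponseFit.load(tmp_path / "fit")
        grid = np.linspace(z.min(), z.max(), 20)
        np.testing.assert_allclose(back.spline_values(grid), fit.spline_values(grid))
        np.testing.assert_allclose(back.mean_design_row(0.3), fit.mean_design_row(0.3))
        assert back.lam == fit.lam and back.sigma2_u == fit.sigma2_u


class TestSelectSmoothing:
    def test_linear_truth_selects_heavy_smoothing(self):
        z, y, _ = sim_logit(20000, lambda z: -1.5 + 0.4 * z, seed=6)
        fit, trace = select_smoothing(z, y, None, None)
        assert fit.edf_smooth < 2.5
        assert {"lam", "sigma2_u", "criterion"} <= set(trace.columns)
        assert len(trace) > 21

    def test_curved_truth_keeps_extra_degrees_of_freedom(self):
        z, y, _ = sim_logit(20000, lambda z: -1.5 + 0.5 * (z - 0.5) ** 2, seed=7)
        fit, _ = select_smoothing(z, y, None, None)
        assert fit.edf_smooth > 2.5

    def test_selection_is_deterministic(self):
        z, y, _ = sim_logit(4000, lambda z: -1.5 + 0.3 * z, seed=8)
        a, ta = select_smoothing(z, y, None, None)
        b, tb = select_smoothing(z, y, None, None)
        assert a.lam == b.lam and a.sigma2_u == b.sigma2_u
        pd.testing.assert_frame_equal(ta, tb)

    def test_aic_criterion_available(self):
        z, y, _ = sim_logit(3000, lambda z: -1.5 + 0.3 * z, seed=9)
        fit, _ = select_smoothing(z, y, None, None, criterion="aic")
        assert fit.lam > 0
        with pytest.raises(ValueError, match="criterion"):
            select_smoothing(z, y, None, None, criterion="gcv")


class TestWaldTest:
    def test_null_smooth_rarely_significant(self):
        """Type-I error of the smooth Wald test stays near nominal under the null."""
        n_sig = 0
        for rep in range(50):
            z, y, _ = sim_logit(20000, lambda z: -1.7 + 0.0 * z, seed=100 + rep)
            fit = fit_gamm(z, y, None, None, lam=10.0, sigma2_u=0.0)
            _, _, p = smooth_wald_test(fit)
            n_sig += p < 0.05
        assert n_sig <= 5  # >= 90% non-significant

    def test_strong_signal_detected(self):
        z, y, _ = sim_logit(20000, lambda z: -1.5 + 0.8 * (z - 0.5) ** 2, seed=10)
        fit = fit_gamm(z, y, None, None, lam=10.0, sigma2_u=0.0)
        stat, df, p = smooth_wald_test(fit)
        assert p < 1e-4 and df >= 1.0


class TestQuintiles:
    def test_balanced_assignment_and_cutpoints(self, rng):
        x = rng.normal(0, 1, 1000)
        q, cuts = quintile_assign(x)
        assert np.bincount(q, minlength=6)[1:].tolist() == [200] * 5
        assert (np.diff(cuts) > 0).all()
        # every value in quintile 2 lies between the first two cut points
        assert x[q == 2].min() >= x[q == 1].max()

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            quintile_assign([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])

    def test_reference_has_unit_odds_ratio(self, rng):
        x = rng.normal(0, 1, 2000)
        y = (rng.random(2000) < 0.2).astype(float)
        qf = fit_quintiles(x, y, None, None, reference=3)
        assert qf.odds_ratio(3) == 1.0
        assert qf.reference == 3

    def test_unadjusted_fit_matches_contingency_table_oracle(self):
        """Saturated quintile logistic reproduces the 2x2 odds ratios exactly."""
        n = 5000
        x = np.arange(n, dtype=float)  # quintiles are contiguous blocks
        events = {1: 20, 2: 50, 3: 10, 4: 40, 5: 60}
        y = np.zeros(n)
        for k, cnt in events.items():
            y[(k - 1) * 1000 : (k - 1) * 1000 + cnt] = 1.0
        qf = fit_quintiles(x, y, None, None, reference=3)
        for k, cnt in events.items():
            expected = (cnt / (1000 - cnt)) / (events[3] / (1000 - events[3]))
            assert qf.odds_ratio(k) == pytest.approx(expected, rel=1e-6)

    def test_decreasing_risk_orders_extreme_quintiles(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            x = rng.lognormal(0.5, 0.6, 4000)
            p = expit(-1.5 - 0.5 * np.log(x))
            y = (rng.random(4000) < p).astype(float)
            qf = fit_quintiles(x, y, None, None, reference=3)
            hits += qf.odds_ratio(1) > qf.odds_ratio(5)
        assert hits >= 9

    def test_invalid_reference_rejected(self, rng):
        with pytest.raises(ValueError, match="reference"):
            fit_quintiles(rng.normal(size=100), np.zeros(100), None, None, reference=0)
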
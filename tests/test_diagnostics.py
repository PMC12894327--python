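"""Profile CIs, dependency, R² family and bands against closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

import sabrefit as sf
from sabrefit.fitting import FitOptions, GenericCurveProblem, fit_problem


def _linear_fit(n=25, a=5.0, b=2.0, sd=0.8, seed=3):
    """Straight line y = a + b*x with small noise, fitted via the engine."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 10.0, n)
    y = a + b * x + rng.normal(0, sd, n)
    problem = GenericCurveProblem(
        lambda th, xv: th[0] + th[1] * xv,
        x,
        y,
        names=["a", "b"],
        lower=[-1e6, -1e6],
        upper=[1e6, 1e6],
    )
    fit = fit_problem(problem, np.array([0.0, 0.0]), FitOptions(multistart=1))
    assert fit.converged
    return fit, x, y


def _ols_slope_ci(x, y, level=0.95):
    """Textbook t-based CI for the slope of simple linear regression."""
    n = x.size
    bhat = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    ahat = y.mean() - bhat * x.mean()
    resid = y - ahat - bhat * x
    s2 = resid @ resid / (n - 2)
    se_b = np.sqrt(s2 / ((x - x.mean()) ** 2).sum())
    t = stats.t.ppf(0.5 + level / 2, n - 2)
    return ahat, bhat, (bhat - t * se_b, bhat + t * se_b), s2


class TestProfileCI:
    def test_matches_t_based_interval_for_linear_model(self):
        """On a quadratic SSR surface the profile CI is the textbook CI."""
        fit, x, y = _linear_fit()
        _, bhat, (lo, hi), _ = _ols_slope_ci(x, y)
        assert fit.values["b"] == pytest.approx(bhat, rel=1e-8)
        ci = sf.profile_ci(fit, "b")
        assert ci.lower == pytest.approx(lo, abs=1e-6)
        assert ci.upper == pytest.approx(hi, abs=1e-6)

    def test_contains_best_fit_value(self, noisy_fit):
        for name in noisy_fit.names:
            ci = sf.profile_ci(noisy_fit, name)
            assert ci.contains(noisy_fit.values[name])

    def test_parameter_without_influence_has_both_ends_open(self):
        """A flat SSR profile never crosses the threshold: open interval."""
        rng = np.random.default_rng(1)
        x = np.linspace(0, 5, 12)
        y = 2.0 * x + rng.normal(0, 0.3, x.size)
        problem = GenericCurveProblem(
            lambda th, xv: th[0] * xv + 0.0 * th[1],  # th[1] is inert
            x,
            y,
            names=["slope", "dead"],
            lower=[-100.0, -10.0],
            upper=[100.0, 10.0],
        )
        fit = fit_problem(problem, np.array([1.0, 0.0]), FitOptions(multistart=1))
        ci = sf.profile_ci(fit, "dead")
        assert ci.open_lower and ci.open_upper
        assert "?" in str(ci)

    def test_never_narrower_than_wald_on_well_conditioned_fit(self, noisy_fit):
        tcrit = stats.t.ppf(0.975, noisy_fit.dof)
        for name in noisy_fit.names:
            ci = sf.profile_ci(noisy_fit, name)
            if ci.open_lower or ci.open_upper:
                continue
            wald = 2 * tcrit * noisy_fit.se[name]
            assert (ci.upper - ci.lower) >= wald * (1 - 1e-3)

    def test_unknown_parameter_rejected(self, noisy_fit):
        with pytest.raises(KeyError):
            sf.profile_ci(noisy_fit, "nope")


class _CovStub:
    """Minimal fit-like object for covariance-only diagnostics."""

    def __init__(self, cov, names):
        self.covariance = np.asarray(cov, dtype=float)
        self.names = names
        self.rank_deficient = False


class TestDependency:
    def test_uncorrelated_estimates_have_zero_dependency(self):
        deps = sf.dependency(_CovStub(np.diag([2.0, 5.0]), ["a", "b"]))
        assert deps == {"a": 0.0, "b": 0.0}

    def test_two_parameter_closed_form_is_r_squared(self):
        r = 0.9
        cov = np.array([[1.0, r], [r, 1.0]])
        deps = sf.dependency(_CovStub(cov, ["a", "b"]))
        assert deps["a"] == pytest.approx(r**2, abs=1e-12)
        assert deps["b"] == pytest.approx(r**2, abs=1e-12)

    def test_invariant_to_parameter_rescaling(self):
        cov = np.array([[4.0, 1.0, 0.5], [1.0, 2.0, 0.3], [0.5, 0.3, 1.0]])
        scale = np.diag([100.0, 0.01, 1.0])
        deps_a = sf.dependency(_CovStub(cov, ["a", "b", "c"]))
        deps_b = sf.dependency(_CovStub(scale @ cov @ scale, ["a", "b", "c"]))
        for k in deps_a:
            assert deps_b[k] == pytest.approx(deps_a[k], rel=1e-9)

    def test_redundant_parameters_detected_and_flagged(self):
        """Two parameters entering only as a sum are perfectly dependent."""
        rng = np.random.default_rng(8)
        x = np.linspace(0, 5, 20)
        y = 3.0 * x + rng.normal(0, 0.2, x.size)
        problem = GenericCurveProblem(
            lambda th, xv: (th[0] + th[1]) * xv,
            x,
            y,
            names=["b1", "b2"],
            lower=[-100, -100],
            upper=[100, 100],
        )
        fit = fit_problem(problem, np.array([1.0, 1.0]), FitOptions(multistart=1))
        deps = sf.dependency(fit)
        assert min(deps.values()) >= 0.9999
        flags, notes, overall = sf.flag_ambiguous(deps)
        assert overall and all(flags.values())


class TestAmbiguityFlags:
    def test_thresholds(self):
        deps = {"a": 0.5, "b": 0.95, "c": 0.995, "d": 1.0}
        flags, notes, overall = sf.flag_ambiguous(deps)
        assert notes == {
            "a": "",
            "b": "high",
            "c": "unacceptably high",
            "d": "unacceptably high",
        }
        assert flags == {"a": False, "b": False, "c": False, "d": True}
        assert overall

    def test_all_moderate_no_flags(self):
        flags, notes, overall = sf.flag_ambiguous({"a": 0.2, "b": 0.9})
        assert not overall and not any(flags.values())
        assert notes == {"a": "", "b": ""}


class TestRSquared:
    def test_perfect_fit_gives_unity(self, noise_free_fit):
        r2_ind, r2_g, r2_adj = sf.r_squared(noise_free_fit)
        for v in r2_ind.values():
            assert v == pytest.approx(1.0, abs=1e-9)
        assert r2_g == pytest.approx(1.0, abs=1e-9)
        assert r2_adj == pytest.approx(1.0, abs=1e-9)

    def test_adjustment_arithmetic(self):
        """1 - 0.1*99/94 for R2 = 0.9, N = 100, K = 5 (direct arithmetic)."""

        class Stub:
            pass

        y = np.concatenate([np.zeros(50), np.ones(50)])  # SST = 25
        fit = Stub()
        fit.problem = Stub()
        fit.problem.y = y
        fit.problem.slices = {"d": slice(0, 100)}
        fit.ssr = 2.5  # makes R2_global = 0.9
        fit.per_dataset_residuals = {"d": np.zeros(100)}
        fit.n_points, fit.k_free = 100, 5
        _, r2_g, r2_adj = sf.r_squared(fit)
        assert r2_g == pytest.approx(0.9, abs=1e-12)
        assert r2_adj == pytest.approx(1 - 0.1 * 99 / 94, abs=1e-12)
        fit.k_free = 0  # formula degenerates to the global value
        _, r2_g0, r2_adj0 = sf.r_squared(fit)
        assert r2_adj0 == r2_g0

    def test_adjusted_below_global_when_parameters_cost(self, noisy_fit):
        _, r2_g, r2_adj = sf.r_squared(noisy_fit)
        assert r2_adj < r2_g < 1.0


class TestBands:
    def test_match_closed_form_linear_bands(self):
        fit, x, y = _linear_fit()
        ahat, bhat, _, s2 = _ols_slope_ci(x, y)
        grid = np.linspace(0.5, 9.5, 7)
        b = sf.bands(fit, "data", grid)
        n = x.size
        sxx = ((x - x.mean()) ** 2).sum()
        t = stats.t.ppf(0.975, n - 2)
        half_conf = t * np.sqrt(s2 * (1.0 / n + (grid - x.mean()) ** 2 / sxx))
        half_pred = t * np.sqrt(s2 * (1.0 + 1.0 / n + (grid - x.mean()) ** 2 / sxx))
        np.testing.assert_allclose(b["yhat"], ahat + bhat * grid, atol=1e-6)
        np.testing.assert_allclose(b["conf_upper"] - b["yhat"], half_conf, atol=1e-6)
        np.testing.assert_allclose(b["pred_upper"] - b["yhat"], half_pred, atol=1e-6)

    def test_prediction_band_strictly_contains_confidence_band(self, noisy_fit):
        grid = np.linspace(-9, -3.5, 23)
        for label in noisy_fit.problem.slices:
            b = sf.bands(noisy_fit, label, grid)
            assert np.all(b["pred_upper"] > b["conf_upper"])
            assert np.all(b["pred_lower"] < b["conf_lower"])
            assert np.all(b["conf_upper"] >= b["yhat"])

    def test_bands_collapse_as_noise_vanishes(self, noise_free_fit):
        grid = np.linspace(-9, -3.5, 11)
        b = sf.bands(noise_free_fit, "NECA:N", grid)
        assert np.max(b["pred_upper"] - b["pred_lower"]) < 1e-4


def test_report_assembles_all_pieces(noisy_fit):
    report = sf.diagnostics_report(noisy_fit, compute_ci=False)
    assert set(report.dependency) == set(noisy_fit.names)
    assert set(report.r2_individual) == set(noisy_fit.problem.slices)
    assert report.r2_adjusted < report.r2_global
    assert not report.ambiguous_fit
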
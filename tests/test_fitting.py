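"""The global least-squares engine: recovery, oracles, invariances."""

import numpy as np
import pytest

import sabrefit as sf
from sabrefit.core import SabreParams, sabre_response
from sabrefit.data import ECDataset, ECPoint
from sabrefit.fitting import SabreProblem
from sabrefit.plan import ParamSpec

TRUTH = {
    "gamma": 85.43,
    "q": 0.22,
    "logKd_NECA": -5.84,
    "logKd_CPA": -6.09,
    "logKd_CHA": -5.38,
}


class TestExactRecovery:
    def test_noise_free_parameters_recovered(self, noise_free_fit):
        """Self-consistency: the generator and the model share one equation."""
        assert noise_free_fit.converged
        for name, true in TRUTH.items():
            assert noise_free_fit.values[name] == pytest.approx(true, rel=1e-6)
        assert noise_free_fit.ssr < 1e-12

    def test_dof_accounting(self, noise_free_fit):
        assert noise_free_fit.n_points == 72  # 6 curves x 12 points
        assert noise_free_fit.k_free == 5
        assert noise_free_fit.dof == 67


def _single_curve_dataset(rng, logKd=-6.2, gamma=20.0, eps=0.5, noise=1.0):
    xs = np.arange(-9.0, -3.4, 0.5)
    p = SabreParams(eps=eps, gamma=gamma, n=1.0, logKd=logKd, q=1.0)
    points = [
        ECPoint(x=float(x), y=float(sabre_response(p, x) + rng.normal(0, noise)))
        for x in xs
    ]
    return ECDataset(agonist="NECA", pretreated=False, points=points)


def _two_param_plan(label, eps=0.5):
    # partial-agonist efficacy fixed below 1 makes gamma set the plateau,
    # so (gamma, logKd) are jointly identifiable from one control curve
    scope = frozenset([label])
    return sf.ModelPlan(
        bindings={label: ("NECA", False)},
        params=[
            ParamSpec("gamma", scope),
            ParamSpec("logKd_NECA", scope),
            ParamSpec("eps_NECA", scope, eps),
            ParamSpec("n", scope, 1.0),
        ],
    )


class TestGridSearchOracle:
    def test_optimizer_matches_exhaustive_grid(self):
        """Brute force over (logKd, gamma) agrees to within one grid cell."""
        rng = np.random.default_rng(11)
        ds = _single_curve_dataset(rng)
        plan = _two_param_plan(ds.label)
        fit = sf.fit_global(plan, [ds], options=sf.FitOptions(seed=1))
        assert fit.converged

        logKd_grid = np.linspace(-8.0, -4.0, 400)
        gamma_grid = np.linspace(1.0, 300.0, 400)
        x, y = ds.x, ds.y
        r = 10.0 ** (x[None, None, :] - logKd_grid[None, :, None])
        g = gamma_grid[:, None, None]
        pred = 100.0 * 0.5 * g * r / ((0.5 * g - 0.5 + 1.0) * r + 1.0)
        ssr = ((y[None, None, :] - pred) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(ssr), ssr.shape)
        cell_g = gamma_grid[1] - gamma_grid[0]
        cell_k = logKd_grid[1] - logKd_grid[0]
        assert abs(fit.values["gamma"] - gamma_grid[i]) <= cell_g
        assert abs(fit.values["logKd_NECA"] - logKd_grid[j]) <= cell_k
        # and the optimizer is at least as good as the best grid point
        assert fit.ssr <= ssr[i, j] + 1e-9


class TestDegenerateInputs:
    def test_constant_response_flagged_not_crashed(self):
        xs = np.linspace(-9, -4, 10)
        points = [ECPoint(x=float(x), y=0.0) for x in xs]
        ds = ECDataset(agonist="NECA", pretreated=False, points=points)
        plan = _two_param_plan(ds.label)
        fit = sf.fit_global(plan, [ds], options=sf.FitOptions(seed=2))
        deps = sf.dependency(fit)
        assert fit.rank_deficient or max(deps.values()) > 0.9
        _, r2_g, _ = sf.r_squared(fit)
        assert r2_g is None  # constant data: SST = 0 is undefined, not a number

    def test_too_few_points_rejected(self):
        points = [ECPoint(-6.0, 10.0), ECPoint(-5.0, 30.0), ECPoint(-4.0, 60.0)]
        ds = ECDataset(agonist="NECA", pretreated=False, points=points)
        scope = frozenset([ds.label])
        plan = sf.ModelPlan(
            bindings={ds.label: ("NECA", False)},
            params=[
                ParamSpec("gamma", scope),
                ParamSpec("logKd_NECA", scope),
                ParamSpec("eps_NECA", scope),
                ParamSpec("n", scope),
            ],
        )
        with pytest.raises(ValueError, match="N=3, K=4"):
            sf.fit_global(plan, [ds])


class TestInvariances:
    def test_dataset_and_point_order_invariance(self):
        datasets = sf.simulate_furchgott(sf.table1_design(seed=77))
        plan = sf.strategy5_plan(datasets)
        opts = sf.FitOptions(seed=3)
        fit_a = sf.fit_global(plan, datasets, options=opts)

        rng = np.random.default_rng(5)
        shuffled = []
        for ds in reversed(datasets):
            pts = list(ds.points)
            rng.shuffle(pts)
            shuffled.append(
                ECDataset(agonist=ds.agonist, pretreated=ds.pretreated, points=pts)
            )
        fit_b = sf.fit_global(sf.strategy5_plan(shuffled), shuffled, options=opts)
        for name in fit_a.names:
            assert fit_b.values[name] == pytest.approx(fit_a.values[name], abs=1e-10)

    def test_refit_from_optimum_is_a_fixed_point(self, noisy_fit):
        refit = sf.fit_global(
            noisy_fit.plan,
            sf.simulate_furchgott(sf.table1_design()),
            init=noisy_fit.values,
            options=sf.FitOptions(seed=0, multistart=1),
        )
        for name in noisy_fit.names:
            assert refit.values[name] == pytest.approx(noisy_fit.values[name], rel=1e-7)
        assert refit.ssr <= noisy_fit.ssr * (1.0 + 1e-12) + 1e-12

    def test_final_cost_is_the_minimum_cost_seen(self, noisy_fit):
        assert noisy_fit.ssr <= noisy_fit.min_cost_seen + 1e-9

    def test_same_options_reproduce_identical_fit(self):
        datasets = sf.simulate_furchgott(sf.table1_design(seed=9))
        plan = sf.strategy5_plan(datasets)
        f1 = sf.fit_global(plan, datasets, options=sf.FitOptions(seed=4))
        f2 = sf.fit_global(plan, datasets, options=sf.FitOptions(seed=4))
        assert f1.values == f2.values


class TestErrorModelConsistency:
    def test_ssr_over_dof_estimates_noise_variance(self):
        """At N = 288, sigma^2-hat averaged over seeds lands near noise_sd^2."""
        sigma2 = []
        for seed in range(40):
            design = sf.table1_design(replicates=4, noise_sd=4.0, seed=1000 + seed)
            datasets = sf.simulate_furchgott(design)
            plan = sf.strategy5_plan(datasets)
            fit = sf.fit_global(
                plan, datasets, options=sf.FitOptions(seed=seed, multistart=1)
            )
            assert fit.converged
            sigma2.append(fit.sigma2)
        assert np.mean(sigma2) == pytest.approx(16.0, rel=0.2)

    def test_use_means_reduces_point_count(self):
        datasets = sf.simulate_furchgott(sf.table1_design(seed=21))
        plan = sf.strategy5_plan(datasets)
        fit = sf.fit_global(
            plan, datasets, options=sf.FitOptions(use_means=True, multistart=2)
        )
        assert fit.n_points == 72  # 12 mean points per curve
        assert fit.converged


def test_default_init_lands_on_the_right_decade(noise_free_datasets):
    plan = sf.strategy5_plan(noise_free_datasets)
    init = sf.default_init(plan, noise_free_datasets)
    # logKd0 = interpolated log EC50 + log10(gamma0); EC50_NECA ~ 1.7e-8 M
    assert init["gamma"] == 10.0 and init["q"] == 0.5
    assert init["logKd_NECA"] == pytest.approx(np.log10(1.69e-8) + 1.0, abs=0.35)


def test_problem_compilation_resolves_sharing(noise_free_datasets):
    plan = sf.strategy5_plan(noise_free_datasets)
    problem = SabreProblem(plan, noise_free_datasets)
    theta = np.array([85.43, -5.38, -6.09, -5.84, 0.22])
    P = problem.param_matrix(theta)
    # every dataset row: [eps, gamma, n, logKd, q]
    for i, label in enumerate(problem.labels):
        assert P[i, 0] == 1.0 and P[i, 2] == 1.0
        assert P[i, 1] == 85.43
        assert P[i, 4] == (0.22 if label.endswith(":X") else 1.0)
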
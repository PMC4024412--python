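import math

import numpy as np
import pytest
from scipy import optimize, stats

from pkresample import (
    PopParams,
    StudyDesign,
    ebe_modes,
    fit,
    foce_objective,
    simulate_dataset,
)
from pkresample.estimate import (
    LOG2PI,
    _naive_two_stage_init,
    _pk_mean_fn,
    laplace_subject,
)

# ---------------------------------------------------------------------------
# independent oracles


def h_subject(eta, y, t, dose, pop):
    """-2 log joint density of one subject, written independently."""
    cl = pop.theta_cl * math.exp(eta[0])
    v = pop.theta_v * math.exp(eta[1])
    f = dose / v * np.exp(-cl / v * t)
    g = pop.sigma_prop2 * f**2 + pop.sigma_add2
    val = float(np.sum((y - f) ** 2 / g + np.log(g) + LOG2PI))
    for e, w in ((eta[0], pop.omega_cl2), (eta[1], pop.omega_v2)):
        if w > 0:
            val += e**2 / w + math.log(2 * math.pi * w)
    return val


def neg2ll_quadrature(data, pop, n_nodes=21):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    doses = data.doses().set_index("ID")["AMT"]
    obs = data.observations()
    for sid in data.subject_ids:
        sub = obs[obs["ID"] == sid]
        y, t = sub["DV"].to_numpy(), sub["TIME"].to_numpy()
        dose = float(doses.loc[sid])
        fun = lambda e: h_subject(e, y, t, dose, pop)  # noqa: E731
        res = optimize.minimize(fun, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxfev": 4000})
        mode = res.x
        hess = np.empty((2, 2))
        step = 1e-4
        for i in range(2):
            for j in range(2):
                ei, ej = np.eye(2)[i] * step, np.eye(2)[j] * step
                hess[i, j] = (
                    fun(mode + ei + ej) - fun(mode + ei - ej)
                    - fun(mode - ei + ej) + fun(mode - ei - ej)
                ) / (4 * step**2)
        cov = np.linalg.inv(hess / 2.0)
        lchol = np.linalg.cholesky(cov)
        # log integral of exp(-h/2) with importance Gaussian N(mode, cov)
        zz = np.array([[zi, zj] for zi in x for zj in x])
        ww = np.array([wi * wj for wi in w for wj in w])
        etas = mode[None, :] + math.sqrt(2.0) * zz @ lchol.T
        hvals = np.array([fun(e) for e in etas])
        logterms = np.log(ww) + (zz**2).sum(axis=1) - hvals / 2.0
        m = logterms.max()
        log_int = (math.log(2.0) * 1.0 + np.log(np.linalg.det(lchol))
                   + m + math.log(np.exp(logterms - m).sum()))
        total += -2.0 * log_int
    return total


# ---------------------------------------------------------------------------
# generic Laplace machinery against linear-Gaussian closed forms


class TestLinearGaussianOracle:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.a = rng.normal(5.0, 1.0, 8)
        self.b = rng.normal(1.0, 0.5, 8)
        self.sigma2 = 0.4
        self.omega2 = 0.25
        self.y = self.a + self.b * 0.3 + rng.normal(0, math.sqrt(self.sigma2), 8)

    def mean_fn(self, eta):
        f = self.a + self.b * eta[0]
        return f, self.b[:, None]

    def test_mode_matches_ridge_closed_form(self):
        # posterior mode of a linear-Gaussian model is the ridge estimate
        _, eta, _ = laplace_subject(
            self.y, self.mean_fn, [self.omega2], 0.0, self.sigma2
        )
        num = self.b @ (self.y - self.a) / self.sigma2
        den = self.b @ self.b / self.sigma2 + 1.0 / self.omega2
        assert eta[0] == pytest.approx(num / den, abs=1e-6)

    def test_neg2ll_matches_exact_marginal(self):
        # Laplace is exact for a linear mean with additive error
        val, _, _ = laplace_subject(
            self.y, self.mean_fn, [self.omega2], 0.0, self.sigma2
        )
        cov = self.sigma2 * np.eye(8) + self.omega2 * np.outer(self.b, self.b)
        exact = -2.0 * stats.multivariate_normal.logpdf(self.y, self.a, cov)
        assert val == pytest.approx(exact, abs=1e-6)


class TestEbeModes:
    def test_infinite_shrinkage_limit(self, small_data, pop):
        tight = PopParams(pop.theta_cl, pop.theta_v, 0.0, 0.0,
                          pop.sigma_prop2, pop.sigma_add2)
        e_cl, e_v, hess = ebe_modes(small_data, tight)
        assert e_cl == 0.0 and e_v == 0.0
        assert np.isinf(hess[0, 0]) and np.isinf(hess[1, 1])

    def test_noise_free_consistency(self):
        pop = PopParams(omega_cl2=0.09, omega_v2=0.09, sigma_prop2=0.0,
                        sigma_add2=1e-8)
        design = StudyDesign(n_subjects=2, sample_times=(0.0, 1.0, 4.0, 12.0))
        data = simulate_dataset(design, pop, seed=0,
                                eta_overrides={1: (0.0, 0.0), 2: (0.0, 0.0)})
        e_cl, e_v, _ = ebe_modes(data, pop)
        assert abs(e_cl) < 1e-4 and abs(e_v) < 1e-4

    def test_mode_matches_independent_optimizer(self, small_data, pop):
        e_cl, e_v, _ = ebe_modes(small_data, pop)
        sid = small_data.subject_ids[0]
        obs = small_data.observations()
        sub = obs[obs["ID"] == sid]
        dose = float(small_data.doses().set_index("ID")["AMT"].loc[sid])
        res = optimize.minimize(
            lambda e: h_subject(e, sub["DV"].to_numpy(),
                                sub["TIME"].to_numpy(), dose, pop),
            [0.0, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxfev": 4000},
        )
        assert e_cl == pytest.approx(res.x[0], abs=1e-6)
        assert e_v == pytest.approx(res.x[1], abs=1e-6)


class TestFoceObjective:
    def test_zero_bsv_equals_wls_deviance(self, small_data):
        pop = PopParams(0.35, 2.0, 0.0, 0.0, 0.01, 0.04)
        ofv = foce_objective(small_data, pop)
        obs = small_data.observations()
        dose = 100.0
        f = (dose / pop.theta_v) * np.exp(
            -(pop.theta_cl / pop.theta_v) * obs["TIME"].to_numpy())
        g = pop.sigma_prop2 * f**2 + pop.sigma_add2
        y = obs["DV"].to_numpy()
        expected = float(np.sum((y - f) ** 2 / g + np.log(g) + LOG2PI))
        assert ofv == pytest.approx(expected, abs=1e-8)

    def test_matches_quadrature_oracle(self, pop):
        design = StudyDesign(n_subjects=5,
                             sample_times=(0.0, 0.5, 1.5, 4.0, 10.0, 24.0))
        data = simulate_dataset(design, pop, seed=33)
        laplace = foce_objective(data, pop)
        quad = neg2ll_quadrature(data, pop, n_nodes=21)
        assert laplace == pytest.approx(quad, rel=0.01)

    def test_batched_equals_generic_per_subject(self, pop):
        design = StudyDesign(n_subjects=4, sample_times=(0.0, 1.0, 4.0, 12.0))
        data = simulate_dataset(design, pop, seed=8)
        total = 0.0
        doses = data.doses().set_index("ID")["AMT"]
        obs = data.observations()
        for sid in data.subject_ids:
            sub = obs[obs["ID"] == sid]
            mean = _pk_mean_fn(float(doses.loc[sid]),
                               sub["TIME"].to_numpy(),
                               pop.theta_cl, pop.theta_v)
            val, _, _ = laplace_subject(
                sub["DV"].to_numpy(), mean,
                [pop.omega_cl2, pop.omega_v2],
                pop.sigma_prop2, pop.sigma_add2,
            )
            total += val
        assert foce_objective(data, pop) == pytest.approx(total, rel=1e-8)


class TestFit:
    def test_near_deterministic_recovery(self):
        truth = PopParams(0.35, 2.0, 1e-13, 1e-13, 0.0, 1e-6)
        design = StudyDesign(n_subjects=20,
                             sample_times=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0,
                                           16.0, 24.0))
        data = simulate_dataset(design, truth, seed=21)
        res = fit(data)
        assert res.status == "converged"
        assert res.pop_hat.theta_cl == pytest.approx(0.35, rel=0.01)
        assert res.pop_hat.theta_v == pytest.approx(2.0, rel=0.01)

    def test_init_robustness_and_improvement(self, small_data, pop):
        r1 = fit(small_data, init=pop)
        r2 = fit(small_data, init=_naive_two_stage_init(small_data))
        assert abs(r1.ofv - r2.ofv) < 0.01
        # the optimizer never ends above its starting objective
        assert r1.ofv <= foce_objective(small_data, pop) + 1e-9

    def test_ebes_cover_exactly_fitted_subjects(self, small_data):
        res = fit(small_data)
        assert sorted(res.ebes) == small_data.subject_ids
        assert res.n_subjects_fit == small_data.n_subjects

    def test_result_json_round_trip(self, small_data, tmp_path):
        res = fit(small_data)
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = type(res).from_json(path)
        assert back.pop_hat == res.pop_hat
        assert back.ofv == res.ofv
        assert back.ebes[1].cl == pytest.approx(res.ebes[1].cl)

    def test_fit_requires_two_subjects(self, small_data):
        solo = small_data.subset([1])
        with pytest.raises(ValueError):
            fit(solo)


class TestShrinkage:
    def test_ebe_shrinkage_grows_with_noise(self):
        # one cohort; as the assumed residual variance grows with fixed
        # Omega, the posterior modes shrink toward zero
        design = StudyDesign(n_subjects=12,
                             sample_times=(0.0, 1.0, 3.0, 8.0, 16.0, 24.0))
        data = simulate_dataset(
            design, PopParams(sigma_prop2=0.0, sigma_add2=0.01), seed=55)
        means = []
        for sa2 in (0.01, 1.0, 25.0):
            pop = PopParams(sigma_prop2=0.0, sigma_add2=sa2)
            abs_etas = []
            for sid in data.subject_ids:
                e_cl, e_v, _ = ebe_modes(data.subset([sid]), pop)
                abs_etas.extend([abs(e_cl), abs(e_v)])
            means.append(np.mean(abs_etas))
        assert means[0] > means[1] > means[2]
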
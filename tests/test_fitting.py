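"""Clustered multinomial fitting: oracle cross-checks, sandwich scaling,
backward elimination and QIC behaviour."""

import numpy as np
import pytest

from cat2eq5d import (
    CatResponse,
    Observation,
    backward_eliminate,
    fit_mnl_independence,
    fit_ols,
    fit_response_mapping,
    get_builtin,
    qic,
)
from cat2eq5d.fitting import FitError
from cat2eq5d.models import MlrResponseSpec, MnlDimensionModel
from cat2eq5d.simulate import recovery_design, simulate_from_spec
from cat2eq5d.tariff import DIMENSIONS

COVS = ["intercept", "cat_total", "age", "sex"]


def _identifiable_spec() -> MlrResponseSpec:
    """Generating coefficients of moderate size: every level reachable for
    both sexes, so all parameters are identified."""
    dims = {}
    for i, d in enumerate(DIMENSIONS):
        dims[d] = MnlDimensionModel(
            covariates=COVS,
            beta2=[-6.0 - 0.3 * i, 0.30, 0.02, 0.5],
            beta3=[-12.0 - 0.3 * i, 0.45, 0.04, 1.0],
        )
    return MlrResponseSpec(name="identifiable", dimensions=dims)


@pytest.fixture(scope="module")
def fitted():
    spec = _identifiable_spec()
    cov = recovery_design(700, 3, seed=11)
    obs = simulate_from_spec(spec, cov, seed=12)
    fit = fit_mnl_independence(obs, "mobility", COVS)
    return spec, obs, fit


def test_point_estimates_match_statsmodels_mnlogit(fitted):
    import statsmodels.api as sm

    spec, obs, fit = fitted
    X = np.column_stack(
        [
            np.ones(len(obs)),
            [o.cat.total for o in obs],
            [o.age for o in obs],
            [o.sex for o in obs],
        ]
    )
    y = np.array([o.eq5d.mobility for o in obs]) - 1
    res = sm.MNLogit(y, X).fit(disp=0, method="newton", maxiter=200)
    assert np.allclose(np.vstack([fit.beta2, fit.beta3]), res.params.T, atol=1e-5)
    # model-based covariance agrees too
    assert np.allclose(fit.cov_model, res.cov_params(), atol=1e-5, rtol=1e-3)


def test_estimates_near_truth(fitted):
    spec, obs, fit = fitted
    truth = np.array(
        spec.dimensions["mobility"].beta2 + spec.dimensions["mobility"].beta3
    )
    assert np.all(np.abs(fit.theta - truth) < 4 * fit.robust_se())
    assert fit.converged and not fit.separation_flag


def test_shuffle_invariance(fitted):
    _, obs, fit = fitted
    rng = np.random.default_rng(3)
    shuffled = [obs[i] for i in rng.permutation(len(obs))]
    fit2 = fit_mnl_independence(shuffled, "mobility", COVS)
    assert np.allclose(fit.theta, fit2.theta, atol=1e-10)
    assert np.allclose(fit.cov_robust, fit2.cov_robust, atol=1e-10)


def test_singleton_clusters_give_hc_covariance(fitted):
    """With one observation per cluster the sandwich must equal the classic
    robust covariance A^-1 (sum s_i s_i') A^-1, recomputed here from scratch
    with naive per-observation loops."""
    spec, obs, _ = fitted
    solo = [
        Observation(f"solo{i}", 1, o.age, o.sex, o.cat, o.eq5d, o.utility)
        for i, o in enumerate(obs[:900])
    ]
    fit = fit_mnl_independence(solo, "mobility", COVS)
    p = len(COVS)
    B = np.zeros((2 * p, 2 * p))
    A = np.zeros((2 * p, 2 * p))
    for o in solo:
        x = np.array([1.0, o.cat.total, o.age, o.sex])
        e2 = np.exp(x @ fit.beta2)
        e3 = np.exp(x @ fit.beta3)
        d = 1 + e2 + e3
        p2, p3 = e2 / d, e3 / d
        y = o.eq5d.mobility
        s = np.concatenate([((y == 2) - p2) * x, ((y == 3) - p3) * x])
        B += np.outer(s, s)
        W = np.array([[p2 * (1 - p2), -p2 * p3], [-p2 * p3, p3 * (1 - p3)]])
        A += np.kron(W, np.outer(x, x))
    V = np.linalg.inv(A) @ B @ np.linalg.inv(A)
    assert np.allclose(fit.cov_robust, V, rtol=1e-6, atol=1e-10)


def test_duplicating_clusters_scales_information(fitted):
    _, obs, fit = fitted
    doubled = list(obs) + [
        Observation(o.patient_id + "_copy", o.visit, o.age, o.sex, o.cat, o.eq5d, o.utility)
        for o in obs
    ]
    fit2 = fit_mnl_independence(doubled, "mobility", COVS)
    assert np.allclose(fit2.theta, fit.theta, atol=1e-8)
    assert np.allclose(fit2.info_model, 2 * fit.info_model, rtol=1e-6)
    assert np.allclose(fit2.cov_robust, fit.cov_robust / 2, rtol=1e-6, atol=1e-12)


def test_symmetric_null_data_gives_zero_coefficients():
    # levels equally frequent, covariate orthogonal to the outcome
    obs = []
    k = 0
    for level in (1, 2, 3):
        for x in (0, 5):
            for _ in range(10):
                st = {d: level for d in DIMENSIONS}
                from cat2eq5d import Eq5dState

                obs.append(
                    Observation(
                        f"c{k}",
                        1,
                        70.0,
                        0,
                        CatResponse(x, 0, 0, 0, 0, 0, 0, 0),
                        Eq5dState(**st),
                    )
                )
                k += 1
    fit = fit_mnl_independence(obs, "mobility", ["intercept", "q1"])
    assert abs(fit.beta2[1]) < 1e-6 and abs(fit.beta3[1]) < 1e-6


def test_absent_level_is_an_error(small_cohort):
    healthy = [o for o in small_cohort if o.eq5d.self_care == 1]
    with pytest.raises(FitError, match="absent"):
        fit_mnl_independence(healthy, "self_care", COVS)


class TestBackwardElimination:
    def test_significant_full_model_unchanged(self):
        spec = _identifiable_spec()
        cov = recovery_design(800, 3, seed=21)
        obs = simulate_from_spec(spec, cov, seed=22)
        fit = backward_eliminate(obs, "mobility", COVS)
        # all generating effects are strong at this n except possibly age
        assert "cat_total" in fit.covariates
        assert all(p <= 0.05 for p in fit.wald_p.values())

    def test_null_covariate_dropped_most_of_the_time(self):
        # age has a true zero effect in this generator; elimination at
        # alpha=0.05 should drop it in roughly 95% of datasets
        base = get_builtin("taiwan_mlr_total")
        dims = {
            d: MnlDimensionModel(
                covariates=["intercept", "cat_total"],
                beta2=base.dimensions[d].beta2[:2],
                beta3=base.dimensions[d].beta3[:2],
            )
            for d in DIMENSIONS
        }
        gen = MlrResponseSpec(name="null_age", dimensions=dims)
        kept = 0
        n_fits = 60
        for r in range(n_fits):
            cov = recovery_design(400, 3, seed=500 + r)
            obs = simulate_from_spec(gen, cov, seed=900 + r)
            fit = backward_eliminate(obs, "anxiety_depression", ["cat_total", "age"])
            kept += "age" in fit.covariates
        assert kept / n_fits < 0.15  # ~5% expected; generous binomial slack

    def test_retains_cat_total_in_all_dimensions(self):
        # end-to-end recovery from the published total-score coefficients
        spec = get_builtin("taiwan_mlr_total")
        cov = recovery_design(1200, 3, seed=31)
        obs = simulate_from_spec(spec, cov, seed=32)
        fitted_spec, fits = fit_response_mapping(obs, COVS, backward=True)
        for d in DIMENSIONS:
            assert "cat_total" in fits[d].covariates


class TestQic:
    def test_iid_limit_is_aic(self, fitted):
        spec, obs, _ = fitted
        solo = [
            Observation(f"s{i}", 1, o.age, o.sex, o.cat, o.eq5d, o.utility)
            for i, o in enumerate(obs)
        ]
        fit = fit_mnl_independence(solo, "mobility", COVS)
        # correct model, independent data: penalty ~ 2 * n_params = 16
        penalty = qic(fit) + 2 * fit.loglik
        assert penalty == pytest.approx(16.0, rel=0.2)

    def test_noise_covariate_increases_qic_in_majority(self):
        spec = _identifiable_spec()
        wins = 0
        n_sets = 40
        for r in range(n_sets):
            cov = recovery_design(250, 3, seed=1500 + r)
            obs = simulate_from_spec(spec, cov, seed=1800 + r)
            lean = fit_mnl_independence(obs, "mobility", ["intercept", "cat_total", "sex"])
            # age has a tiny true effect here; replace it with a pure-noise
            # item the generator never uses (q7 enters no equation)
            full = fit_mnl_independence(
                obs, "mobility", ["intercept", "cat_total", "sex", "q7"]
            )
            wins += qic(full) > qic(lean)
        assert wins > n_sets / 2

    def test_qic_finite_and_requires_convergence(self, fitted):
        _, _, fit = fitted
        assert np.isfinite(qic(fit))


class TestOlsRefit:
    def _obs_with_utility(self, utilities, cats, ages):
        return [
            Observation(f"p{i}", 1, a, 0, c, utility=u)
            for i, (u, c, a) in enumerate(zip(utilities, cats, ages))
        ]

    def test_intercept_only_returns_mean(self, rng):
        cats = [CatResponse(*rng.integers(0, 6, 8)) for _ in range(50)]
        u = rng.uniform(0, 1, 50)
        spec = fit_ols(self._obs_with_utility(u, cats, np.full(50, 70.0)), [])
        assert spec.equation.intercept == pytest.approx(u.mean(), abs=1e-10)
        assert spec.equation.slopes == {}

    def test_noiseless_exact_recovery(self, rng):
        cats = [CatResponse(*rng.integers(0, 6, 8)) for _ in range(60)]
        ages = rng.uniform(40, 90, 60)
        u = [1.2 - 0.02 * c.total - 0.003 * a for c, a in zip(cats, ages)]
        spec = fit_ols(self._obs_with_utility(u, cats, ages), ["cat_total", "age"])
        assert spec.equation.intercept == pytest.approx(1.2, abs=1e-10)
        assert spec.equation.slopes["cat_total"] == pytest.approx(-0.02, abs=1e-10)
        assert spec.equation.slopes["age"] == pytest.approx(-0.003, abs=1e-10)

    def test_recovers_published_modified_total_equation(self, rng):
        # simulate from the re-estimated total-score equation plus noise
        lim = get_builtin("lim_total_mod").equation
        n = 2000
        totals = rng.integers(0, 41, n)
        ages = rng.uniform(0, 90, n)
        cats = [CatResponse(*([5] * (t // 5) + [t % 5] + [0] * 7)[:8]) for t in totals]
        u = (
            lim.intercept
            + lim.slopes["cat_total"] * totals
            + lim.slopes["age"] * ages
            + rng.normal(0, 0.1, n)
        )
        spec = fit_ols(self._obs_with_utility(u, cats, ages), ["cat_total", "age"])
        assert spec.equation.intercept == pytest.approx(1.26848, abs=0.02)

    def test_rank_deficiency_raises(self, rng):
        cats = [CatResponse(3, 0, 0, 0, 0, 0, 0, 0) for _ in range(20)]
        obs = self._obs_with_utility(rng.uniform(0, 1, 20), cats, np.full(20, 70.0))
        with pytest.raises(FitError, match="rank"):
            fit_ols(obs, ["q1", "cat_total"])  # q1 == cat_total here
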
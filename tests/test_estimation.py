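"""Laplace/FOCE estimation engine: oracle equivalences and recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats

import mtxhcy as m
import mtxhcy.estimation as est
from mtxhcy.estimation import ArrayProblem, ebe_modes, laplace_ofv
from mtxhcy.population import params_to_dict, zero_variance


# --------------------------------------------------------------------------
# linear-Gaussian oracle: Laplace must equal the exact -2 log-likelihood
# --------------------------------------------------------------------------

def _random_intercept_problem(y, sigma2, omega2, theta):
    """y_ij = theta + b_i + eps_ij with b ~ N(0, omega2), eps ~ N(0, sigma2)."""
    return ArrayProblem(
        y=y, n_re=1,
        predict_fn=lambda p, b: p["theta"] + np.broadcast_to(b, (b.shape[0], y.shape[1])),
        prior_fn=lambda p: np.array([p["omega2"]]),
        var_fn=lambda p, preds: np.full_like(preds, p["sigma2"]),
        param_names=("theta", "omega2", "sigma2"),
        start={"theta": theta, "omega2": omega2, "sigma2": sigma2},
    )


def _exact_random_intercept_m2ll(y, sigma2, omega2, theta):
    m2ll = 0.0
    for row in y:
        obs = row[np.isfinite(row)]
        n = len(obs)
        cov = sigma2 * np.eye(n) + omega2 * np.ones((n, n))
        m2ll += -2.0 * stats.multivariate_normal.logpdf(obs, mean=np.full(n, theta), cov=cov)
    return m2ll


# printed fixture: 2 subjects, 3 observations each
_Y_FIXTURE = np.array([[9.3, 10.8, 10.1], [11.6, 12.4, 11.9]])


def test_laplace_equals_exact_m2ll_random_intercept():
    theta, omega2, sigma2 = 10.5, 0.8, 0.4
    problem = _random_intercept_problem(_Y_FIXTURE, sigma2, omega2, theta)
    ofv, _, _ = laplace_ofv(problem, {"theta": theta, "omega2": omega2, "sigma2": sigma2})
    exact = _exact_random_intercept_m2ll(_Y_FIXTURE, sigma2, omega2, theta)
    assert ofv == pytest.approx(exact, abs=1e-6)


def test_laplace_equals_exact_m2ll_random_slope():
    """Intercept + slope random effects, unbalanced data, exact MVN oracle."""
    x = np.array([0.0, 0.5, 1.0, 2.0])
    y = np.array([[5.1, 6.0, 7.2, 9.9], [4.2, 5.5, np.nan, 8.1], [5.8, 6.1, 7.7, 11.0]])
    theta0, theta1 = 5.0, 2.3
    w0, w1, s2 = 0.5, 0.3, 0.2

    def predict(p, b):
        return (p["t0"] + b[:, [0]]) + (p["t1"] + b[:, [1]]) * x[None, :]

    problem = ArrayProblem(
        y=y, n_re=2, predict_fn=predict,
        prior_fn=lambda p: np.array([p["w0"], p["w1"]]),
        var_fn=lambda p, preds: np.full_like(preds, p["s2"]),
        param_names=("t0", "t1", "w0", "w1", "s2"),
        start={"t0": theta0, "t1": theta1, "w0": w0, "w1": w1, "s2": s2},
    )
    params = problem.default_start
    ofv, _, _ = laplace_ofv(problem, params)

    exact = 0.0
    for row in y:
        sel = np.isfinite(row)
        X = np.column_stack([np.ones(sel.sum()), x[sel]])
        cov = s2 * np.eye(sel.sum()) + X @ np.diag([w0, w1]) @ X.T
        mean = theta0 + theta1 * x[sel]
        exact += -2.0 * stats.multivariate_normal.logpdf(row[sel], mean=mean, cov=cov)
    assert ofv == pytest.approx(exact, abs=1e-6)


def test_laplace_matches_adaptive_quadrature_nonlinear():
    """One subject, exponential-growth model: OFV within 0.1 of quadrature."""
    x = np.array([0.0, 0.5, 1.0])
    y = np.array([[2.1, 2.9, 4.4]])
    theta, omega2, sigma2 = 2.0, 0.09, 0.05

    def predict(p, b):
        return p["theta"] * np.exp(b[:, [0]] * (1.0 + x[None, :]))

    problem = ArrayProblem(
        y=y, n_re=1, predict_fn=predict,
        prior_fn=lambda p: np.array([p["omega2"]]),
        var_fn=lambda p, preds: np.full_like(preds, p["sigma2"]),
        param_names=("theta", "omega2", "sigma2"),
        start={"theta": theta, "omega2": omega2, "sigma2": sigma2},
    )
    params = problem.default_start
    ofv, _, _ = laplace_ofv(problem, params)

    def integrand(b):
        f = theta * np.exp(b * (1.0 + x))
        lik = np.prod(stats.norm.pdf(y[0], loc=f, scale=np.sqrt(sigma2)))
        return lik * stats.norm.pdf(b, scale=np.sqrt(omega2))

    L, _ = integrate.quad(integrand, -3.0, 3.0, epsabs=1e-12)
    assert ofv == pytest.approx(-2.0 * np.log(L), abs=0.1)


def test_large_omega_reduces_to_unpenalized_fit():
    """As omega² grows the mode approaches the unpenalised least-squares fit."""
    y = np.array([[3.0, 3.4, 2.8]])
    problem = _random_intercept_problem(y, sigma2=0.2, omega2=1e8, theta=1.0)
    b, _ = ebe_modes(problem, problem.default_start)
    assert b[0, 0] == pytest.approx(np.mean(y) - 1.0, abs=1e-4)


# --------------------------------------------------------------------------
# empirical Bayes modes
# --------------------------------------------------------------------------

def test_mode_at_zero_without_observations():
    y = np.array([[np.nan, np.nan]])
    problem = _random_intercept_problem(y, 0.5, 0.7, 2.0)
    b, _ = ebe_modes(problem, problem.default_start)
    assert b[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_single_observation_shrinkage_closed_form():
    """One observation: mode = omega²(y - theta)/(omega² + sigma²)."""
    theta, omega2, sigma2, yval = 10.0, 0.6, 0.3, 11.4
    y = np.array([[yval]])
    problem = _random_intercept_problem(y, sigma2, omega2, theta)
    b, _ = ebe_modes(problem, problem.default_start)
    assert b[0, 0] == pytest.approx(omega2 * (yval - theta) / (omega2 + sigma2), abs=1e-8)


def test_modes_track_truth_within_shrinkage_distance():
    """200 simulated subjects: EBE errors consistent with posterior SD."""
    rng = np.random.default_rng(5)
    theta, omega2, sigma2, n_obs = 10.0, 0.5, 0.2, 3
    b_true = rng.normal(0, np.sqrt(omega2), 200)
    y = theta + b_true[:, None] + rng.normal(0, np.sqrt(sigma2), (200, n_obs))
    problem = _random_intercept_problem(y, sigma2, omega2, theta)
    b, _ = ebe_modes(problem, problem.default_start)
    shrink = omega2 / (omega2 + sigma2 / n_obs)
    resid = b[:, 0] - shrink * (y.mean(axis=1) - theta)
    assert np.max(np.abs(resid)) < 1e-6
    post_sd = np.sqrt(1.0 / (1.0 / omega2 + n_obs / sigma2))
    z = (b[:, 0] - b_true) / np.sqrt(post_sd**2 + (1 - shrink) ** 2 * omega2)
    assert abs(np.mean(z)) < 0.2  # unbiased to Monte-Carlo precision


# --------------------------------------------------------------------------
# OFV invariances
# --------------------------------------------------------------------------

def test_ofv_invariant_under_subject_reordering(small_trial, pk_params):
    params = params_to_dict(pk_params)
    a = est.marginal_ofv(small_trial, pk_params)
    flipped = small_trial.copy()
    ids = flipped["ID"].to_numpy()
    flipped["ID"] = ids.max() + 1 - ids  # reverse the ID order
    b = est.marginal_ofv(flipped, pk_params)
    assert a == pytest.approx(b, abs=1e-6)


def test_nested_model_never_worse(small_trial):
    """Adding the creatinine covariate cannot raise the optimal OFV."""
    base = est.fit_population(small_trial, covariates=(), maxfev=150)
    ext = est.fit_population(
        small_trial, covariates=("scr",), start=base.params, maxfev=150
    )
    assert ext.ofv <= base.ofv + 0.1


# --------------------------------------------------------------------------
# population fits
# --------------------------------------------------------------------------

def test_noiseless_trial_identifies_structural_pk(pk_params, pd_params):
    """All variances and residual noise at zero: thetas recovered exactly."""
    pk0, pd0 = zero_variance(pk_params, pd_params)
    rng = np.random.default_rng(31)
    pop = m.sample_population(12, rng)
    df = m.generate_trial(pop, pk0, pd0, rng)
    start = params_to_dict(pk_params)
    start.update({"theta_cl": 5.0, "theta_v1": 25.0, "omega2_cl": 0.0,
                  "omega2_v1": 0.0, "omega2_q": 0.0, "iov2_cl": 0.0,
                  "sigma_exp": 0.01})
    fit = est.fit_population(
        df, start=start,
        fixed=("omega2_cl", "omega2_v1", "omega2_q", "iov2_cl", "sigma_exp"),
        maxfev=600,
    )
    assert fit.params["theta_cl"] == pytest.approx(pk0.theta_cl, rel=1e-3)
    assert fit.params["theta_v1"] == pytest.approx(pk0.theta_v1, rel=1e-2)
    assert fit.params["theta_cr"] == pytest.approx(pk0.theta_cr, abs=0.02)


def test_pk_recovery_medium_cohort(medium_fits, pk_params):
    """35-subject trial: clearance recovered well, V1 reasonably."""
    pk_res, _ = medium_fits
    assert pk_res.params["theta_cl"] == pytest.approx(pk_params.theta_cl, rel=0.10)
    assert pk_res.params["theta_v1"] == pytest.approx(pk_params.theta_v1, rel=0.20)
    assert pk_res.params["sigma_exp"] == pytest.approx(pk_params.sigma_exp, rel=0.20)


def test_sequential_pd_recovery_medium_cohort(medium_fits, pd_params):
    _, pd_res = medium_fits
    assert pd_res.params["theta_bl"] == pytest.approx(pd_params.theta_bl, rel=0.15)
    assert pd_res.params["theta_kout"] == pytest.approx(pd_params.theta_kout, rel=0.25)
    assert pd_res.params["theta_emax"] == 1.0  # fixed by default


def test_estimating_emax_approaches_one(medium_trial, medium_fits):
    """Freeing Emax on data generated at Emax=1 drives it towards 1."""
    pk_res, pd_res = medium_fits
    free = est.sequential_pd_fit(
        medium_trial, pk_res.fit_result, start=pd_res.fit_result.params,
        estimate_emax=True, maxfev=120,
    )
    assert free.params["theta_emax"] > 0.85


def test_perturbing_optimum_increases_ofv(medium_fits, medium_trial):
    pk_res, _ = medium_fits
    problem = pk_res.fit_result.problem
    base, _, _ = laplace_ofv(problem, pk_res.fit_result.params)
    for factor in (0.8, 1.25):
        worse = dict(pk_res.fit_result.params)
        worse["theta_cl"] *= factor
        ofv, _, _ = laplace_ofv(problem, worse)
        assert ofv > base


# --------------------------------------------------------------------------
# covariate search
# --------------------------------------------------------------------------

def _search_trial(theta_cr, seed, n=30):
    pk = dataclasses.replace(m.PKParameters(), theta_cr=theta_cr)
    rng = np.random.default_rng(seed)
    pop = m.sample_population(n, rng)
    from mtxhcy.design import TrialDesign

    return m.generate_trial(pop, pk, m.PDParameters(), rng,
                            design=TrialDesign(n_consolidation=3))


def test_covariate_search_selects_true_creatinine_effect():
    df = _search_trial(theta_cr=0.314, seed=21)
    records, selected = est.covariate_search(df, candidates=("scr",), maxfev=200)
    assert "scr" in selected
    fwd = [r for r in records if r.direction == "forward" and r.covariate == "scr"]
    assert fwd[0].included and fwd[0].delta_ofv >= est.FORWARD_DELTA_OFV


def test_covariate_search_rejects_null_effect():
    df = _search_trial(theta_cr=0.0, seed=22)
    records, selected = est.covariate_search(df, candidates=("scr",), maxfev=200)
    assert selected == ()


def test_covariate_search_empty_candidates(small_trial):
    records, selected = est.covariate_search(small_trial, candidates=(), maxfev=100)
    assert records == [] and selected == ()
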
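"""Observation-family likelihoods, decomposition identity, VIF selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit, logit
from scipy.stats import norm

import statsmodels.api as sm

from taprhythm import inference
from taprhythm.inference import (Design, DesignSpec, beta_loglik,
                                 binomial_loglik, build_design,
                                 censored_normal_loglik, fit_beta_accuracy,
                                 fit_binomial_logit, fit_censored_normal,
                                 fit_truncated_normal, sdt_decompose,
                                 truncated_normal_loglik, vif,
                                 vif_forward_select)


def make_design(X, y, columns=None, trials=None):
    return Design(X=X, columns=columns or [f"x{i}" for i in range(X.shape[1])],
                  y=y, trials=trials, standardization={})


def simulate_logistic(seed, n=400, beta=(-1.0, 1.5, 0.6, -0.4), trials=12):
    rng = np.random.default_rng(seed)
    cue = rng.integers(0, 2, n).astype(float)
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), cue, x, cue * x])
    p = expit(X @ np.array(beta))
    y = rng.binomial(trials, p).astype(float)
    return X, y, np.full(n, float(trials))


# ---------------------------------------------------------------------------
# design construction


def test_build_design_columns_and_standardization(small_joined):
    joined = small_joined["joined"]
    spec = DesignSpec(response="tap_num", rhythm_predictors=["mean_ioi"],
                      pulse_predictors=["markov2", "proj_cent"])
    design = build_design(joined, spec)
    assert design.columns == ["intercept", "cue", "mean_ioi", "markov2",
                              "proj_cent", "cue:markov2", "cue:proj_cent"]
    j = design.columns.index("mean_ioi")
    assert np.mean(design.X[:, j]) == pytest.approx(0.0, abs=1e-8)
    assert np.std(design.X[:, j]) == pytest.approx(1.0)
    assert design.trials is not None


def test_build_design_scale_only_response(small_joined):
    joined = small_joined["joined"].dropna(subset=["mean_velocity"]).copy()
    spec = DesignSpec(response="mean_velocity", pulse_predictors=["markov2"],
                      scale_only_response=True)
    design = build_design(joined, spec)
    assert design.response_scale == pytest.approx(
        joined["mean_velocity"].std(ddof=0))
    assert np.std(design.y) == pytest.approx(1.0)
    # scaled, not centred
    assert abs(np.mean(design.y)) > 0.1


def test_build_design_rank_deficiency_names_columns(small_joined):
    joined = small_joined["joined"].copy()
    joined["markov2_copy"] = joined["markov2"]
    spec = DesignSpec(response="tap_num",
                      pulse_predictors=["markov2", "markov2_copy"])
    with pytest.raises(ValueError, match="aliased"):
        build_design(joined, spec)


# ---------------------------------------------------------------------------
# binomial-logit


def test_binomial_matches_statsmodels_glm():
    X, y, n = simulate_logistic(0)
    fit = fit_binomial_logit(make_design(X, y, trials=n))
    glm = sm.GLM(np.column_stack([y, n - y]), X,
                 family=sm.families.Binomial()).fit()
    assert np.allclose(fit.coef, glm.params, atol=1e-6)
    assert np.allclose(fit.se, glm.bse, rtol=1e-3)


def test_binomial_loglik_matches_scipy_pmf():
    from scipy.stats import binom
    X, y, n = simulate_logistic(1, n=10)
    coef = np.array([-0.5, 1.0, 0.3, -0.2])
    ll = binomial_loglik(make_design(X, y, trials=n), coef)
    p = expit(X @ coef)
    assert ll == pytest.approx(float(binom.logpmf(y, n, p).sum()), abs=1e-8)


def test_binomial_penalty_shrinks_coefficients():
    X, y, n = simulate_logistic(2, n=60)
    design = make_design(X, y, trials=n)
    plain = fit_binomial_logit(design)
    shrunk = fit_binomial_logit(design, penalty="student_t")
    assert np.all(np.abs(shrunk.coef[1:]) <= np.abs(plain.coef[1:]) + 1e-9)


def test_binomial_recovery_within_three_se():
    truth = np.array([-1.0, 1.5, 0.6, -0.4])
    X, y, n = simulate_logistic(3, n=800)
    fit = fit_binomial_logit(make_design(X, y, trials=n))
    assert np.all(np.abs(fit.coef - truth) <= 3 * fit.se)


def test_odds_ratio_table():
    X, y, n = simulate_logistic(4)
    fit = fit_binomial_logit(make_design(X, y, trials=n))
    tab = fit.coef_table()
    assert np.allclose(tab["odds_ratio"], np.exp(tab["coef"]))


# ---------------------------------------------------------------------------
# censored normal


def simulate_censored(seed, n=500, beta=(0.5, 0.8), sigma=1.0, ceiling=1.6):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    latent = X @ np.array(beta) + rng.normal(0, sigma, n)
    y = np.minimum(latent, ceiling)
    return X, y


def test_censored_equals_ols_without_censoring():
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(300), rng.normal(size=300)])
    y = X @ np.array([1.0, 0.5]) + rng.normal(0, 0.3, 300)
    fit = fit_censored_normal(make_design(X, y), ceiling=y.max() + 10)
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.allclose(fit.coef, ols, atol=1e-6)


def test_censored_loglik_quadrature_oracle():
    """Upper-tail mass agrees with numerical integration on a toy table."""
    rng = np.random.default_rng(6)
    X = np.column_stack([np.ones(10), rng.normal(size=10)])
    y = rng.normal(size=10)
    ceiling = 0.5
    y[::3] = ceiling  # censored rows
    params = np.array([0.2, -0.3, np.log(0.8)])
    ll = censored_normal_loglik(params, X, y, ceiling)
    mu = X @ params[:2]
    sigma = np.exp(params[-1])
    expected = 0.0
    for yi, mi in zip(y, mu):
        if yi >= ceiling:
            mass, _ = integrate.quad(lambda t: norm.pdf(t, mi, sigma),
                                     ceiling, np.inf)
            expected += np.log(mass)
        else:
            expected += norm.logpdf(yi, mi, sigma)
    assert ll == pytest.approx(expected, abs=1e-8)


def test_censored_recovery_and_ols_bias():
    truth = np.array([0.5, 0.8])
    X, y = simulate_censored(7, ceiling=1.0)  # roughly 20-30% at the ceiling
    assert (y >= 1.0).mean() > 0.15
    fit = fit_censored_normal(make_design(X, y), ceiling=1.0)
    assert np.all(np.abs(fit.coef - truth) <= 3 * fit.se)
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert ols[0] < fit.coef[0]  # naive mean is biased downward


def test_censored_all_at_ceiling_errors():
    X = np.ones((5, 1))
    with pytest.raises(ValueError, match="censored"):
        fit_censored_normal(make_design(X, np.full(5, 2.0)), ceiling=1.0)


# ---------------------------------------------------------------------------
# truncated normal


def test_truncated_wide_bounds_equals_gaussian_regression():
    rng = np.random.default_rng(8)
    X = np.column_stack([np.ones(300), rng.normal(size=300)])
    y = X @ np.array([0.2, 0.7]) + rng.normal(0, 0.5, 300)
    fit = fit_truncated_normal(make_design(X, y), bounds=(-1e6, 1e6))
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.allclose(fit.coef, ols, atol=1e-5)


def test_truncated_loglik_quadrature_oracle():
    rng = np.random.default_rng(9)
    X = np.column_stack([np.ones(10), rng.normal(size=10)])
    y = rng.uniform(-1, 1, 10)
    bounds = (-1.2, 1.2)
    params = np.array([0.1, 0.4, np.log(0.9)])
    ll = truncated_normal_loglik(params, X, y, bounds)
    mu = X @ params[:2]
    sigma = np.exp(params[-1])
    expected = 0.0
    for yi, mi in zip(y, mu):
        mass, _ = integrate.quad(lambda t: norm.pdf(t, mi, sigma), *bounds)
        expected += norm.logpdf(yi, mi, sigma) - np.log(mass)
    assert ll == pytest.approx(expected, abs=1e-8)


def test_truncated_recovery_of_negative_asynchrony_mean():
    """Recover a -9 ms mean from window-truncated draws (ms scale)."""
    from scipy.stats import truncnorm
    rng = np.random.default_rng(10)
    n = 2000
    mu, sigma, b = -9.0, 40.0, 117.0
    y = truncnorm.rvs((-b - mu) / sigma, (b - mu) / sigma, loc=mu,
                      scale=sigma, size=n, random_state=rng)
    X = np.ones((n, 1))
    fit = fit_truncated_normal(make_design(X, y), bounds=(-b, b))
    assert abs(fit.coef[0] - mu) <= 3 * fit.se[0]


def test_truncated_bound_violation_errors():
    X = np.ones((5, 1))
    with pytest.raises(ValueError, match="outside"):
        fit_truncated_normal(make_design(X, np.array([0, 0, 0, 0, 5.0])),
                             bounds=(-1, 1))


# ---------------------------------------------------------------------------
# beta regression


def test_beta_constant_response_gives_logit_mean_intercept():
    rng = np.random.default_rng(11)
    X = np.column_stack([np.ones(200), rng.normal(size=200)])
    y = np.full(200, 0.3)
    fit = fit_beta_accuracy(make_design(X, y))
    assert fit.coef[0] == pytest.approx(logit(0.3), abs=1e-4)
    assert abs(fit.coef[1]) < 1e-4


def test_beta_matches_statsmodels_betareg():
    from statsmodels.othermod.betareg import BetaModel
    rng = np.random.default_rng(12)
    X = np.column_stack([np.ones(400), rng.normal(size=400)])
    mu = expit(X @ np.array([0.4, 0.8]))
    phi = 20.0
    y = rng.beta(mu * phi, (1 - mu) * phi)
    fit = fit_beta_accuracy(make_design(X, y))
    sm_fit = BetaModel(y, X).fit(disp=0)
    assert np.allclose(fit.coef, sm_fit.params[:2], atol=1e-4)
    assert fit.aux["log_phi"] == pytest.approx(sm_fit.params[-1], abs=1e-3)


def test_beta_loglik_matches_scipy_density():
    from scipy.stats import beta as beta_dist
    rng = np.random.default_rng(13)
    X = np.column_stack([np.ones(10), rng.normal(size=10)])
    y = rng.uniform(0.05, 0.95, 10)
    params = np.array([0.2, 0.5, np.log(7.0)])
    mu = expit(X @ params[:2])
    expected = beta_dist.logpdf(y, mu * 7.0, (1 - mu) * 7.0).sum()
    assert beta_loglik(params, X, y) == pytest.approx(expected, abs=1e-8)


def test_beta_recovery_and_fitted_means_in_unit_interval():
    rng = np.random.default_rng(14)
    X = np.column_stack([np.ones(600), rng.normal(size=600)])
    truth = np.array([0.3, -0.6])
    y = rng.beta(expit(X @ truth) * 30, (1 - expit(X @ truth)) * 30)
    fit = fit_beta_accuracy(make_design(X, y))
    assert np.all(np.abs(fit.coef - truth) <= 3 * fit.se)
    fitted = expit(X @ fit.coef)
    assert np.all((fitted > 0) & (fitted < 1))


def test_beta_rejects_out_of_range():
    X = np.ones((4, 1))
    with pytest.raises(ValueError):
        fit_beta_accuracy(make_design(X, np.array([0.2, 0.4, 1.3, 0.5])))


# ---------------------------------------------------------------------------
# decomposition and selection


def test_decomposition_identity_exact():
    X, y, n = simulate_logistic(15)
    fit = fit_binomial_logit(make_design(
        X, y, columns=["intercept", "cue", "x", "cue:x"], trials=n))
    dec = sdt_decompose(fit)
    assert dec.loc["x", "cued"] == dec.loc["x", "uncued"] + dec.loc[
        "x", "discriminability"]
    assert dec.loc["x", "uncued"] == fit["x"]
    assert dec.loc["x", "discriminability"] == fit["cue:x"]


def test_decomposition_worked_arithmetic():
    """An uncued effect of 0.30 with discriminability -0.27 sums to 0.03."""
    fit = inference.FitResult(
        family="binomial-logit",
        columns=["intercept", "cue", "x", "cue:x"],
        coef=np.array([0.0, 2.0, 0.30, -0.27]),
        se=np.full(4, 0.05), cov=np.eye(4) * 0.0025,
        loglik=0.0, n=10, converged=True, grad_norm=0.0)
    dec = sdt_decompose(fit)
    assert dec.loc["x", "cued"] == pytest.approx(0.03)
    # zero interaction leaves cued equal to uncued
    fit.coef[3] = 0.0
    dec = sdt_decompose(fit)
    assert dec.loc["x", "cued"] == dec.loc["x", "uncued"]


def test_decomposition_cued_se_uses_covariance():
    cov = np.array([[0.04, -0.01], [-0.01, 0.09]])
    fit = inference.FitResult(
        family="binomial-logit", columns=["intercept", "cue", "x", "cue:x"],
        coef=np.array([0.0, 1.0, 0.2, 0.1]),
        se=np.array([0.1, 0.1, 0.2, 0.3]),
        cov=np.block([[np.eye(2) * 0.01, np.zeros((2, 2))],
                      [np.zeros((2, 2)), cov]]),
        loglik=0.0, n=10, converged=True, grad_norm=0.0)
    dec = sdt_decompose(fit)
    assert dec.loc["x", "se_cued"] == pytest.approx(
        np.sqrt(0.04 + 0.09 - 0.02))


def test_decomposition_requires_interactions():
    fit = inference.FitResult(
        family="beta", columns=["intercept", "x"], coef=np.zeros(2),
        se=np.ones(2), cov=np.eye(2), loglik=0.0, n=5, converged=True,
        grad_norm=0.0)
    with pytest.raises(ValueError, match="interaction"):
        sdt_decompose(fit)


def test_vif_identity_and_forward_selection():
    rng = np.random.default_rng(16)
    n = 300
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    table = pd.DataFrame({
        "a": a, "b": b,
        "a_copy": a * 2.0 + 1.0,            # perfectly collinear with a
        "near": a + rng.normal(0, 0.1, n),  # R^2 > 0.9 with a
    })
    # algebraic identity: VIF = 1/(1 - R^2)
    z = table[["a", "near"]]
    resid = np.linalg.lstsq(np.column_stack([np.ones(n), z["a"]]),
                            z["near"].to_numpy(), rcond=None)[1]
    r2 = 1 - float(resid[0]) / float(np.sum((z["near"] - z["near"].mean()) ** 2))
    assert vif(table, ["a", "near"])["near"] == pytest.approx(1 / (1 - r2))

    selected = vif_forward_select(["a", "a_copy", "b", "near"], table)
    assert selected == ["a", "b"]

    orthogonal = vif_forward_select(["a", "b"], table)
    assert orthogonal == ["a", "b"]
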
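"""Regression families and the signal-detection decomposition.

Four observation families cover the dependent variables: binomial-logit for
per-pulse tap counts, upper-censored normal for MIDI velocities (taps harder
than 127 are still recorded as 127), two-sided truncated normal for signed
asynchronies (taps outside the +/-117-ms window are reassigned, so the data
cannot contain them), and beta regression for performance-level accuracy
scores in (0, 1).

Every pulse-level predictor x enters together with its cue interaction, so a
fit yields three effects per predictor: on uncued responses (beta_x), on cued
responses (beta_x + beta_{cue:x}), and on discriminability — the cued-uncued
difference (beta_{cue:x}), the regression analogue of signal-detection
d-prime.  The identity cued = uncued + discriminability holds exactly by
construction.

Fits are fixed-effects maximum (optionally Student-t penalized) likelihood
with observed-information standard errors; crossed random effects and full
posterior inference are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from scipy.stats import norm, t as student_t
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "DesignSpec",
    "Design",
    "FitResult",
    "build_design",
    "fit_binomial_logit",
    "fit_censored_normal",
    "fit_truncated_normal",
    "fit_beta_accuracy",
    "sdt_decompose",
    "vif",
    "vif_forward_select",
]


@dataclass
class DesignSpec:
    """What to regress on what.

    ``pulse_predictors`` each enter twice: as a main effect and interacted
    with ``cue``.  Continuous inputs are standardized to mean 0, SD 1;
    ``scale_only_response`` divides the response by its SD without centring
    (used for velocity and asynchrony, whose censoring/truncation bounds must
    stay interpretable).  Binary inputs are left as 0/1 dummies.
    """

    response: str
    performance_predictors: List[str] = field(default_factory=list)
    rhythm_predictors: List[str] = field(default_factory=list)
    pulse_predictors: List[str] = field(default_factory=list)
    include_cue: bool = True
    standardize: bool = True
    scale_only_response: bool = False
    binary_inputs: Tuple[str, ...] = ("cue", "duple_triple", "iso_accent",
                                      "start_accent", "end_accent")


@dataclass
class Design:
    X: np.ndarray
    columns: List[str]
    y: np.ndarray
    trials: Optional[np.ndarray]  # binomial denominators, else None
    standardization: Dict[str, Tuple[float, float]]
    response_scale: float = 1.0


@dataclass
class FitResult:
    family: str
    columns: List[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    converged: bool
    grad_norm: float
    aux: Dict[str, float] = field(default_factory=dict)
    standardization: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    response_scale: float = 1.0

    def coef_table(self) -> pd.DataFrame:
        z = self.coef / self.se
        tab = pd.DataFrame({"coef": self.coef, "se": self.se, "z": z},
                           index=self.columns)
        if self.family == "binomial-logit":
            tab["odds_ratio"] = np.exp(self.coef)
        return tab

    def __getitem__(self, name: str) -> float:
        return float(self.coef[self.columns.index(name)])


def build_design(table: pd.DataFrame, spec: DesignSpec) -> Design:
    """Assemble the model matrix, response, and standardization record.

    Columns: intercept, cue (dummy), performance-, rhythm-, and pulse-level
    predictors, then cue x pulse-level interactions.  Raises on rank
    deficiency, naming the aliased columns.
    """
    cols: Dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    std: Dict[str, Tuple[float, float]] = {}

    def add(name: str, values: np.ndarray):
        if spec.standardize and name not in spec.binary_inputs:
            m, s = float(np.mean(values)), float(np.std(values))
            if s == 0:
                raise ValueError(f"predictor '{name}' is constant")
            std[name] = (m, s)
            values = (values - m) / s
        cols[name] = values

    if spec.include_cue:
        cols["cue"] = table["cue"].to_numpy(dtype=float)
    for name in list(spec.performance_predictors) + list(spec.rhythm_predictors):
        add(name, table[name].to_numpy(dtype=float))
    for name in spec.pulse_predictors:
        add(name, table[name].to_numpy(dtype=float))
    for name in spec.pulse_predictors:
        if not spec.include_cue:
            raise ValueError("cue interactions require include_cue")
        cols[f"cue:{name}"] = cols["cue"] * cols[name]

    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        aliased = [names[i] for i in range(X.shape[1])
                   if abs(R[i, i]) < 1e-8 * max(abs(np.diag(R)))]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    scale = 1.0
    if spec.response == "tap_num":
        y = table["tap_num"].to_numpy(dtype=float)
        trials = table["n_pulses"].to_numpy(dtype=float)
    else:
        y = table[spec.response].to_numpy(dtype=float)
        trials = None
        if spec.scale_only_response:
            scale = float(np.std(y))
            if scale == 0:
                raise ValueError("response has zero variance")
            y = y / scale
    return Design(X=X, columns=names, y=y, trials=trials,
                  standardization=std, response_scale=scale)


# ---------------------------------------------------------------------------
# penalties and the generic optimizer


def _t_penalty(beta: np.ndarray, df: float, scale: float) -> float:
    """Negative log Student-t prior on non-intercept coefficients."""
    return -float(np.sum(student_t.logpdf(beta[1:], df, loc=0.0, scale=scale)))


def _maximize(negloglik, n_params: int, family: str, columns, n_obs: int,
              extra_names=(), x0: Optional[np.ndarray] = None,
              standardization=None, response_scale: float = 1.0,
              aux_builder=None) -> FitResult:
    """Quasi-Newton ML from a zero start with observed-information SEs."""
    if x0 is None:
        x0 = np.zeros(n_params)
    res = minimize(negloglik, x0, method="BFGS",
                   options={"maxiter": 500, "gtol": 1e-7})
    if not res.success:  # polish from the BFGS point
        res = minimize(negloglik, res.x, method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-5})
    grad_norm = float(np.max(np.abs(res.jac)))
    hess = approx_hess1(res.x, negloglik)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    k = len(columns)
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    fit = FitResult(
        family=family, columns=list(columns), coef=res.x[:k].copy(),
        se=se[:k], cov=cov[:k, :k], loglik=-float(res.fun), n=n_obs,
        converged=bool(res.success or grad_norm < 1e-3), grad_norm=grad_norm,
        standardization=dict(standardization or {}),
        response_scale=response_scale)
    for i, name in enumerate(extra_names):
        fit.aux[name] = float(res.x[k + i])
    if aux_builder is not None:
        fit.aux.update(aux_builder(res.x))
    if not fit.converged:
        fit.aux["warning_grad_norm"] = grad_norm
    return fit


# ---------------------------------------------------------------------------
# observation families


def fit_binomial_logit(design: Design, penalty: Optional[str] = None,
                       penalty_df: float = 3.0,
                       penalty_scale: float = 1.0) -> FitResult:
    """Binomial-logit ML (or Student-t-penalized MAP) for tap counts.

    Responses are (tap_num, n_pulses) pairs; coefficients are log-odds
    effects, reported alongside odds ratios exp(coef).  The optional penalty
    is a Student-t(3, 0, 1) log-density on the non-intercept coefficients,
    mirroring a weakly informative prior; off by default so recovery
    simulations are unbiased.
    """
    if design.trials is None:
        raise ValueError("binomial fit needs (tap_num, n_pulses) responses")
    X, y, n = design.X, design.y, design.trials

    def nll(params):
        eta = X @ params
        # log(1 + e^eta) computed stably
        log1pe = np.logaddexp(0.0, eta)
        val = -np.sum(y * eta - n * log1pe)
        if penalty == "student_t":
            val += _t_penalty(params, penalty_df, penalty_scale)
        return val

    def grad(params):
        p = expit(X @ params)
        g = -X.T @ (y - n * p)
        if penalty == "student_t":
            b = params.copy()
            b[0] = 0.0
            g += (penalty_df + 1) * b / (penalty_df * penalty_scale ** 2
                                         + b ** 2)
        return g

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                   options={"maxiter": 500, "gtol": 1e-8})
    hess = approx_hess1(res.x, nll)
    cov = np.linalg.inv(hess)
    grad_norm = float(np.max(np.abs(grad(res.x))))
    return FitResult(
        family="binomial-logit", columns=list(design.columns),
        coef=res.x.copy(), se=np.sqrt(np.diag(cov)), cov=cov,
        loglik=-float(nll(res.x)), n=len(y),
        converged=bool(res.success or grad_norm < 1e-4), grad_norm=grad_norm,
        standardization=design.standardization,
        response_scale=design.response_scale)


def binomial_loglik(design: Design, coef: np.ndarray,
                    include_constant: bool = True) -> float:
    """Full binomial log-likelihood (with choose-term) at given coefficients."""
    eta = design.X @ coef
    y, n = design.y, design.trials
    ll = float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))
    if include_constant:
        ll += float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))
    return ll


def censored_normal_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                           ceiling: float) -> float:
    """Log-likelihood of an upper-censored Gaussian regression.

    Observations at the ceiling contribute the upper-tail mass
    log P(Y >= ceiling); the rest contribute the normal density.
    """
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    mu = X @ beta
    cens = y >= ceiling
    ll = np.sum(norm.logpdf(y[~cens], mu[~cens], sigma))
    ll += np.sum(norm.logsf((ceiling - mu[cens]) / sigma))
    return float(ll)


def fit_censored_normal(design: Design, ceiling: float) -> FitResult:
    """ML Gaussian regression with upper censoring at ``ceiling``.

    ``ceiling`` is on the same scale as the response in the design (for MIDI
    velocities divided by their SD, pass 127/sd).  With no censored
    observations this reduces to ordinary least squares.
    """
    X, y = design.X, design.y
    if np.all(y >= ceiling):
        raise ValueError("all observations censored; mean is unidentified")

    def nll(params):
        return -censored_normal_loglik(params, X, y, ceiling)

    # start from OLS for stability
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    x0 = np.concatenate([beta0, [np.log(np.std(resid) + 1e-9)]])
    return _maximize(nll, X.shape[1] + 1, "censored-normal", design.columns,
                     len(y), extra_names=("log_sigma",), x0=x0,
                     standardization=design.standardization,
                     response_scale=design.response_scale)


def truncated_normal_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                            bounds: Tuple[float, float]) -> float:
    """Log-likelihood of a two-sided truncated Gaussian regression.

    The Gaussian density is renormalized to the observation window
    [bounds[0], bounds[1]].
    """
    lo, hi = bounds
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    mu = X @ beta
    z = norm.logpdf((y - mu) / sigma) - log_sigma
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    # log(Phi(b) - Phi(a)) via the complementary tail when both are positive
    log_mass = np.where(
        a > 0,
        np.log(norm.sf(a) - norm.sf(b)),
        np.log(norm.cdf(b) - norm.cdf(a)),
    )
    return float(np.sum(z - log_mass))


def fit_truncated_normal(design: Design, bounds: Tuple[float, float]) -> FitResult:
    """ML Gaussian regression truncated to the window ``bounds``.

    For signed asynchronies divided by their SD the window is
    (-117/sd, +117/sd).  Raises when any observation lies outside the window.
    """
    X, y = design.X, design.y
    lo, hi = bounds
    if np.any(y < lo) or np.any(y > hi):
        raise ValueError("observations outside the truncation window")

    def nll(params):
        return -truncated_normal_loglik(params, X, y, (lo, hi))

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    x0 = np.concatenate([beta0, [np.log(np.std(y - X @ beta0) + 1e-9)]])
    return _maximize(nll, X.shape[1] + 1, "truncated-normal", design.columns,
                     len(y), extra_names=("log_sigma",), x0=x0,
                     standardization=design.standardization,
                     response_scale=design.response_scale)


def beta_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood of a logit-mean, common-precision beta regression."""
    beta, log_phi = params[:-1], params[-1]
    phi = np.exp(log_phi)
    mu = expit(X @ beta)
    a, b = mu * phi, (1.0 - mu) * phi
    return float(np.sum(gammaln(phi) - gammaln(a) - gammaln(b)
                        + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)))


def fit_beta_accuracy(design: Design) -> FitResult:
    """Beta regression (logit mean link, common precision) for accuracy scores.

    Responses must lie in (0, 1); exact 0/1 values are nudged inward by a
    machine-epsilon amount.  Fitted means are guaranteed inside (0, 1) by the
    link.
    """
    X = design.X
    y = design.y.copy()
    if np.any((y < 0) | (y > 1)):
        raise ValueError("accuracy responses must lie in [0, 1]")
    if np.all(y == y[0]) and (y[0] in (0.0, 1.0)):
        raise ValueError("degenerate constant 0/1 response")
    eps = np.sqrt(np.finfo(float).eps)
    y = np.clip(y, eps, 1 - eps)

    def nll(params):
        return -beta_loglik(params, X, y)

    # moment-based start: logit of the mean, precision from the variance
    m = float(np.mean(y))
    v = float(np.var(y)) + 1e-12
    phi0 = max(m * (1 - m) / v - 1.0, 1.0)
    x0 = np.zeros(X.shape[1] + 1)
    x0[0] = np.log(m / (1 - m))
    x0[-1] = np.log(phi0)
    return _maximize(nll, X.shape[1] + 1, "beta", design.columns, len(y),
                     extra_names=("log_phi",), x0=x0,
                     standardization=design.standardization,
                     response_scale=design.response_scale)


# ---------------------------------------------------------------------------
# signal-detection decomposition and variable selection


def sdt_decompose(fit: FitResult) -> pd.DataFrame:
    """Per-predictor (uncued, cued, discriminability) effects with SEs.

    For each predictor x with a cue interaction: the uncued effect is
    beta_x, the discriminability effect is beta_{cue:x}, and the cued effect
    is their sum — exactly, with the cued-effect variance including the
    covariance term.  The cue row itself reports the baseline cued-uncued
    contrast.
    """
    inter = [c for c in fit.columns if c.startswith("cue:")]
    if not inter:
        raise ValueError("fit has no cue interactions to decompose")
    rows = []
    for c in inter:
        x = c[len("cue:"):]
        i = fit.columns.index(x)
        j = fit.columns.index(c)
        uncued, disc = fit.coef[i], fit.coef[j]
        var_cued = fit.cov[i, i] + fit.cov[j, j] + 2 * fit.cov[i, j]
        rows.append({
            "predictor": x,
            "uncued": uncued,
            "discriminability": disc,
            "cued": uncued + disc,
            "se_uncued": fit.se[i],
            "se_discriminability": fit.se[j],
            "se_cued": float(np.sqrt(max(var_cued, 0.0))),
        })
    return pd.DataFrame(rows).set_index("predictor")


def vif(table: pd.DataFrame, columns: Sequence[str]) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) of each column on the others."""
    out = {}
    Z = table[list(columns)].to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(Z)), Z])
    for i, name in enumerate(columns, start=1):
        others = [j for j in range(Z.shape[1]) if j != i]
        y = Z[:, i]
        coef, *_ = np.linalg.lstsq(Z[:, others], y, rcond=None)
        resid = y - Z[:, others] @ coef
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_forward_select(candidates: Sequence[str], table: pd.DataFrame,
                       vif_max: float = 10.0) -> List[str]:
    """Forward-add pre-ranked candidates, skipping any that push a VIF over 10.

    A VIF above 10 means the column can be regressed on the others with
    R^2 > 0.9.  Previously admitted candidates are never removed; the
    ranking itself is supplied by the caller.
    """
    selected: List[str] = []
    for cand in candidates:
        trial = selected + [cand]
        if len(trial) == 1:
            if table[cand].std() > 0:
                selected.append(cand)
            continue
        if float(vif(table, trial).max()) <= vif_max:
            selected.append(cand)
    return selected
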
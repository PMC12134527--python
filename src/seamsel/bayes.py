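"""Bayesian interim selection: logistic regression on the dichotomized
phase-II outcomes with shrinkage priors, and the posterior-probability
decision rules.

The model is logit P(alive at t*) = theta_0 + theta_S*S + theta_T*T +
theta_TS*S*T for subgroup indicator S and treatment indicator T.  theta_T is
the treatment shift in the complement-reference cell and theta_TS the
treatment-by-subgroup interaction, so theta_T + theta_TS is the treatment
effect inside the subgroup.  The interim decision thresholds the posterior
exceedance probabilities P(theta_TS > zeta_e), P(theta_T > zeta_e) and
P(theta_T + theta_TS > zeta_e).

Sampling uses an ensemble MCMC sampler (emcee, differential-evolution
moves).  With one global shrinkage scale per coefficient the horseshoe
scales can be integrated out exactly: each coefficient then carries an
independent 1-D marginal prior (a normal scale mixture over the product of
two half-Cauchy scales), so the posterior is sampled directly over the four
regression coefficients.  This avoids the funnel geometry of the explicit
scale parametrization, which biases ensemble samplers; the marginal density
is tabulated once per prior family by numerical integration.  The
``shared`` global-scale variant cannot be marginalized coefficient-wise and
uses the explicit non-centered parametrization instead.  Because the
likelihood depends on the data only through the four (subgroup x arm)
binomial cells, posterior evaluation is cheap and each interim fit takes a
fraction of a second.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from functools import lru_cache

import emcee
import numpy as np
import pandas as pd

from .design import InterimDecision, MCMCConfig, PriorSpec, TrialDesign
from .simulate import TrialDataset

__all__ = [
    "PosteriorSummary",
    "build_design_matrix",
    "fit_logistic_posterior",
    "exceedance_probabilities",
    "interim_decision_bayes",
]

THETA_NAMES = ("theta_0", "theta_S", "theta_T", "theta_TS")

# the four binomial cells (S, T) and their design-matrix rows
_CELLS = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],  # complement, control
        [1.0, 0.0, 1.0, 0.0],  # complement, treated
        [1.0, 1.0, 0.0, 0.0],  # subgroup, control
        [1.0, 1.0, 1.0, 1.0],  # subgroup, treated
    ]
)


def build_design_matrix(dataset: TrialDataset) -> tuple[np.ndarray, np.ndarray]:
    """Covariate rows (1, S, T, S*T) and binary outcomes, excluded dropped."""
    df = dataset.df
    if "binary_status" not in df.columns:
        raise ValueError("dataset must be dichotomized before model fitting")
    keep = df["binary_status"].notna()
    if not keep.any():
        raise ValueError("no evaluable patients (all excluded)")
    sub = df[keep]
    s = sub["in_S"].to_numpy(dtype=float)
    t = sub["arm"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(s), s, t, s * t])
    y = sub["binary_status"].to_numpy(dtype=float)
    return X, y


def _cell_counts(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse patient rows to per-cell (alive, total) binomial counts."""
    idx = (2 * X[:, 1] + X[:, 2]).astype(np.int64)  # 0..3 in _CELLS order
    alive = np.bincount(idx, weights=y, minlength=4)
    total = np.bincount(idx, minlength=4).astype(float)
    return alive, total


def _binom_loglik(theta: np.ndarray, alive: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Log-likelihood for a batch of theta rows, via the four cells."""
    eta = theta @ _CELLS.T  # (m, 4)
    softplus = np.logaddexp(0.0, eta)
    return (alive * eta - total * softplus).sum(axis=1)


def _log_halfcauchy_logscale(u: np.ndarray, scale: float) -> np.ndarray:
    """log density of log(x) where x ~ half-Cauchy(0, scale) (Jacobian included)."""
    return math.log(2.0 / (math.pi * scale)) + u - np.logaddexp(0.0, 2.0 * (u - math.log(scale)))


def _log_half_t_logscale(u: np.ndarray, scale: float, df: float) -> np.ndarray:
    """log density of log(x), x ~ half-t(df, 0, scale); df=1 is half-Cauchy."""
    if df == 1.0:
        return _log_halfcauchy_logscale(u, scale)
    from scipy import special

    x = np.exp(u)
    logc = (
        special.gammaln((df + 1.0) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * math.log(df * math.pi)
        - math.log(scale)
        + math.log(2.0)
    )
    return logc - (df + 1.0) / 2.0 * np.log1p((x / scale) ** 2 / df) + u


@lru_cache(maxsize=2)
def _local_horseshoe_logpdf():
    """Tabulated log density of x = z * lambda, z ~ N(0,1), lambda ~ C+(0,1).

    This is the textbook horseshoe marginal at unit global scale; the
    shared-global posterior evaluates each coefficient as
    log m(theta_k | tau) = logpdf(log(|theta_k| / tau)) - log tau.
    Interpolated over log|x| as in :func:`_marginal_shrinkage_logpdf`.
    """
    from scipy.interpolate import PchipInterpolator

    u = np.linspace(-45.0, 45.0, 1801)
    du = u[1] - u[0]
    p_lam = np.exp(_log_halfcauchy_logscale(u, 1.0))
    log_abs_x = np.linspace(math.log(1e-9), math.log(1e6), 500)
    x = np.exp(log_abs_x)[:, None]
    ku = np.exp(-u)[None, :]
    integ = np.exp(-0.5 * (x * ku) ** 2) / math.sqrt(2.0 * math.pi) * ku * p_lam[None, :]
    m = np.trapezoid(integ, dx=du, axis=1)
    return PchipInterpolator(log_abs_x, np.log(m), extrapolate=True)


@lru_cache(maxsize=8)
def _marginal_shrinkage_logpdf(scale: float, df: float):
    """Tabulated log marginal prior density of a horseshoe coefficient.

    theta = z * lambda * tau with z ~ N(0,1), lambda ~ half-Cauchy(0,1),
    tau ~ half-t(df, 0, scale).  The density of u = log(lambda * tau) is the
    convolution of the two log-scale densities, computed on a grid; the
    marginal m(theta) = E[phi(theta/kappa)/kappa] follows by trapezoidal
    integration.  Returns a monotone-cubic interpolant of log m over
    log|theta| (the density has an integrable log singularity at zero, which
    is smooth on this scale).
    """
    from scipy.interpolate import PchipInterpolator

    u = np.linspace(-45.0, 45.0, 1801)
    du = u[1] - u[0]
    p_lam = np.exp(_log_halfcauchy_logscale(u, 1.0))
    p_tau = np.exp(_log_half_t_logscale(u, scale, df))
    conv = np.convolve(p_lam, p_tau, mode="same") * du  # density of log(kappa)
    log_abs_theta = np.linspace(math.log(1e-9), math.log(1e6), 500)
    # integrand over log kappa: phi(theta * e^{-u}) * e^{-u} * p(u)
    t = np.exp(log_abs_theta)[:, None]
    ku = np.exp(-u)[None, :]
    integ = np.exp(-0.5 * (t * ku) ** 2) / math.sqrt(2.0 * math.pi) * ku * conv[None, :]
    m = np.trapezoid(integ, dx=du, axis=1)
    return PchipInterpolator(log_abs_theta, np.log(m), extrapolate=True)


class _Posterior:
    """Vectorized log-posterior over an unconstrained parametrization.

    Modes: ``normal`` and the marginalized per-coefficient horseshoe sample
    the four coefficients directly (ndim 4); the shared-global horseshoe
    additionally samples log tau with the local scales integrated out
    (ndim 5).
    """

    def __init__(self, prior: PriorSpec, alive: np.ndarray, total: np.ndarray):
        self.prior = prior
        self.alive = alive
        self.total = total
        self.shared = prior.family != "normal" and prior.global_shrinkage == "shared"
        if prior.family != "normal":
            if self.shared:
                self._logm = _local_horseshoe_logpdf()
            else:
                self._logm = _marginal_shrinkage_logpdf(prior.global_scale, prior.global_df)
        self.ndim = 5 if self.shared else 4

    def theta(self, pos: np.ndarray) -> np.ndarray:
        """Coefficient rows (m, 4) from unconstrained positions (m, ndim)."""
        return np.atleast_2d(pos)[:, :4]

    def __call__(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos)
        p = self.prior
        lp = -0.5 * pos[:, 0] ** 2 / p.intercept_variance
        if p.family == "normal":
            lp = lp - 0.5 * (pos[:, 1:4] ** 2).sum(axis=1) / p.normal_variance
        else:
            labs = np.log(np.maximum(np.abs(pos[:, 1:4]), 1e-300))
            if self.shared:
                u = pos[:, 4]
                lp = lp + (self._logm(labs - u[:, None]) - u[:, None]).sum(axis=1)
                lp = lp + _log_half_t_logscale(u, p.global_scale, p.global_df)
            else:
                lp = lp + self._logm(labs).sum(axis=1)
        return lp + _binom_loglik(self.theta(pos), self.alive, self.total)


@dataclasses.dataclass
class PosteriorSummary:
    """Pooled posterior draws of the four coefficients with diagnostics."""

    draws: pd.DataFrame  # columns THETA_NAMES, chains*draws rows
    p_TS: float
    p_T: float
    p_sum: float
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def _split_rhat(x: np.ndarray) -> float:
    """Split-Rhat over (chains, draws) for one parameter."""
    c, n = x.shape
    if n < 4:
        return math.nan
    half = n // 2
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n2 = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w <= 0.0:
        return math.nan
    return float(math.sqrt((n2 - 1) / n2 + b / (w * n2)))


def exceedance_probabilities(
    draws_T: np.ndarray, draws_TS: np.ndarray, zeta_e: float = 0.0
) -> tuple[float, float, float]:
    """(p_TS, p_T, p_sum): fraction of draws strictly above zeta_e.

    p_sum uses the per-draw sums theta_T + theta_TS, preserving their
    posterior correlation.
    """
    draws_T = np.asarray(draws_T, dtype=float)
    draws_TS = np.asarray(draws_TS, dtype=float)
    if draws_T.size == 0 or draws_T.shape != draws_TS.shape:
        raise ValueError("draws must be non-empty and aligned")
    p_T = float(np.mean(draws_T > zeta_e))
    p_TS = float(np.mean(draws_TS > zeta_e))
    p_sum = float(np.mean(draws_T + draws_TS > zeta_e))
    return p_TS, p_T, p_sum


def fit_logistic_posterior(
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int | np.random.Generator | None = None,
    zeta_e: float = 0.0,
) -> PosteriorSummary:
    """Sample the posterior of (theta_0, theta_S, theta_T, theta_TS).

    Runs an ensemble sampler, discards ``mcmc.warmup`` steps, thins the
    retained ensemble evenly to ``mcmc.n_draws`` pooled draws, and attaches
    split-Rhat (walkers as chains) and an autocorrelation-based effective
    sample size.  Non-convergence (Rhat above ``mcmc.rhat_warn``) raises a
    warning and flags the summary, never fails silently.
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4 or X.shape[0] != y.size:
        raise ValueError("X must be (n, 4) aligned with y")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary")
    alive, total = _cell_counts(X, y)
    arms_present = {(int(r[2])) for r in X}
    if arms_present != {0, 1}:
        raise ValueError("need evaluable patients in both arms")
    post = _Posterior(prior, alive, total)
    rng = np.random.default_rng(seed)
    nwalkers = max(2 * post.ndim + 4, 16)
    # initial ensemble: intercept near the empirical pooled logit, small
    # coefficients, scales near the bulk of their priors
    p_hat = min(max(alive.sum() / total.sum(), 0.02), 0.98)
    init = np.zeros((nwalkers, post.ndim))
    init[:, 0] = math.log(p_hat / (1 - p_hat)) + 0.2 * rng.standard_normal(nwalkers)
    init[:, 1:4] = 0.3 * rng.standard_normal((nwalkers, 3))
    if post.ndim == 5:
        init[:, 4] = math.log(0.3 * prior.global_scale) + 0.5 * rng.standard_normal(nwalkers)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, post.ndim, post, vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(int(rng.integers(2**31 - 1))).get_state()
    steps_post = max(mcmc.min_steps, math.ceil(mcmc.n_draws / nwalkers))
    state = sampler.run_mcmc(init, mcmc.warmup + steps_post, progress=False, skip_initial_state_check=True)
    del state
    chain = sampler.get_chain(discard=mcmc.warmup)  # (steps, walkers, ndim)
    theta = post.theta(chain.reshape(-1, post.ndim)).reshape(chain.shape[0], nwalkers, 4)
    # diagnostics on the full retained ensemble (walkers as chains)
    rhat = {
        name: _split_rhat(theta[:, :, j].T) for j, name in enumerate(THETA_NAMES)
    }
    try:
        act = sampler.get_autocorr_time(discard=mcmc.warmup, tol=0)
        n_eff_pos = chain.shape[0] * nwalkers / np.maximum(act, 1.0)
    except Exception:  # pragma: no cover - emcee internals
        n_eff_pos = np.full(post.ndim, math.nan)
    if prior.family == "normal":
        ess = {name: float(n_eff_pos[j]) for j, name in enumerate(THETA_NAMES)}
    else:
        # effective size of the slowest-mixing raw coordinate is the honest bound
        ess = {name: float(np.nanmin(n_eff_pos)) for name in THETA_NAMES}
    converged = all(not (r > mcmc.rhat_warn) for r in rhat.values() if not math.isnan(r))
    if not converged:
        warnings.warn(
            f"posterior sampling may not have converged (max Rhat = {max(rhat.values()):.3f})",
            RuntimeWarning,
            stacklevel=2,
        )
    # thin the pooled draws evenly down to the requested count
    pooled = theta.reshape(-1, 4)
    idx = np.linspace(0, pooled.shape[0] - 1, num=min(mcmc.n_draws, pooled.shape[0])).astype(int)
    pooled = pooled[idx]
    p_TS, p_T, p_sum = exceedance_probabilities(pooled[:, 2], pooled[:, 3], zeta_e)
    return PosteriorSummary(
        draws=pd.DataFrame(pooled, columns=list(THETA_NAMES)),
        p_TS=p_TS,
        p_T=p_T,
        p_sum=p_sum,
        rhat=rhat,
        ess=ess,
        converged=converged,
    )


def interim_decision_bayes(
    p_TS: float, p_T: float, p_sum: float, design: TrialDesign
) -> InterimDecision:
    """Map the exceedance probabilities to an interim decision.

    F&S if p_TS > tau_S and p_T > tau_F; S alone if the subgroup signal
    survives (p_TS > tau_S, p_T <= tau_F) and the subgroup treatment effect
    clears the futility threshold (p_sum > tau_1); F alone if only p_T >
    tau_F; futility otherwise.  Boundary ties fall to the non-selection
    side.
    """
    for name, v in (("p_TS", p_TS), ("p_T", p_T), ("p_sum", p_sum)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if p_TS > design.tau_S:
        if p_T > design.tau_F:
            return InterimDecision.F_AND_S
        if p_sum > design.tau_1:
            return InterimDecision.S_ONLY
        return InterimDecision.FUTILITY
    if p_T > design.tau_F:
        return InterimDecision.F_ONLY
    return InterimDecision.FUTILITY
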
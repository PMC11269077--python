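"""Bayesian binomial random-effects shrinkage of per-procedure mortality.

Model
-----
For procedure j with ``n_j`` cases and ``d_j`` in-hospital deaths,

.. math::

    d_j \\sim \\mathrm{Binomial}(n_j, p_j), \\qquad
    \\mathrm{logit}(p_j) = \\mu + b_j, \\qquad
    b_j \\sim \\mathcal N(0, \\tau^2),

with weakly-informative priors :math:`\\mu \\sim \\mathcal N(0, 5^2)` and
:math:`\\tau \\sim \\mathrm{HalfNormal}(1)` on the logit scale.  The posterior
mean of :math:`p_j` ("model-based" mortality) shrinks the raw rate
``d_j / n_j`` toward the population rate, strongly for low-volume
procedures and barely at all for high-volume ones, which stabilises the
rate ordering that the downstream risk stratification depends on.

Inference
---------
The random effects are integrated out by adaptive Gauss-Hermite
quadrature (the integrand is re-centred at its conditional mode, found
by a vectorised Newton iteration, and re-scaled by its curvature),
leaving a two-dimensional marginal posterior over
:math:`(\\mu, \\log\\tau)` that is cheap to evaluate in batches:

* ``method="eb"``: deterministic empirical Bayes - the marginal
  posterior is maximised and per-procedure posteriors are computed by
  quadrature at the plug-in :math:`(\\hat\\mu, \\hat\\tau)`.  Bit-for-bit
  reproducible; ignores hyperparameter uncertainty.
* ``method="mcmc"``: fully Bayesian - four independent affine-invariant
  ensembles (emcee) sample the marginal posterior, convergence is gated
  on cross-ensemble R-hat, and per-draw random effects are recovered
  exactly from their conditional density by grid inverse-CDF sampling,
  propagating hyperparameter uncertainty into the rate estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, gammaln, log_expit, logit, logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import raw_rate

__all__ = [
    "BinomialRandomEffects",
    "ConvergenceError",
    "fit_random_effects",
    "posterior_predictive_check",
    "log_marginal_likelihood",
    "conditional_rate_posterior",
    "population_rate",
]


def population_rate(mu, tau, quad_points=80):
    """Population mean event rate E[expit(mu + tau Z)], Z standard normal.

    This, not ``expit(mu)`` (the population *median* rate), is the point
    the posterior mean rate of a data-poor procedure shrinks toward: the
    logit-normal mean exceeds the inverse-logit of its location, markedly
    so at tau around 1.
    """
    if tau == 0:
        return float(expit(mu))
    x, w = hermgauss(quad_points)
    return float((w * expit(mu + np.sqrt(2.0) * tau * x)).sum() / np.sqrt(np.pi))


class ConvergenceError(RuntimeError):
    """MCMC convergence gate failed; carries the offending diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def _log_binom_const(d, n):
    return gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1)


def _conditional_mode(mu, tau, d, n, tol=1e-9, max_iter=80):
    """Mode and curvature scale of log p(b_j | d_j, mu, tau).

    Vectorised over a batch of T hyperparameter points and J procedures:
    ``mu``, ``tau`` have shape (T,), ``d``, ``n`` shape (J,); returns
    (T, J) arrays.  The score g'(b) = d - n expit(mu+b) - b/tau^2 is
    strictly decreasing and its root lies between the prior mode 0 and
    the likelihood mode logit((d+1/2)/(n+1)) - mu, so a bisection-
    safeguarded Newton iteration on that bracket cannot diverge (plain
    capped Newton can cycle when tau is large and the likelihood sharp).
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    inv_t2 = (1.0 / tau**2)[:, None]
    mu_c = mu[:, None]
    # initial bracket around the (continuity-corrected) likelihood mode and
    # the prior mode, expanded geometrically until the score changes sign
    b_lik = logit((d + 0.5) / (n + 1.0)) - mu_c          # (T, J)
    lo = np.minimum(b_lik, 0.0) - 1.0
    hi = np.maximum(b_lik, 0.0) + 1.0
    width = 1.0
    for _ in range(70):
        g_lo = d - n * expit(mu_c + lo) - lo * inv_t2
        g_hi = d - n * expit(mu_c + hi) - hi * inv_t2
        bad_lo = g_lo <= 0
        bad_hi = g_hi >= 0
        if not (bad_lo.any() or bad_hi.any()):
            break
        lo = np.where(bad_lo, lo - width, lo)
        hi = np.where(bad_hi, hi + width, hi)
        width *= 2.0
    b = 0.5 * (lo + hi)
    for _ in range(max_iter):
        p = expit(mu_c + b)
        grad = d - n * p - b * inv_t2
        lo = np.where(grad > 0, b, lo)
        hi = np.where(grad > 0, hi, b)
        hess = n * p * (1 - p) + inv_t2
        newton = b + grad / hess
        inside = (newton > lo) & (newton < hi)
        b_new = np.where(inside, newton, 0.5 * (lo + hi))
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b = b_new
    p = expit(mu_c + b)
    sd = 1.0 / np.sqrt(n * p * (1 - p) + inv_t2)
    return b, sd


def _log_joint_b(b, mu, tau, d, n):
    """log Bin(d | n, expit(mu + b)) + log N(b; 0, tau^2), no binomial const.

    Shapes broadcast; typically b is (T, J, G), mu/tau (T, 1, 1), d/n (J, 1).
    """
    eta = mu + b
    ll = d * log_expit(eta) + (n - d) * log_expit(-eta)
    return ll - 0.5 * b**2 / tau**2 - 0.5 * np.log(2 * np.pi) - np.log(tau)


def log_marginal_likelihood(mu, tau, d, n, quad_points=20):
    """Log marginal likelihood of (mu, tau), random effects integrated out.

    Adaptive Gauss-Hermite quadrature per procedure.  ``mu``/``tau`` may
    be scalars (returns a float) or length-T arrays (returns shape (T,)).
    """
    scalar = np.isscalar(mu) or np.ndim(mu) == 0
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    d = np.asarray(d, dtype=float)
    n = np.asarray(n, dtype=float)
    bhat, sd = _conditional_mode(mu, tau, d, n)           # (T, J)
    x, w = hermgauss(quad_points)
    bk = bhat[..., None] + np.sqrt(2.0) * sd[..., None] * x   # (T, J, Q)
    lf = _log_joint_b(bk, mu[:, None, None], tau[:, None, None],
                      d[:, None], n[:, None])
    per_j = logsumexp(lf + x**2 + np.log(w), axis=-1)
    per_j += 0.5 * np.log(2.0) + np.log(sd)
    out = per_j.sum(axis=-1) + _log_binom_const(d, n).sum()
    return float(out[0]) if scalar else out


def _log_prior(mu, tau, prior_mu_sd, prior_tau_sd):
    return (stats.norm.logpdf(mu, 0.0, prior_mu_sd)
            + stats.halfnorm.logpdf(tau, 0.0, prior_tau_sd))


def _make_log_posterior(d, n, prior_mu_sd, prior_tau_sd, quad_points):
    """Batched log posterior over theta = (mu, log tau); theta is (T, 2)."""

    def log_post(theta):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        mu, log_tau = theta[:, 0], theta[:, 1]
        ok = (mu > -30) & (mu < 10) & (log_tau > -20) & (log_tau < 4)
        out = np.full(len(theta), -np.inf)
        if ok.any():
            tau = np.exp(log_tau[ok])
            out[ok] = (log_marginal_likelihood(mu[ok], tau, d, n, quad_points)
                       + _log_prior(mu[ok], tau, prior_mu_sd, prior_tau_sd)
                       + log_tau[ok])   # Jacobian of tau -> log tau
        return out

    return log_post


def _conditional_grid(mu, tau, d, n, grid_points, half_width=8.0):
    """Grids over b and normalised log conditional densities, batched.

    ``mu``/``tau`` shape (T,) -> returns (T, J, G) grids spanning the
    conditional mode +/- ``half_width`` conditional standard deviations,
    which covers the posterior mass to beyond floating-point relevance.
    """
    d = np.asarray(d, dtype=float)
    n = np.asarray(n, dtype=float)
    bhat, sd = _conditional_mode(mu, tau, d, n)
    u = np.linspace(-half_width, half_width, grid_points)
    b = bhat[..., None] + sd[..., None] * u
    mu = np.atleast_1d(mu)
    tau = np.atleast_1d(tau)
    lp = _log_joint_b(b, mu[:, None, None], tau[:, None, None],
                      d[:, None], n[:, None])
    lp -= logsumexp(lp, axis=-1, keepdims=True)
    return b, lp


def conditional_rate_posterior(mu, tau, d, n, grid_points=2001):
    """Posterior mean and equal-tailed 95% interval of p_j given (mu, tau).

    Deterministic quadrature on a per-procedure grid; p = expit(mu + b)
    is monotone in b, so quantiles of b map directly to quantiles of p.
    """
    b, lp = _conditional_grid(float(mu), float(tau), d, n, grid_points)
    b, lp = b[0], lp[0]
    wgt = np.exp(lp)
    p = expit(mu + b)
    mean = np.sum(wgt * p, axis=1)
    cdf = np.cumsum(wgt, axis=1)
    lo = np.empty(len(mean))
    hi = np.empty(len(mean))
    for j in range(len(mean)):
        lo[j] = np.interp(0.025, cdf[j], p[j])
        hi[j] = np.interp(0.975, cdf[j], p[j])
    return mean, lo, hi


def _sample_conditional_rates(rng, mu, tau, d, n, grid_points=401):
    """Draws of p_j for a batch of hyperparameter draws.

    ``mu``/``tau`` shape (T,); returns (T, J) with one conditional draw
    of b_j per hyperparameter draw, by grid inverse-CDF.
    """
    b, lp = _conditional_grid(mu, tau, d, n, grid_points)
    cdf = np.cumsum(np.exp(lp), axis=-1)
    cdf /= cdf[..., -1:]
    T, J, _ = b.shape
    u = rng.random((T, J))
    out = np.empty((T, J))
    for t in range(T):
        for j in range(J):
            out[t, j] = np.interp(u[t, j], cdf[t, j], b[t, j])
    return expit(np.atleast_1d(mu)[:, None] + out)


class BinomialRandomEffects(BaseEstimator):
    """Hierarchical binomial shrinkage estimator for event rates.

    Parameters
    ----------
    method : {"eb", "mcmc"}
        ``"eb"`` maximises the marginal posterior over (mu, log tau) and
        plugs the optimum in (deterministic).  ``"mcmc"`` samples the
        marginal posterior with independent emcee ensembles and
        propagates hyperparameter uncertainty.
    prior_mu_sd, prior_tau_sd : float
        Scales of the Normal(0, .) prior on mu and HalfNormal prior on tau.
    n_draws : int
        Posterior draws of (mu, tau) retained after thinning (mcmc), and
        the number of conditional draws used by the posterior predictive
        check under either method.
    n_chains, n_walkers, n_burn, n_steps : int
        Sampler geometry (mcmc only): independent ensembles, walkers per
        ensemble, burn-in and retained steps per walker.
    rhat_threshold : float
        Convergence gate on the max cross-ensemble R-hat; exceeding it
        raises :class:`ConvergenceError`.
    quad_points : int
        Gauss-Hermite nodes for the marginal likelihood.
    grid_points : int
        Grid resolution for conditional rate posteriors.
    random_state : int or None
        Seed for all stochastic steps.

    Attributes
    ----------
    mu_, tau_ : float
        Posterior means (mcmc) or marginal-posterior modes (eb).
    hyperparameters_ : dict
        Point estimates with 95% intervals for mu and tau.
    estimates_ : pandas.DataFrame
        One row per procedure: raw_rate, posterior_mean, credible_low,
        credible_high, n_draws.
    diagnostics_ : dict
        method, convergence flag, R-hat and acceptance fraction (mcmc).
    """

    def __init__(self, method="eb", prior_mu_sd=5.0, prior_tau_sd=1.0,
                 n_draws=400, n_chains=4, n_walkers=32, n_burn=150, n_steps=350,
                 rhat_threshold=1.01, quad_points=20, grid_points=2001,
                 random_state=None):
        self.method = method
        self.prior_mu_sd = prior_mu_sd
        self.prior_tau_sd = prior_tau_sd
        self.n_draws = n_draws
        self.n_chains = n_chains
        self.n_walkers = n_walkers
        self.n_burn = n_burn
        self.n_steps = n_steps
        self.rhat_threshold = rhat_threshold
        self.quad_points = quad_points
        self.grid_points = grid_points
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _optimum(self, log_post):
        pooled = max(self._d.sum(), 0.5) / self._n.sum()
        x0 = np.array([logit(pooled), 0.0])
        res = optimize.minimize(lambda t: -log_post(t)[0], x0,
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 2000})
        return res.x

    def _hessian_se(self, log_post, theta):
        """Standard errors from a finite-difference Hessian at the mode."""
        h = 1e-4
        pts = []
        for a in range(2):
            for b in range(2):
                for sa, sb in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    e = np.zeros(2)
                    e[a] += sa * h
                    e[b] += sb * h
                    pts.append(theta + e)
        vals = log_post(np.array(pts))
        H = np.zeros((2, 2))
        for k, (a, b) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            v = vals[4 * k:4 * k + 4]
            H[a, b] = (v[0] - v[1] - v[2] + v[3]) / (4 * h * h)
        cov = np.linalg.inv(-H)
        return np.sqrt(np.clip(np.diag(cov), 0, None))

    def fit(self, X, y=None):
        """Fit the model to a procedure-outcome table.

        ``X`` is a DataFrame with ``cases``/``deaths`` (and optionally
        ``procedure``) columns, or an array of shape (J, 2) holding
        (cases, deaths) per row.  Requires at least two procedures.
        """
        if isinstance(X, pd.DataFrame):
            names = (X["procedure"].to_numpy() if "procedure" in X.columns
                     else np.arange(len(X)).astype(str))
            n = X["cases"].to_numpy(dtype=float)
            d = X["deaths"].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            n, d = X[:, 0], X[:, 1]
            names = np.arange(len(n)).astype(str)
        if len(n) < 2:
            raise ValueError("need at least 2 procedures to estimate heterogeneity")
        if (n <= 0).any() or (d < 0).any() or (d > n).any():
            raise ValueError("need cases >= 1 and 0 <= deaths <= cases")
        self._n, self._d, self._names = n, d, names

        log_post = self._log_post = _make_log_posterior(
            d, n, self.prior_mu_sd, self.prior_tau_sd, self.quad_points)
        theta_hat = self._optimum(log_post)

        if self.method == "eb":
            self._fit_eb(log_post, theta_hat)
        elif self.method == "mcmc":
            self._fit_mcmc(log_post, theta_hat)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        mean, lo, hi = self._rate_posterior()
        self.estimates_ = pd.DataFrame({
            "procedure": names,
            "cases": n.astype(int),
            "deaths": d.astype(int),
            "raw_rate": raw_rate(d, n),
            "posterior_mean": mean,
            "credible_low": lo,
            "credible_high": hi,
            "n_draws": self.diagnostics_["n_draws"],
        })
        return self

    def _fit_eb(self, log_post, theta_hat):
        mu_hat, log_tau_hat = theta_hat
        se = self._hessian_se(log_post, theta_hat)
        self.mu_ = float(mu_hat)
        self.tau_ = float(np.exp(log_tau_hat))
        z = stats.norm.ppf(0.975)
        self.hyperparameters_ = {
            "mu": self.mu_,
            "mu_ci": (self.mu_ - z * se[0], self.mu_ + z * se[0]),
            "tau": self.tau_,
            "tau_ci": (float(np.exp(log_tau_hat - z * se[1])),
                       float(np.exp(log_tau_hat + z * se[1]))),
        }
        self._hyper_draws = None
        self.diagnostics_ = {"method": "eb", "converged": True, "rhat": None,
                             "n_draws": 0}

    def _fit_mcmc(self, log_post, theta_hat):
        import arviz as az
        import emcee

        rng = np.random.default_rng(self.random_state)
        chains = []
        acc = []
        for _ in range(self.n_chains):
            p0 = theta_hat + 0.05 * rng.standard_normal((self.n_walkers, 2))
            sampler = emcee.EnsembleSampler(self.n_walkers, 2, log_post,
                                            vectorize=True)
            state = emcee.State(p0, random_state=np.random.RandomState(
                rng.integers(2**31)).get_state())
            state = sampler.run_mcmc(state, self.n_burn, progress=False)
            sampler.reset()
            sampler.run_mcmc(state, self.n_steps, progress=False)
            chains.append(sampler.get_chain(flat=True))   # (steps*walkers, 2)
            acc.append(float(np.mean(sampler.acceptance_fraction)))

        stacked = np.stack(chains)                         # (chains, S, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat_ds = az.rhat(az.convert_to_dataset(stacked))
        rhat = float(np.max(rhat_ds.to_array().values))
        diagnostics = {
            "method": "mcmc",
            "rhat": rhat,
            "acceptance_fraction": float(np.mean(acc)),
            "n_draws": self.n_draws,
        }
        if rhat > self.rhat_threshold:
            raise ConvergenceError(
                f"cross-ensemble R-hat {rhat:.4f} exceeds "
                f"{self.rhat_threshold}", diagnostics)
        diagnostics["converged"] = True

        flat = stacked.reshape(-1, 2)
        idx = np.linspace(0, len(flat) - 1, self.n_draws).astype(int)
        draws = flat[idx]
        self._hyper_draws = np.column_stack([draws[:, 0], np.exp(draws[:, 1])])
        self._rng_draws = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1)
        mu_d, tau_d = self._hyper_draws[:, 0], self._hyper_draws[:, 1]
        self.mu_ = float(np.mean(mu_d))
        self.tau_ = float(np.mean(tau_d))
        self.hyperparameters_ = {
            "mu": self.mu_,
            "mu_ci": tuple(np.percentile(mu_d, [2.5, 97.5])),
            "tau": self.tau_,
            "tau_ci": tuple(np.percentile(tau_d, [2.5, 97.5])),
        }
        self.diagnostics_ = diagnostics

    def _rate_posterior(self):
        if self._hyper_draws is None:
            return conditional_rate_posterior(self.mu_, self.tau_, self._d,
                                              self._n, self.grid_points)
        p = self._draw_rates(self._rng_draws)
        return p.mean(axis=0), *np.percentile(p, [2.5, 97.5], axis=0)

    def _draw_rates(self, rng, n_draws=None, chunk=100):
        """Posterior draws of p_j, shape (n_draws, J)."""
        if self._hyper_draws is not None:
            hyper = (self._hyper_draws if n_draws is None else
                     self._hyper_draws[rng.integers(len(self._hyper_draws),
                                                    size=n_draws)])
        else:
            m = n_draws or self.n_draws
            hyper = np.tile([self.mu_, self.tau_], (m, 1))
        outs = []
        for i in range(0, len(hyper), chunk):
            h = hyper[i:i + chunk]
            outs.append(_sample_conditional_rates(
                rng, h[:, 0], h[:, 1], self._d, self._n))
        return np.vstack(outs)

    def posterior_predictive_check(self, seed=None, replicate="marginal"):
        """Per-procedure upper-tail probabilities P(d_rep >= d_obs | data).

        With ``replicate="marginal"`` (default) the replicated rate is a
        fresh draw from the fitted population law, p_rep = expit(mu + tau z),
        z ~ N(0, 1): the check asks whether each observed count is
        consistent with a procedure of that volume drawn from the
        population, and retains power against rows whose own data would
        otherwise dominate their posterior.  ``replicate="conditional"``
        uses the procedure's own rate posterior instead (the classical
        same-data check; conservative for high-volume rows).  The
        binomial tail is computed exactly per draw and averaged, adding
        no replication noise.  Small values flag procedures with more
        deaths than the model can explain.
        """
        check_is_fitted(self, "estimates_")
        rng = np.random.default_rng(seed)
        if replicate == "conditional":
            p = self._draw_rates(rng)
        elif replicate == "marginal":
            if self._hyper_draws is not None:
                hyper = self._hyper_draws
            else:
                hyper = np.tile([self.mu_, self.tau_], (self.n_draws, 1))
            z = rng.standard_normal((len(hyper), len(self._n)))
            p = expit(hyper[:, :1] + hyper[:, 1:] * z)
        else:
            raise ValueError(f"unknown replicate mode {replicate!r}")
        # P(Bin(n, p) >= d) = sf(d - 1, n, p)
        tail = stats.binom.sf(self._d[None, :] - 1,
                              self._n.astype(int)[None, :], p)
        return tail.mean(axis=0)


def fit_random_effects(table, config=None, seed=None):
    """Fit the random-effects model; returns (hyperparameter summary, estimates).

    Thin functional wrapper over :class:`BinomialRandomEffects`; ``config``
    is a dict of estimator parameters (e.g. ``{"method": "mcmc"}``).
    """
    params = dict(config or {})
    params.setdefault("random_state", seed)
    model = BinomialRandomEffects(**params).fit(table)
    summary = dict(model.hyperparameters_, diagnostics=model.diagnostics_)
    return summary, model.estimates_


def posterior_predictive_check(model, seed=None):
    """Functional wrapper for :meth:`BinomialRandomEffects.posterior_predictive_check`."""
    return model.posterior_predictive_check(seed=seed)
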
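"""Two-segment Gaussian change-point regression of |k-3| on d0.

The model locates the parent-diameter threshold tau above which deviation
from Murray's Law plateaus:

    y_i ~ Normal(mu(x_i), sigma^2)
    mu(x) = alpha + beta1 * x                          for x <= tau
    mu(x) = alpha + beta1 * tau + beta2 * (x - tau)    for x >  tau

(segments joined at tau; a disjoint variant with a free second intercept
is available).  Priors: tau uniform over the central span of the observed
x (trimmed by ``tau_trim`` on each side so both segments keep enough
points to identify their slopes, which also tempers the boundary Occam
bonus a change-point marginal likelihood gives to nearly-empty
segments), diffuse normals on the coefficients, and a weakly-informative
half-normal on sigma.

Sampling is a seeded Metropolis-within-Gibbs over
(tau, alpha, beta1, beta2, log sigma): random-walk Metropolis steps for
tau and log sigma, and exact conjugate Gibbs draws for the linear
coefficients given (tau, sigma) — the normal priors make their
conditional a 3-variate normal, which removes the tau-coefficient random
walk correlation that would otherwise cripple mixing.  The Gaussian
likelihood depends on the data only through second-order sums of the
piecewise design, all of which are O(1) functions of prefix sums of the
x-sorted data, so each MCMC iteration costs O(1) after an O(n log n)
setup.  Proposal scales adapt during warm-up only (the first third of
each chain, discarded), keeping the post-warm-up chain a valid Markov
chain and the whole run reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import arviz as az
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["ChangePointFit", "ChangePointRegressor", "fit_changepoint", "summarize_fit"]

_JOINED_PARAMS = ("tau", "alpha", "beta1", "beta2", "sigma")
_DISJOINT_PARAMS = ("tau", "alpha", "beta1", "alpha2", "beta2", "sigma")


@dataclass
class ChangePointFit:
    """Posterior draws and summaries of the two-segment regression."""

    draws: dict[str, np.ndarray]  # name -> (chains, kept draws)
    summary: pd.DataFrame         # per-parameter median/mean/CI/rhat/ess
    converged: bool               # all rhat < 1.05
    chains: int
    iterations: int
    warmup: int
    seed: Optional[int]
    joined: bool
    x_range: tuple[float, float]

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0 * 100.0
        pooled = self.draws[name].ravel()
        return tuple(np.percentile(pooled, [lo, 100.0 - lo]))

    def median(self, name: str) -> float:
        return float(np.median(self.draws[name].ravel()))


class _PiecewiseSuffStats:
    """Prefix sums of the x-sorted data giving O(1) Gaussian sufficient
    statistics of the piecewise design at any tau."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        order = np.lexsort((y, x))  # canonical ordering: permutation-invariant
        self.x = x[order]
        self.y = y[order]
        self.n = x.size
        z = np.zeros(1)
        self.cx = np.concatenate([z, np.cumsum(self.x)])
        self.cx2 = np.concatenate([z, np.cumsum(self.x * self.x)])
        self.cy = np.concatenate([z, np.cumsum(self.y)])
        self.cxy = np.concatenate([z, np.cumsum(self.x * self.y)])
        self.Sy = self.cy[-1]
        self.Syy = float(np.sum(self.y * self.y))

    def design_sums_joined(self, tau: float):
        """Gram matrix and cross-products of [1, min(x,tau), (x-tau)+]."""
        Su, Suu, Sv, Svv, Suv, Suy, Svy = self.joined(tau)
        XtX = np.array(
            [[self.n, Su, Sv], [Su, Suu, Suv], [Sv, Suv, Svv]], dtype=float
        )
        Xty = np.array([self.Sy, Suy, Svy], dtype=float)
        return XtX, Xty

    def design_sums_disjoint(self, tau: float):
        """Block-diagonal Gram matrix of the two free segments."""
        m = int(np.searchsorted(self.x, tau, side="right"))
        n = self.n
        nh, nt = m, n - m
        S1, S2, Syh, Sxyh = self.cx[m], self.cx2[m], self.cy[m], self.cxy[m]
        T1, T2 = self.cx[n] - S1, self.cx2[n] - S2
        Ty, Txy = self.cy[n] - Syh, self.cxy[n] - Sxyh
        XtX = np.array(
            [
                [nh, S1, 0.0, 0.0],
                [S1, S2, 0.0, 0.0],
                [0.0, 0.0, nt, T1],
                [0.0, 0.0, T1, T2],
            ]
        )
        Xty = np.array([Syh, Sxyh, Ty, Txy])
        return XtX, Xty

    def joined(self, tau: float):
        """Second-order sums of [1, min(x,tau), (x-tau)+] and y."""
        m = int(np.searchsorted(self.x, tau, side="right"))
        n, nt = self.n, self.n - m
        S1, S2 = self.cx[m], self.cx2[m]
        Sxy_h = self.cxy[m]
        T1 = self.cx[n] - S1
        T2 = self.cx2[n] - S2
        Ty = self.cy[n] - self.cy[m]
        Txy = self.cxy[n] - Sxy_h
        Su = S1 + nt * tau
        Suu = S2 + nt * tau * tau
        Sv = T1 - nt * tau
        Svv = T2 - 2.0 * tau * T1 + nt * tau * tau
        Suv = tau * Sv
        Suy = Sxy_h + tau * Ty
        Svy = Txy - tau * Ty
        return Su, Suu, Sv, Svv, Suv, Suy, Svy

    def ssr_joined(self, tau, alpha, b1, b2) -> float:
        Su, Suu, Sv, Svv, Suv, Suy, Svy = self.joined(tau)
        return (
            self.Syy
            - 2.0 * (alpha * self.Sy + b1 * Suy + b2 * Svy)
            + alpha * alpha * self.n
            + b1 * b1 * Suu
            + b2 * b2 * Svv
            + 2.0 * (alpha * b1 * Su + alpha * b2 * Sv + b1 * b2 * Suv)
        )

    def ssr_disjoint(self, tau, alpha, b1, alpha2, b2) -> float:
        m = int(np.searchsorted(self.x, tau, side="right"))
        n = self.n
        nh, nt = m, n - m
        S1, S2, Syh, Sxyh = self.cx[m], self.cx2[m], self.cy[m], self.cxy[m]
        T1, T2 = self.cx[n] - S1, self.cx2[n] - S2
        Ty, Txy = self.cy[n] - Syh, self.cxy[n] - Sxyh
        ssr_h = (
            -2.0 * (alpha * Syh + b1 * Sxyh)
            + alpha * alpha * nh
            + b1 * b1 * S2
            + 2.0 * alpha * b1 * S1
        )
        ssr_t = (
            -2.0 * (alpha2 * Ty + b2 * Txy)
            + alpha2 * alpha2 * nt
            + b2 * b2 * T2
            + 2.0 * alpha2 * b2 * T1
        )
        return self.Syy + ssr_h + ssr_t


class ChangePointRegressor(RegressorMixin, BaseEstimator):
    """Bayesian two-segment regression with a free change point.

    Parameters
    ----------
    chains, iterations : int
        MCMC configuration; the first third of each chain is warm-up and
        is discarded.
    seed : int or None
        Seeds every chain (via spawned ``SeedSequence`` children); the
        same data and seed give identical draws.
    joined : bool
        Joined segments share the value at tau (default); ``False`` frees
        the second-segment intercept.
    tau_trim : float
        Quantile trimmed off each end of x for the uniform change-point
        prior (default 0.05: tau lives between the 5th and 95th
        percentiles of the predictor).

    Attributes
    ----------
    fit_ : ChangePointFit
        Draws, summaries and convergence flag.
    tau_, beta1_, beta2_ : float
        Posterior medians.
    converged_ : bool
        All split-R-hat below 1.05.
    """

    def __init__(
        self,
        chains: int = 3,
        iterations: int = 9000,
        seed: Optional[int] = None,
        joined: bool = True,
        tau_trim: float = 0.05,
    ):
        self.chains = chains
        self.iterations = iterations
        self.seed = seed
        self.joined = joined
        self.tau_trim = tau_trim

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "ChangePointRegressor":
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("expected a single predictor column (d0)")
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size < 40:
            raise ValueError(f"need at least 40 observations, got {x.size}")
        if np.unique(x).size < 10:
            raise ValueError("need at least 10 distinct x values")
        if np.ptp(x) == 0:
            raise ValueError("degenerate x: all values equal")

        if not 0.0 <= self.tau_trim < 0.5:
            raise ValueError("tau_trim must lie in [0, 0.5)")
        stats = _PiecewiseSuffStats(x, y)
        self.fit_ = _sample(
            stats,
            chains=self.chains,
            iterations=self.iterations,
            seed=self.seed,
            joined=self.joined,
            tau_trim=self.tau_trim,
        )
        self.tau_ = self.fit_.median("tau")
        self.beta1_ = self.fit_.median("beta1")
        self.beta2_ = self.fit_.median("beta2")
        self.sigma_ = self.fit_.median("sigma")
        self.converged_ = self.fit_.converged
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior-mean regression line, averaged over thinned draws."""
        if not hasattr(self, "fit_"):
            raise AttributeError("ChangePointRegressor is not fitted yet")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        d = self.fit_.draws
        kept = d["tau"].size
        step = max(1, kept // 500)
        tau = d["tau"].ravel()[::step, None]
        alpha = d["alpha"].ravel()[::step, None]
        b1 = d["beta1"].ravel()[::step, None]
        b2 = d["beta2"].ravel()[::step, None]
        if self.joined:
            mu = alpha + b1 * np.minimum(x, tau) + b2 * np.maximum(0.0, x - tau)
        else:
            a2 = d["alpha2"].ravel()[::step, None]
            mu = np.where(x <= tau, alpha + b1 * x, a2 + b2 * x)
        return mu.mean(axis=0)


# ----------------------------------------------------------------------
def _sample(stats, chains, iterations, seed, joined, tau_trim=0.05) -> ChangePointFit:
    n = stats.n
    x, y = stats.x, stats.y
    xmin, xmax = float(x[0]), float(x[-1])
    xbar = float(x.mean())
    sd_y = float(y.std()) or 1.0
    sd_x = float(x.std()) or 1.0

    # priors (on the centred-x scale used internally)
    prior_sd_alpha = 10.0 * sd_y + abs(float(y.mean()))
    prior_sd_beta = 10.0 * sd_y / sd_x
    sigma_scale = 5.0 * sd_y  # half-normal scale

    names = _JOINED_PARAMS if joined else _DISJOINT_PARAMS
    warmup = iterations // 3
    kept = iterations - warmup
    store = {nm: np.empty((chains, kept)) for nm in names}

    # centre x for numerical conditioning of the quadratic forms
    cstats = _PiecewiseSuffStats(x - xbar, y)
    lo_t = float(np.quantile(x, tau_trim)) - xbar
    hi_t = float(np.quantile(x, 1.0 - tau_trim)) - xbar

    if joined:
        prior_sds = np.array([prior_sd_alpha, prior_sd_beta, prior_sd_beta])
    else:
        prior_sds = np.array(
            [prior_sd_alpha, prior_sd_beta, prior_sd_alpha, prior_sd_beta]
        )
    prior_prec = np.diag(prior_sds**-2.0)

    def ssr_at(tau: float, coef: np.ndarray) -> float:
        s = (
            cstats.ssr_joined(tau, *coef)
            if joined
            else cstats.ssr_disjoint(tau, *coef)
        )
        return max(s, 0.0)  # guard tiny negative round-off in the sums

    def log_post(tau: float, coef: np.ndarray, logsig: float) -> float:
        if not (lo_t <= tau <= hi_t):
            return -math.inf
        sig = math.exp(logsig)
        ll = -0.5 * n * math.log(2.0 * math.pi * sig * sig) - ssr_at(
            tau, coef
        ) / (2.0 * sig * sig)
        lp = -0.5 * float(coef @ (prior_prec @ coef))
        lp += -0.5 * (sig / sigma_scale) ** 2 + logsig  # half-normal + Jacobian
        return ll + lp

    def gibbs_coef(tau: float, sig: float, rng) -> np.ndarray:
        """Exact draw from the conditional normal of the coefficients."""
        XtX, Xty = (
            cstats.design_sums_joined(tau)
            if joined
            else cstats.design_sums_disjoint(tau)
        )
        prec = XtX / (sig * sig) + prior_prec
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Xty / (sig * sig))
        z = rng.standard_normal(mean.size)
        return mean + np.linalg.solve(chol.T, z)

    log_det_prior = float(np.sum(np.log(np.diag(prior_prec))))

    def log_marg_tau(tau: float, sig: float) -> float:
        """log p(y | tau, sigma) with the coefficients integrated out.

        Collapsing the conjugate coefficients makes the tau random walk
        explore the change-point posterior directly instead of dragging
        the current coefficient draw along.
        """
        if not (lo_t <= tau <= hi_t):
            return -math.inf
        XtX, Xty = (
            cstats.design_sums_joined(tau)
            if joined
            else cstats.design_sums_disjoint(tau)
        )
        s2 = sig * sig
        A = XtX / s2 + prior_prec
        chol = np.linalg.cholesky(A)
        b = Xty / s2
        w = np.linalg.solve(chol, b)
        quad = cstats.Syy / s2 - float(w @ w)
        log_det_A = 2.0 * float(np.sum(np.log(np.diag(chol))))
        return (
            -0.5 * n * math.log(2.0 * math.pi * s2)
            + 0.5 * log_det_prior
            - 0.5 * log_det_A
            - 0.5 * quad
        )

    seed_seq = np.random.SeedSequence(seed if seed is not None else 0)
    child_seqs = seed_seq.spawn(chains)

    for c in range(chains):
        rng = np.random.default_rng(child_seqs[c])
        q = tau_trim + (1.0 - 2.0 * tau_trim) * (c + 1.0) / (chains + 1.0)
        tau0 = float(np.quantile(x, q)) - xbar
        tau, coef, logsig = _init_state(cstats, tau0, joined)
        s_tau = 0.05 * (hi_t - lo_t)
        s_sig = 0.2
        lp = log_post(tau, coef, logsig)
        acc = np.zeros(2)
        tries = np.zeros(2)
        lm = log_marg_tau(tau, math.exp(logsig))
        for it in range(iterations):
            # Metropolis on the change point, coefficients collapsed
            # out (partially collapsed Gibbs); 1-in-10 proposals are
            # uniform independence jumps so multimodal tau posteriors mix
            jump = rng.random() < 0.1
            if jump:
                tau_prop = rng.uniform(lo_t, hi_t)
            else:
                tau_prop = tau + s_tau * rng.standard_normal()
            lm_prop = log_marg_tau(tau_prop, math.exp(logsig))
            if jump:
                if math.log(rng.random()) < lm_prop - lm:
                    tau, lm = tau_prop, lm_prop
            else:
                tries[0] += 1
                if math.log(rng.random()) < lm_prop - lm:
                    tau, lm = tau_prop, lm_prop
                    acc[0] += 1
            # exact conjugate Gibbs draw of the linear coefficients
            coef = gibbs_coef(tau, math.exp(logsig), rng)
            lp = log_post(tau, coef, logsig)
            # random-walk Metropolis on log sigma
            logsig_prop = logsig + s_sig * rng.standard_normal()
            lp_prop = log_post(tau, coef, logsig_prop)
            tries[1] += 1
            if math.log(rng.random()) < lp_prop - lp:
                logsig, lp = logsig_prop, lp_prop
                acc[1] += 1
                lm = log_marg_tau(tau, math.exp(logsig))
            if it < warmup and (it + 1) % 50 == 0:
                rates = acc / np.maximum(tries, 1)
                s_tau = max(s_tau * math.exp(0.5 * (rates[0] - 0.44)), 1e-8)
                s_sig = max(s_sig * math.exp(0.5 * (rates[1] - 0.44)), 1e-8)
                acc[:] = 0
                tries[:] = 0
            if it >= warmup:
                k = it - warmup
                store["tau"][c, k] = tau + xbar
                store["sigma"][c, k] = math.exp(logsig)
                if joined:
                    alpha, b1, b2 = coef
                    store["alpha"][c, k] = alpha - b1 * xbar
                    store["beta1"][c, k] = b1
                    store["beta2"][c, k] = b2
                else:
                    alpha, b1, a2, b2 = coef
                    store["alpha"][c, k] = alpha - b1 * xbar
                    store["beta1"][c, k] = b1
                    store["alpha2"][c, k] = a2 - b2 * xbar
                    store["beta2"][c, k] = b2

    summary, converged = _summaries(store)
    return ChangePointFit(
        draws=store,
        summary=summary,
        converged=converged,
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        seed=seed,
        joined=joined,
        x_range=(xmin, xmax),
    )


def _init_state(cstats, tau0, joined):
    """Least-squares start at a fixed tau; chains start at spread x-quantiles."""
    x, y = cstats.x, cstats.y
    if joined:
        X = np.column_stack(
            [np.ones_like(x), np.minimum(x, tau0), np.maximum(0.0, x - tau0)]
        )
    else:
        left = x <= tau0
        X = np.column_stack(
            [left, np.where(left, x, 0.0), ~left, np.where(left, 0.0, x)]
        ).astype(float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sig0 = max(float(resid.std()), 1e-6)
    return tau0, coef, math.log(sig0)


def _summaries(store: dict[str, np.ndarray]) -> tuple[pd.DataFrame, bool]:
    idata = az.from_dict(posterior={k: v for k, v in store.items()})
    rows = []
    converged = True
    for name, draws in store.items():
        pooled = draws.ravel()
        if np.ptp(pooled) == 0:
            rhat = float("nan")
            ess = float("nan")
            converged = False  # degenerate chains cannot be certified
        else:
            rhat = float(az.rhat(idata, var_names=[name])[name].values)
            ess = float(az.ess(idata, var_names=[name])[name].values)
            if not (rhat < 1.05):
                converged = False
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "median": float(np.median(pooled)),
                "ci_2.5": float(lo),
                "ci_97.5": float(hi),
                "rhat": rhat,
                "ess": ess,
            }
        )
    return pd.DataFrame(rows).set_index("parameter"), converged


def fit_changepoint(
    x,
    y,
    chains: int = 3,
    iterations: int = 9000,
    seed: Optional[int] = None,
    joined: bool = True,
) -> ChangePointFit:
    """Functional wrapper over :class:`ChangePointRegressor`."""
    reg = ChangePointRegressor(
        chains=chains, iterations=iterations, seed=seed, joined=joined
    )
    reg.fit(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return reg.fit_


def summarize_fit(fit: ChangePointFit) -> pd.DataFrame:
    """Per-parameter posterior summary table (deterministic given draws)."""
    if not fit.draws or next(iter(fit.draws.values())).size == 0:
        raise ValueError("fit contains no draws")
    return fit.summary.copy()
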
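"""Negative-binomial mixed models by Gauss-Hermite quadrature.

Fits a log-link NB2 model with Gaussian random intercepts, either a single
grouping level (``zone``) or two nested levels (``zone/reef``). For nested
intercepts the marginal likelihood factorizes over zones: the reef-level
integrals are one-dimensional conditional on the zone effect, so the whole
likelihood is evaluated with two nested one-dimensional Gauss-Hermite grids.

The model for fish i in reef r within zone z:

    y_i ~ NB(mu_i, theta),   mu_i = exp(x_i' beta + offset_i + u_z + v_r)
    u_z ~ N(0, sigma_z^2),   v_r ~ N(0, sigma_r^2)

Maximum likelihood is obtained with Nelder-Mead over
(beta, log theta, log sigma_z[, log sigma_r]); log standard deviations are
clipped below at -6 so variance components can collapse to (numerical) zero
without destabilizing the search. Likelihood-ratio tests between nested
fixed-effect specifications use 2*(l_full - l_null) against chi2(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = ["NBMixedFit", "fit_nb_mixed", "lrt"]

_LOG_SD_MIN, _LOG_SD_MAX = -6.0, 3.0


@dataclass
class NBMixedFit:
    beta: np.ndarray
    beta_se: np.ndarray | None
    theta: float
    sigma_zone: float
    sigma_reef: float | None
    loglik: float
    converged: bool
    n: int
    random: str
    params_: np.ndarray | None = None  # raw optimizer vector, for warm starts


def _nb_logpmf_terms(y: np.ndarray, theta: float):
    # parts of the NB2 log-pmf that do not depend on mu
    return special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1)


def _loglik(params, y, X, offset, zone_onehot, reef_onehot, reef_zone_onehot,
            nodes, logw, random):
    p = X.shape[1]
    beta = params[:p]
    theta = np.exp(np.clip(params[p], -10, 10))
    log_sz = np.clip(params[p + 1], _LOG_SD_MIN, _LOG_SD_MAX)
    sz = np.exp(log_sz)
    eta = X @ beta + offset
    const = _nb_logpmf_terms(y, theta)
    Q = nodes.size

    if random == "zone":
        mu = np.exp(eta[:, None] + sz * nodes[None, :])  # (n, Q)
        lp = (const[:, None] + theta * np.log(theta / (theta + mu))
              + y[:, None] * np.log(mu / (theta + mu)))
        zone_lp = zone_onehot @ lp  # (n_zone, Q)
        return float(special.logsumexp(logw[None, :] + zone_lp, axis=1).sum())

    log_sr = np.clip(params[p + 2], _LOG_SD_MIN, _LOG_SD_MAX)
    sr = np.exp(log_sr)
    # grid of zone x reef node offsets, flattened: c[k*Q + l] = sz*a_k + sr*b_l
    c = (sz * nodes[:, None] + sr * nodes[None, :]).ravel()
    mu = np.exp(eta[:, None] + c[None, :])  # (n, Q*Q)
    lp = (const[:, None] + theta * np.log(theta / (theta + mu))
          + y[:, None] * np.log(mu / (theta + mu)))
    reef_lp = (reef_onehot @ lp).reshape(-1, Q, Q)           # (n_reef, Q, Q)
    inner = special.logsumexp(logw[None, None, :] + reef_lp, axis=2)  # (n_reef, Q)
    zone_inner = reef_zone_onehot @ inner                    # (n_zone, Q)
    return float(special.logsumexp(logw[None, :] + zone_inner, axis=1).sum())


def fit_nb_mixed(
    y,
    X,
    zone,
    reef=None,
    offset=None,
    random: str = "zone/reef",
    n_nodes: int = 11,
    compute_se: bool = True,
    maxiter: int = 4000,
    x0_extra: np.ndarray | None = None,
) -> NBMixedFit:
    """Fit the NB mixed model by maximum likelihood.

    Parameters
    ----------
    y : array of non-negative integer counts.
    X : (n, p) fixed-effects design matrix (include the intercept column).
    zone, reef : group labels per observation; ``reef`` required for the
        nested ``"zone/reef"`` structure.
    offset : optional log-offset per observation (e.g. log read depth).
    random : ``"zone/reef"`` (nested intercepts) or ``"zone"``.
    n_nodes : Gauss-Hermite nodes per integration level.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    zone_idx = np.unique(np.asarray(zone), return_inverse=True)[1]
    n_zone = zone_idx.max() + 1
    zone_onehot = np.zeros((n_zone, n))
    zone_onehot[zone_idx, np.arange(n)] = 1.0
    reef_onehot = reef_zone_onehot = None
    if random == "zone/reef":
        if reef is None:
            raise ValueError("reef labels required for nested random effects")
        reef_idx = np.unique(np.asarray(reef), return_inverse=True)[1]
        n_reef = reef_idx.max() + 1
        reef_onehot = np.zeros((n_reef, n))
        reef_onehot[reef_idx, np.arange(n)] = 1.0
        # zone of each reef (nesting: each reef belongs to exactly one zone)
        reef_zone_onehot = np.zeros((n_zone, n_reef))
        for r in range(n_reef):
            zs = np.unique(zone_idx[reef_idx == r])
            if zs.size != 1:
                raise ValueError("each reef must be nested in exactly one zone")
            reef_zone_onehot[zs[0], r] = 1.0
        n_extra = 2
    elif random == "zone":
        n_extra = 1
    else:
        raise ValueError(f"unknown random structure {random!r}")

    t_nodes, t_weights = np.polynomial.hermite.hermgauss(n_nodes)
    nodes = np.sqrt(2.0) * t_nodes
    logw = np.log(t_weights / np.sqrt(np.pi))

    # moment start for beta via a log-linear least-squares on log1p counts
    z0 = np.log1p(y) - offset
    beta0, *_ = np.linalg.lstsq(X, z0, rcond=None)
    # a warm start (e.g. the nested null's optimum) replaces the moment starts:
    # it already encodes the variance-component structure. Cold fits try both a
    # moderate and a near-zero variance start; with few groups the likelihood
    # can hold distinct local modes in the variance components.
    if x0_extra is not None:
        starts = [np.asarray(x0_extra, dtype=float)]
    else:
        starts = [
            np.concatenate([beta0, [np.log(2.0)], [np.log(0.3)] * n_extra]),
            np.concatenate([beta0, [np.log(2.0)], [np.log(0.05)] * n_extra]),
        ]

    def nll(params):
        with np.errstate(over="ignore", invalid="ignore"):
            ll = _loglik(params, y, X, offset, zone_onehot, reef_onehot,
                         reef_zone_onehot, nodes, logw, random)
        return -ll if np.isfinite(ll) else 1e12

    res = None
    for x0 in starts:
        r = optimize.minimize(nll, x0, method="Nelder-Mead",
                              options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-7})
        # polishing restart from the optimum guards against premature collapse
        r2 = optimize.minimize(nll, r.x, method="Nelder-Mead",
                               options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8})
        if r2.fun <= r.fun:
            r = r2
        if res is None or r.fun < res.fun:
            res = r
    params = res.x
    beta = params[:p]
    theta = float(np.exp(np.clip(params[p], -10, 10)))
    sigma_zone = float(np.exp(np.clip(params[p + 1], _LOG_SD_MIN, _LOG_SD_MAX)))
    sigma_reef = (float(np.exp(np.clip(params[p + 2], _LOG_SD_MIN, _LOG_SD_MAX)))
                  if n_extra == 2 else None)

    beta_se = None
    if compute_se:
        beta_se = _beta_se(params, p, nll)
    return NBMixedFit(
        beta=beta, beta_se=beta_se, theta=theta, sigma_zone=sigma_zone,
        sigma_reef=sigma_reef, loglik=float(-res.fun),
        converged=bool(res.success), n=n, random=random, params_=params,
    )


def _beta_se(params: np.ndarray, p: int, nll) -> np.ndarray | None:
    """Observed-information SEs for the fixed effects via a central-difference
    Hessian. Variance components that collapsed to the lower bound are held
    fixed (the likelihood is flat there and would make the Hessian singular)."""
    m = params.size
    free = [i for i in range(m) if i < p + 1 or params[i] > _LOG_SD_MIN + 1e-4]
    h = 1e-4 * np.maximum(1.0, np.abs(params))
    H = np.zeros((len(free), len(free)))
    for a, i in enumerate(free):
        for b, j in enumerate(free[a:], start=a):
            pp = params.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = params.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = params.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = params.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            H[a, b] = H[b, a] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        var = np.diag(cov)[:p]
        if np.any(var <= 0) or not np.all(np.isfinite(var)):
            return None
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        return None


def lrt(full: NBMixedFit, null: NBMixedFit) -> tuple[float, float]:
    """Likelihood-ratio chi-square (df 1) and p-value for nested fits.

    The statistic is clipped at zero: tiny negative values can arise from the
    quadrature/optimizer tolerance even though l_full >= l_null in exact
    arithmetic for nested models.
    """
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    return chi2, float(stats.chi2.sf(chi2, df=1))
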
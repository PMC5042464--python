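"""Binomial mixed models by Gauss-Hermite quadrature.

Shared engine for the per-SNP frequency tests, the selection-trajectory
fit and the vial-level daily-survival model.  All three are logistic
models for counts ``y`` out of ``n`` with

* optional fixed effects ``X @ beta`` on the logit scale,
* an optional grouped random intercept (replicate population or
  reciprocal cross), and
* an optional observation-level random effect (OLRE) that absorbs
  overdispersion relative to the binomial.

Because the OLRE is independent across observations, its integral
factorises and each observation needs only a one-dimensional
Gauss-Hermite quadrature; a grouped intercept adds one outer quadrature
per group.  Both integrals use quadrature against the standard normal
density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

__all__ = ["BinomialMixedFit", "fit_binomial_mixed", "lr_test"]

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/log-weights for integrating against the N(0,1) density."""
    if k not in _GH_CACHE:
        x, w = hermgauss(k)
        _GH_CACHE[k] = (np.sqrt(2.0) * x, np.log(w) - 0.5 * np.log(np.pi))
    return _GH_CACHE[k]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """Log-sum-exp along one axis (lean replacement for the scipy call
    in the optimizer hot path)."""
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


@dataclass
class BinomialMixedFit:
    """Result of a binomial mixed-model fit."""

    beta: np.ndarray
    beta_se: np.ndarray
    sigma_olre: float
    sigma_group: float
    loglik: float
    converged: bool
    n_obs: int
    beta_names: list[str] = field(default_factory=list)
    cov: np.ndarray | None = None

    def wald_z(self, j: int = -1) -> float:
        return float(self.beta[j] / self.beta_se[j])


def _loglik(params, y, n, X, group_index, n_groups, olre, grouped, logc,
            k_inner=21, k_outer=21):
    """Marginal log-likelihood; quadrature over OLRE and group effects."""
    p = X.shape[1]
    beta = params[:p]
    eta = X @ beta
    i = p
    tau = np.exp(params[i]) if grouped else 0.0
    if grouped:
        i += 1
    sig = np.exp(params[i]) if olre else 0.0

    if grouped:
        a, lwa = _gh(k_outer)
        if olre:
            z, lwz = _gh(k_inner)
            lp = (eta[:, None, None] + tau * a[None, :, None]
                  + sig * z[None, None, :])
            ll_obs = _lse(
                lwz[None, None, :] + y[:, None, None] * lp
                - n[:, None, None] * _softplus(lp), axis=2)
        else:
            lp = eta[:, None] + tau * a[None, :]
            ll_obs = y[:, None] * lp - n[:, None] * _softplus(lp)
        # sum observations within group, then integrate the group effect
        gsum = np.zeros((n_groups, ll_obs.shape[1]))
        np.add.at(gsum, group_index, ll_obs)
        return float(np.sum(_lse(lwa[None, :] + gsum, axis=1)) + logc)
    if olre:
        z, lwz = _gh(k_inner)
        lp = eta[:, None] + sig * z[None, :]
        ll_obs = _lse(
            lwz[None, :] + y[:, None] * lp - n[:, None] * _softplus(lp),
            axis=1)
    else:
        ll_obs = y * eta - n * _softplus(eta)
    return float(np.sum(ll_obs) + logc)


def _num_hessian(f, x, h=1e-4):
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_binomial_mixed(
    y,
    n,
    X,
    groups=None,
    olre: bool = True,
    beta_names: list[str] | None = None,
    k_inner: int = 15,
    k_outer: int = 15,
    start_sd: float = 0.3,
) -> BinomialMixedFit:
    """Fit counts ``y`` out of ``n`` on design ``X`` by maximum likelihood.

    Parameters
    ----------
    groups
        Optional group labels (one per observation) for a normal random
        intercept; ``None`` means no grouped effect.
    olre
        Include an observation-level normal random effect on the logit
        scale to capture overdispersion.

    Returns a :class:`BinomialMixedFit`; standard errors come from the
    finite-difference observed information.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if np.any(n < 1):
        raise ValueError("binomial totals must be >= 1")
    if np.any((y < 0) | (y > n)):
        raise ValueError("counts must lie in [0, n]")

    grouped = groups is not None
    if grouped:
        _, group_index = np.unique(np.asarray(groups), return_inverse=True)
        n_groups = int(group_index.max()) + 1
        if n_groups < 2:
            warnings.warn("single group: dropping grouped random intercept")
            grouped = False
            group_index, n_groups = None, 0
    else:
        group_index, n_groups = None, 0

    logc = float(np.sum(special.gammaln(n + 1) - special.gammaln(y + 1)
                        - special.gammaln(n - y + 1)))

    p = X.shape[1]
    # empirical-logit least squares start for beta
    adj = (y + 0.5) / (n + 1.0)
    elogit = np.log(adj / (1 - adj))
    beta0, *_ = np.linalg.lstsq(X, elogit, rcond=None)
    x0 = list(beta0)
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * p
    if grouped:
        x0.append(np.log(start_sd))
        bounds.append((-8.0, 4.0))
    if olre:
        x0.append(np.log(start_sd))
        bounds.append((-8.0, 4.0))
    x0 = np.array(x0)

    def nll(params):
        return -_loglik(params, y, n, X, group_index, n_groups, olre,
                        grouped, logc, k_inner, k_outer)

    # Nelder-Mead first: variance parameters often end on the boundary,
    # where finite-difference gradients mislead quasi-Newton methods
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-10,
                                     "maxiter": 2000})
    res2 = optimize.minimize(nll, res.x, method="L-BFGS-B", bounds=bounds,
                             options={"maxiter": 60})
    best = res2 if res2.fun <= res.fun else res

    H = _num_hessian(nll, best.x)
    cov = None
    se = np.full(p, np.nan)
    try:
        cov_full = np.linalg.inv(H)
        d = np.diag(cov_full)[:p]
        if not np.all(d > 0):
            raise np.linalg.LinAlgError
        se = np.sqrt(d)
        cov = cov_full[:p, :p]
    except np.linalg.LinAlgError:
        # variance components at the boundary leave flat directions;
        # the pseudo-inverse drops them and keeps the beta block usable
        cov_full = np.linalg.pinv(H, rcond=1e-10)
        d = np.diag(cov_full)[:p]
        if np.all(d > 0):
            se = np.sqrt(d)
            cov = cov_full[:p, :p]

    i = p
    tau = float(np.exp(best.x[i])) if grouped else 0.0
    if grouped:
        i += 1
    sig = float(np.exp(best.x[i])) if olre else 0.0
    return BinomialMixedFit(
        beta=best.x[:p].copy(),
        beta_se=se,
        sigma_olre=sig,
        sigma_group=tau,
        loglik=-float(best.fun),
        converged=bool(res.success or res2.success),
        n_obs=len(y),
        beta_names=beta_names or [f"b{j}" for j in range(p)],
        cov=cov,
    )


def lr_test(fit_full: BinomialMixedFit, fit_null: BinomialMixedFit,
            df: int) -> tuple[float, float]:
    """Likelihood-ratio chi-square and p-value for nested fits."""
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    return chi2, float(stats.chi2.sf(chi2, df))


# -- batched fitter ----------------------------------------------------
#
# The per-SNP frequency test fits the same small OLRE model thousands of
# times (once per position, twice per likelihood-ratio test).  The
# batched fitter runs one damped finite-difference Newton iteration
# across all positions simultaneously; it is algebraically the same
# model as fit_binomial_mixed with groups=None and agrees with it to
# optimizer tolerance.

def _batch_nll(params, y, n, Xt, nodes, logw):
    """Negative marginal log-likelihood per problem (constants dropped).

    params: (S, p+1) with the last column log sigma; y, n: (S, m);
    Xt: (m, p) shared design.
    """
    p = Xt.shape[1]
    beta = params[:, :p]
    sig = np.exp(params[:, p])
    eta = beta @ Xt.T
    lp = eta[:, :, None] + sig[:, None, None] * nodes
    a = logw + y[:, :, None] * lp - n[:, :, None] * np.logaddexp(0.0, lp)
    m = a.max(axis=2, keepdims=True)
    ll = m[..., 0] + np.log(np.exp(a - m).sum(axis=2))
    return -ll.sum(axis=1)


def fit_binomial_olre_batch(y, n, X, k_quad: int = 15, max_iter: int = 60,
                            tol: float = 1e-10):
    """Fit the OLRE binomial model independently for many problems.

    ``y`` and ``n`` are (S, m) count/total arrays sharing the (m, p)
    design ``X``.  Returns ``(beta, log_sigma, loglik)`` with the
    binomial normalizing constants included in ``loglik``.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    Xt = np.atleast_2d(np.asarray(X, dtype=float))
    S, m = y.shape
    p = Xt.shape[1]
    nodes, logw = _gh(k_quad)
    nodes = nodes[None, None, :]
    logw = logw[None, None, :]

    adj = (y + 0.5) / (n + 1.0)
    elogit = np.log(adj / (1 - adj))
    beta0 = elogit @ np.linalg.pinv(Xt).T
    params = np.concatenate(
        [beta0, np.full((S, 1), np.log(0.3))], axis=1)
    k = p + 1

    f = _batch_nll(params, y, n, Xt, nodes, logw)
    h = 1e-4
    eye = np.eye(k) * h
    for _ in range(max_iter):
        grad = np.empty((S, k))
        hess = np.empty((S, k, k))
        for i in range(k):
            fp = _batch_nll(params + eye[i], y, n, Xt, nodes, logw)
            fm = _batch_nll(params - eye[i], y, n, Xt, nodes, logw)
            grad[:, i] = (fp - fm) / (2 * h)
            hess[:, i, i] = (fp - 2 * f + fm) / (h * h)
        for i in range(k):
            for j in range(i + 1, k):
                fpp = _batch_nll(params + eye[i] + eye[j], y, n, Xt,
                                 nodes, logw)
                fpm = _batch_nll(params + eye[i] - eye[j], y, n, Xt,
                                 nodes, logw)
                fmp = _batch_nll(params - eye[i] + eye[j], y, n, Xt,
                                 nodes, logw)
                fmm = _batch_nll(params - eye[i] - eye[j], y, n, Xt,
                                 nodes, logw)
                hess[:, i, j] = hess[:, j, i] = (
                    fpp - fpm - fmp + fmm) / (4 * h * h)
        # Levenberg-style ridge keeps indefinite Hessians descending
        ridge = 1e-6 * np.maximum(
            1.0, np.abs(hess.reshape(S, -1)).max(axis=1))
        hess[:, np.arange(k), np.arange(k)] += ridge[:, None]
        try:
            step = np.linalg.solve(hess, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.einsum("sij,sj->si", np.linalg.pinv(hess), grad)
        lam = np.ones(S)
        new = params - step
        new[:, p] = np.clip(new[:, p], -8.0, 4.0)
        fn = _batch_nll(new, y, n, Xt, nodes, logw)
        for _ in range(25):
            worse = fn > f + 1e-12
            if not worse.any():
                break
            lam[worse] *= 0.5
            new[worse] = params[worse] - lam[worse, None] * step[worse]
            new[:, p] = np.clip(new[:, p], -8.0, 4.0)
            fn_w = _batch_nll(new[worse], y[worse], n[worse], Xt, nodes,
                              logw)
            fn[worse] = fn_w
        improved = fn <= f
        params[improved] = new[improved]
        gain = f - fn
        f = np.where(improved, fn, f)
        if np.all(np.abs(gain) < tol * (np.abs(f) + 1)):
            break
    logc = np.sum(special.gammaln(n + 1) - special.gammaln(y + 1)
                  - special.gammaln(n - y + 1), axis=1)
    return params[:, :p], params[:, p], -f + logc
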
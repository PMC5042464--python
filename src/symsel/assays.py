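"""Survival and reproduction models for the fitness assays.

Female progeny of reciprocal crosses between isofemale lines carrying
competing symbiont clades are assayed after viral infection:

* daily survival — vial-level binomial GLMM (clade fixed effect, cross
  random intercept, vial-level overdispersion), at days 5-7;
* full survival dynamics — mixed-effects Cox model with cross and vial
  frailties, censored at 20 days;
* reproductive output — linear mixed model of pupae counts with cross
  random intercept; optionally a hurdle model (mixed logistic zero
  part + zero-truncated negative-binomial count part) when many
  females fail to reproduce;
* Tukey-type pairwise contrasts with single-step multivariate-normal
  adjustment.

Fixed-effect tests are likelihood-ratio tests against the model without
the focal term, on full maximum-likelihood fits.  The factorial design
(cytotype x symbiont presence, after tetracycline clearing) is handled
by an interaction term with within-presence clade contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

from .coxfrailty import CoxFrailtyModel
from .glmm import fit_binomial_mixed, lr_test
from .results import MixedFitResult

__all__ = [
    "fit_daily_survival_glmm",
    "fit_cox_frailty",
    "fit_fecundity_lmm",
    "fit_hurdle",
    "pairwise_contrasts",
    "ztnb_logpmf",
]


def _design(df: pd.DataFrame, factorial: bool):
    """Fixed-effect design for clade (III vs reference V), optionally
    crossed with symbiont presence."""
    clade = (df["clade"].astype(str) == "III").to_numpy(float)
    if factorial:
        absent = (~df["wolbachia"].astype(bool)).to_numpy(float)
        X = np.column_stack([clade, absent, clade * absent])
        names = ["clade[III]", "wolbachia[absent]",
                 "clade[III]:wolbachia[absent]"]
        focal = [0, 2]  # clade main effect + interaction
    else:
        X = clade[:, None]
        names = ["clade[III]"]
        focal = [0]
    return X, names, focal


def _is_factorial(df: pd.DataFrame) -> bool:
    return "wolbachia" in df.columns and df["wolbachia"].nunique() > 1


def fit_daily_survival_glmm(table: pd.DataFrame, day: int) -> MixedFitResult:
    """Vial-level survival GLMM at a fixed day post-infection.

    ``table`` is individual-level (columns vial, cross, clade, day,
    event, optionally wolbachia).  Per vial the number of flies still
    alive after ``day`` out of the initial count is modelled as
    binomial with clade fixed effect, cross random intercept and
    vial-level (observation-level) overdispersion; the clade effect is
    tested by likelihood ratio.
    """
    factorial = _is_factorial(table)
    alive = (table["day"] > day) | (table["event"] == 0)
    agg = table.assign(alive=alive.astype(int)).groupby("vial").agg(
        surv=("alive", "sum"), total=("alive", "size"),
        cross=("cross", "first"), clade=("clade", "first"),
        **({"wolbachia": ("wolbachia", "first")} if factorial else {}))
    if len(agg) < 2:
        raise ValueError("need >= 2 vials")
    y = agg["surv"].to_numpy(float)
    n = agg["total"].to_numpy(float)
    degenerate = None
    if y.sum() == 0 or (y == n).all():
        degenerate = "all flies dead or all alive at this day"
    Xf, names, focal = _design(agg, factorial)
    X = np.column_stack([np.ones(len(agg)), Xf])
    names = ["intercept"] + names
    groups = agg["cross"].to_numpy()
    full = fit_binomial_mixed(y, n, X, groups=groups, beta_names=names)
    keep = [0] + [1 + j for j in range(Xf.shape[1])
                  if j not in focal]
    null = fit_binomial_mixed(y, n, X[:, keep], groups=groups)
    chi2, p = lr_test(full, null, df=len(focal))
    cov = full.cov if full.cov is not None else np.full(
        (len(names), len(names)), np.nan)
    return MixedFitResult(
        params=pd.Series(full.beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        ranef_var={"cross": full.sigma_group ** 2,
                   "vial_olre": full.sigma_olre ** 2},
        loglik=full.loglik, chi2=chi2, df=len(focal), p=p,
        converged=full.converged, degenerate=degenerate,
        model=f"daily_survival_glmm(day={day})",
        extra={"factorial": factorial})


def fit_cox_frailty(table: pd.DataFrame) -> MixedFitResult:
    """Mixed-effects Cox model of time to death, censored at day 20.

    Clade fixed effect (hazard ratio of clade III vs V), normal random
    effects for cross and vial, Efron tie handling; the clade term
    (main effect plus, in the factorial design, its interaction with
    symbiont presence) is tested by likelihood ratio on the Laplace
    integrated likelihood.  In the factorial design the result carries
    within-presence clade z-tests.
    """
    factorial = _is_factorial(table)
    X, names, focal = _design(table, factorial)
    rand = {"cross": table["cross"].to_numpy(),
            "vial": table["vial"].to_numpy()}
    full_m = CoxFrailtyModel(table["day"], table["event"], X, rand)
    full = full_m.fit()
    keep = [j for j in range(X.shape[1]) if j not in focal]
    if keep:
        null_m = CoxFrailtyModel(table["day"], table["event"], X[:, keep],
                                 rand)
        null = null_m.fit()
    else:
        null_m = CoxFrailtyModel(
            table["day"], table["event"], np.zeros((len(table), 0)), rand)
        null = null_m.fit()
    chi2 = max(0.0, 2.0 * (full["loglik"] - null["loglik"]))
    p = float(stats.chi2.sf(chi2, len(focal)))
    cov = pd.DataFrame(full["cov"], index=names, columns=names)
    res = MixedFitResult(
        params=pd.Series(full["beta"], index=names),
        cov=cov,
        ranef_var={k: v ** 2 for k, v in full["sigmas"].items()},
        loglik=full["loglik"], chi2=chi2, df=len(focal), p=p,
        converged=full["converged"], model="cox_frailty",
        extra={"factorial": factorial,
               "hazard_ratio": float(np.exp(full["beta"][0]))})
    if factorial:
        rows = []
        for label, c in (("clade within wolbachia+", [1.0, 0.0, 0.0]),
                         ("clade within wolbachia-", [1.0, 0.0, 1.0])):
            c = np.asarray(c)
            est = float(c @ full["beta"])
            se = float(np.sqrt(c @ full["cov"] @ c))
            z = est / se
            rows.append((label, est, se, z, 2 * stats.norm.sf(abs(z))))
        res.contrasts = pd.DataFrame(
            rows, columns=["contrast", "estimate", "se", "z", "p"])
    return res


def fit_fecundity_lmm(table: pd.DataFrame) -> MixedFitResult:
    """Linear mixed model of pupae counts with cross random intercept.

    ML fits (not REML) so the clade likelihood-ratio test is valid for
    nested fixed-effect structures.
    """
    factorial = _is_factorial(table)
    if table["cross"].nunique() < 2:
        warnings.warn("single cross: falling back to ordinary least squares")
        return _fecundity_ols(table, factorial)
    y = table["pupae"].to_numpy(float)
    Xf, names, focal = _design(table, factorial)
    X = np.column_stack([np.ones(len(table)), Xf])
    names = ["intercept"] + names
    groups = table["cross"].to_numpy()
    full = sm.MixedLM(y, X, groups=groups).fit(reml=False)
    keep = [0] + [1 + j for j in range(Xf.shape[1]) if j not in focal]
    null = sm.MixedLM(y, X[:, keep], groups=groups).fit(reml=False)
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(chi2, len(focal)))
    k = len(names)
    cov = np.asarray(full.cov_params())[:k, :k]
    return MixedFitResult(
        params=pd.Series(np.asarray(full.fe_params), index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        ranef_var={"cross": float(np.asarray(full.cov_re)[0, 0]),
                   "residual": float(full.scale)},
        loglik=float(full.llf), chi2=chi2, df=len(focal), p=p,
        converged=bool(full.converged), model="fecundity_lmm",
        extra={"factorial": factorial})


def _fecundity_ols(table, factorial):
    y = table["pupae"].to_numpy(float)
    Xf, names, focal = _design(table, factorial)
    X = np.column_stack([np.ones(len(table)), Xf])
    names = ["intercept"] + names
    full = sm.OLS(y, X).fit()
    null = sm.OLS(y, X[:, [0] + [1 + j for j in range(Xf.shape[1])
                                 if j not in focal]]).fit()
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    return MixedFitResult(
        params=pd.Series(full.params, index=names),
        cov=pd.DataFrame(np.asarray(full.cov_params()), index=names,
                         columns=names),
        ranef_var={"residual": float(full.mse_resid)},
        loglik=float(full.llf), chi2=chi2, df=len(focal),
        p=float(stats.chi2.sf(chi2, len(focal))),
        model="fecundity_ols", extra={"factorial": factorial})


# -- hurdle model ------------------------------------------------------

def ztnb_logpmf(k, mu, alpha):
    """Zero-truncated negative binomial log-pmf (mean-dispersion form,
    Var = mu + alpha mu^2 before truncation)."""
    k = np.asarray(k, dtype=float)
    r = 1.0 / alpha
    logp0 = r * (np.log(r) - np.log(r + mu))
    lognb = (special.gammaln(k + r) - special.gammaln(r)
             - special.gammaln(k + 1)
             + r * (np.log(r) - np.log(r + mu))
             + k * (np.log(mu) - np.log(r + mu)))
    return lognb - np.log1p(-np.exp(logp0))


def _ztnb_mixed_nll(params, y, X, group_index, n_groups, nodes, logw):
    p = X.shape[1]
    beta, log_alpha, log_tau = params[:p], params[p], params[p + 1]
    alpha = np.exp(log_alpha)
    tau = np.exp(log_tau)
    eta = X @ beta
    # (obs, nodes)
    mu = np.exp(eta[:, None] + tau * nodes[None, :])
    ll_obs = ztnb_logpmf(y[:, None], mu, alpha)
    gsum = np.zeros((n_groups, len(nodes)))
    np.add.at(gsum, group_index, ll_obs)
    return -float(np.sum(special.logsumexp(logw[None, :] + gsum, axis=1)))


def fit_hurdle(table: pd.DataFrame) -> MixedFitResult:
    """Two-part hurdle model for pupae counts.

    Zero part: mixed logistic model of reproducing (count > 0) vs not,
    cross random intercept.  Count part: zero-truncated negative
    binomial mixed model on the positive counts (log link, cross
    random intercept integrated by Gauss-Hermite quadrature).  The
    likelihood-ratio test reported is for the focal clade term (the
    interaction in the factorial design) in the count part.
    """
    y_all = table["pupae"].to_numpy(float)
    if np.any(y_all < 0):
        raise ValueError("counts must be nonnegative")
    pos = table[table["pupae"] > 0]
    if not len(pos):
        raise ValueError("no positive counts: count part unidentifiable")
    factorial = _is_factorial(table)

    zero_fit = None
    if (y_all == 0).any():
        Xf, names_z, focal_z = _design(table, factorial)
        X = np.column_stack([np.ones(len(table)), Xf])
        reproduced = (y_all > 0).astype(float)
        zero_fit = fit_binomial_mixed(
            reproduced, np.ones_like(reproduced), X,
            groups=table["cross"].to_numpy(),
            beta_names=["intercept"] + names_z)
    else:
        warnings.warn("no zero counts: zero part skipped")

    Xf, names, focal = _design(pos, factorial)
    X = np.column_stack([np.ones(len(pos)), Xf])
    names = ["intercept"] + names
    y = pos["pupae"].to_numpy(float)
    _, gidx = np.unique(pos["cross"].to_numpy(), return_inverse=True)
    ngrp = int(gidx.max()) + 1
    x, w = hermgauss(21)
    nodes, logw = np.sqrt(2.0) * x, np.log(w) - 0.5 * np.log(np.pi)

    def fit_part(Xmat):
        p = Xmat.shape[1]
        b0 = np.zeros(p)
        b0[0] = np.log(max(y.mean(), 1.0))
        x0 = np.concatenate([b0, [np.log(0.3), np.log(0.3)]])
        bounds = [(None, None)] * p + [(-8, 4), (-8, 4)]
        res = optimize.minimize(
            _ztnb_mixed_nll, x0, args=(y, Xmat, gidx, ngrp, nodes, logw),
            method="L-BFGS-B", bounds=bounds)
        res2 = optimize.minimize(
            _ztnb_mixed_nll, res.x, args=(y, Xmat, gidx, ngrp, nodes, logw),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
        return res2 if res2.fun <= res.fun else res

    full = fit_part(X)
    keepc = [0] + [1 + j for j in range(Xf.shape[1]) if j not in focal]
    null = fit_part(X[:, keepc])
    chi2 = max(0.0, 2.0 * (null.fun - full.fun))
    p_lrt = float(stats.chi2.sf(chi2, len(focal)))

    # observed-information covariance of the count-part fixed effects
    from .glmm import _num_hessian
    H = _num_hessian(
        lambda th: _ztnb_mixed_nll(th, y, X, gidx, ngrp, nodes, logw),
        full.x)
    k = len(names)
    try:
        cov = np.linalg.inv(H)[:k, :k]
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    alpha = float(np.exp(full.x[k]))
    tau = float(np.exp(full.x[k + 1]))
    res = MixedFitResult(
        params=pd.Series(full.x[:k], index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        ranef_var={"cross": tau ** 2},
        loglik=-float(full.fun), chi2=chi2, df=len(focal), p=p_lrt,
        converged=True, model="hurdle_ztnb",
        extra={"dispersion_alpha": alpha, "factorial": factorial,
               "zero_part": zero_fit})
    if factorial:
        rows = []
        for label, c in (("clade within wolbachia+", [0, 1.0, 0.0, 0.0]),
                         ("clade within wolbachia-", [0, 1.0, 0.0, 1.0])):
            c = np.asarray(c)
            est = float(c @ full.x[:k])
            se = float(np.sqrt(c @ cov @ c))
            z = est / se
            rows.append((label, est, se, z, 2 * stats.norm.sf(abs(z))))
        res.contrasts = pd.DataFrame(
            rows, columns=["contrast", "estimate", "se", "z", "p"])
    return res


# -- multiplicity-adjusted pairwise contrasts --------------------------

def _mvn_max_abs_sf(z: float, R: np.ndarray, rng_seed: int = 0) -> float:
    """P(max_j |Z_j| > z) for Z ~ MVN(0, R).

    Uses scipy's quasi-Monte-Carlo MVN rectangle integrator; contrast
    covariances are rank-deficient for >2 levels, so on failure the
    probability is estimated by direct simulation from the (possibly
    singular) distribution.
    """
    k = R.shape[0]
    lo = np.full(k, -abs(z))
    hi = np.full(k, abs(z))
    try:
        mvn = stats.multivariate_normal(np.zeros(k), R, allow_singular=True,
                                        seed=rng_seed)
        pr = float(mvn.cdf(hi, lower_limit=lo))
        if np.isfinite(pr):
            return float(min(max(1.0 - pr, 0.0), 1.0))
    except Exception:
        pass
    rng = np.random.default_rng(rng_seed)
    vals, vecs = np.linalg.eigh(R)
    A = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    Z = rng.standard_normal((400_000, k)) @ A.T
    return float(np.mean(np.abs(Z).max(axis=1) > abs(z)))


def pairwise_contrasts(estimates, cov, labels=None,
                       adjustment: str = "mvn") -> pd.DataFrame:
    """All pairwise comparisons of level estimates on the link scale.

    ``estimates`` are the fitted level means (length k) with covariance
    ``cov``; z statistics are adjusted single-step over the whole
    contrast family using the multivariate-normal distribution of the
    contrast estimates (Tukey-type), or by Holm with
    ``adjustment="holm"``.
    """
    est = np.asarray(estimates, dtype=float)
    V = np.asarray(cov, dtype=float)
    k = len(est)
    if k < 2:
        raise ValueError("need >= 2 levels")
    if labels is None:
        labels = [f"level{j}" for j in range(k)]
    C = []
    names = []
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(k)
            c[i], c[j] = 1.0, -1.0
            C.append(c)
            names.append(f"{labels[i]} - {labels[j]}")
    C = np.asarray(C)
    diffs = C @ est
    Vc = C @ V @ C.T
    ses = np.sqrt(np.diag(Vc))
    zs = diffs / ses
    R = Vc / np.outer(ses, ses)
    if adjustment == "mvn":
        padj = np.array([_mvn_max_abs_sf(z, R) for z in zs])
    elif adjustment == "holm":
        from .poolseq import holm_adjust
        padj = holm_adjust(2 * stats.norm.sf(np.abs(zs)))
    else:
        raise ValueError("adjustment must be 'mvn' or 'holm'")
    return pd.DataFrame({
        "contrast": names, "estimate": diffs, "se": ses, "z": zs,
        "p_raw": 2 * stats.norm.sf(np.abs(zs)), "p_adj": padj})
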
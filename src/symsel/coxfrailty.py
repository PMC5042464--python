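"""Mixed-effects Cox proportional-hazards model (normal frailties).

The hazard of individual i from cross j in vial k is

    H_ijk(t) = H_0(t) * exp(x_i' beta + c_j + e_k)

with c_j ~ N(0, sigma_cross^2) and e_k ~ N(0, sigma_vial^2) acting as
log-normal frailties.  Estimation follows the penalized partial
likelihood approach: for fixed variance components, (beta, b) maximize
the Efron-tie partial likelihood minus the Gaussian penalty by Newton
iterations; variance components are then chosen to maximize the Laplace
approximation of the integrated partial likelihood.  Likelihood-ratio
tests of fixed effects compare integrated likelihoods of refitted
nested models.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

__all__ = ["efron_partial_loglik", "CoxFrailtyModel"]


def _risk_structures(durations, events):
    """Pre-compute risk/death index masks per distinct event time."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValueError("no events in the data")
    times = np.unique(durations[events])
    risk_masks, death_masks = [], []
    for t in times:
        risk_masks.append(durations >= t)
        death_masks.append((durations == t) & events)
    return times, risk_masks, death_masks


def efron_partial_loglik(eta, risk_masks, death_masks,
                         want_derivs: bool = False, W=None):
    """Efron-tie Cox partial log-likelihood of a linear predictor.

    With ``want_derivs`` also returns the gradient and Hessian with
    respect to the coefficients of design ``W`` (eta = W @ theta),
    exploiting the fact that every within-tie term is a linear
    combination of the risk-set and death-set exponential-score
    vectors.
    """
    eta = np.asarray(eta, dtype=float)
    ex = np.exp(eta)
    ll = 0.0
    if want_derivs:
        p = W.shape[1]
        grad_eta = np.zeros_like(eta)
        wtot = np.zeros_like(eta)       # accumulated diag weights
        U = []                          # columns W' w_jl for outer products
    for rmask, dmask in zip(risk_masks, death_masks):
        d = int(dmask.sum())
        r = ex * rmask
        dv = ex * dmask
        S_r, S_d = r.sum(), dv.sum()
        cs = np.arange(d) / d
        phis = S_r - cs * S_d
        ll += eta[dmask].sum() - np.log(phis).sum()
        if want_derivs:
            inv = 1.0 / phis
            a0, a1 = inv.sum(), (cs * inv).sum()
            grad_eta += dmask.astype(float) - (r * a0 - dv * a1)
            wtot += r * a0 - dv * a1
            Wr, Wd = W.T @ r, W.T @ dv
            U.append((Wr[:, None] - np.outer(Wd, cs)) * inv[None, :])
    if not want_derivs:
        return ll
    Umat = np.concatenate(U, axis=1)
    grad = W.T @ grad_eta
    hess = -(W.T @ (wtot[:, None] * W)) + Umat @ Umat.T
    return ll, grad, hess


def _random_design(labels):
    cats, idx = np.unique(np.asarray(labels), return_inverse=True)
    Z = np.zeros((len(idx), len(cats)))
    Z[np.arange(len(idx)), idx] = 1.0
    return Z, list(cats)


class CoxFrailtyModel:
    """Penalized-partial-likelihood Cox model with normal random effects.

    Parameters
    ----------
    durations, events
        Day of death/censoring and event flag per individual.
    X
        Fixed-effect design (no intercept; the baseline hazard absorbs
        it).
    random_labels
        Mapping term-name -> per-individual group labels; one normal
        random intercept per term.  Empty mapping gives a plain Cox
        fit.
    """

    def __init__(self, durations, events, X, random_labels=None):
        self.durations = np.asarray(durations, dtype=float)
        self.events = np.asarray(events, dtype=bool)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(self.durations):
            X = X.T
        self.X = X
        self.p = X.shape[1]
        (self.times, self.risk_masks,
         self.death_masks) = _risk_structures(self.durations, self.events)
        self.terms = []
        Zs = []
        if random_labels:
            for name, labels in random_labels.items():
                Z, cats = _random_design(labels)
                self.terms.append((name, Z.shape[1]))
                Zs.append(Z)
        self.Z = np.concatenate(Zs, axis=1) if Zs else np.zeros(
            (len(self.durations), 0))
        self.q = self.Z.shape[1]
        self.W = np.concatenate([self.X, self.Z], axis=1)
        self._warm: np.ndarray | None = None

    # -- inner problem -------------------------------------------------
    def _penalty_diag(self, sigmas):
        d = np.zeros(self.p + self.q)
        off = self.p
        for (name, k), sg in zip(self.terms, sigmas):
            d[off:off + k] = 1.0 / max(sg, 1e-8) ** 2
            off += k
        return d

    def _inner_fit(self, sigmas, theta0=None, tol=1e-9, max_iter=50):
        pen = self._penalty_diag(sigmas)
        theta = np.zeros(self.p + self.q) if theta0 is None else theta0.copy()
        obj_prev = -np.inf
        for _ in range(max_iter):
            ll, grad, hess = efron_partial_loglik(
                self.W @ theta, self.risk_masks, self.death_masks,
                want_derivs=True, W=self.W)
            obj = ll - 0.5 * np.sum(pen * theta * theta)
            g = grad - pen * theta
            Hn = -(hess - np.diag(pen))
            try:
                step = np.linalg.solve(Hn, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(Hn, g, rcond=None)[0]
            # dampen steps that do not improve the objective
            lam = 1.0
            for _ in range(30):
                cand = theta + lam * step
                llc = efron_partial_loglik(self.W @ cand, self.risk_masks,
                                           self.death_masks)
                objc = llc - 0.5 * np.sum(pen * cand * cand)
                if objc >= obj - 1e-12:
                    break
                lam *= 0.5
            theta = cand
            if abs(objc - obj_prev) < tol * (abs(obj_prev) + 1):
                obj_prev = objc
                break
            obj_prev = objc
        ll, grad, hess = efron_partial_loglik(
            self.W @ theta, self.risk_masks, self.death_masks,
            want_derivs=True, W=self.W)
        Hpen = -(hess - np.diag(pen))
        return theta, ll, Hpen

    def integrated_loglik(self, sigmas):
        """Laplace approximation of the integrated partial likelihood."""
        theta, ll, Hpen = self._inner_fit(sigmas, theta0=self._warm)
        self._warm = theta
        if self.q == 0:
            return ll, theta, Hpen
        pen = self._penalty_diag(sigmas)[self.p:]
        b = theta[self.p:]
        Kbb = Hpen[self.p:, self.p:]
        sign, logdet_K = np.linalg.slogdet(Kbb)
        if sign <= 0:
            return -np.inf, theta, Hpen
        logdet_D = -np.sum(np.log(pen))  # |D| = prod sigma^2
        il = (ll - 0.5 * np.sum(pen * b * b)
              - 0.5 * logdet_D - 0.5 * logdet_K)
        return il, theta, Hpen

    def fit(self, start_sd: float = 0.3):
        """Maximize the Laplace likelihood over the variance components.

        Returns a dict with beta, cov (fixed-effect block of the inverse
        penalized Hessian), per-term frailty SDs, the integrated
        log-likelihood and a convergence flag.
        """
        if not self.terms:
            theta, ll, Hpen = self._inner_fit(np.array([]))
            cov = np.linalg.inv(Hpen)[:self.p, :self.p] if self.p else \
                np.zeros((0, 0))
            return {"beta": theta[:self.p], "cov": cov, "sigmas": {},
                    "loglik": ll, "converged": True,
                    "ranef": np.zeros(0)}

        def neg_il(log_sg):
            il, *_ = self.integrated_loglik(np.exp(log_sg))
            return -il

        x0 = np.full(len(self.terms), np.log(start_sd))
        res = optimize.minimize(
            neg_il, x0, method="Nelder-Mead",
            bounds=[(-6.0, 2.0)] * len(self.terms),
            options={"xatol": 5e-3, "fatol": 1e-4, "maxiter": 80})
        sigmas = np.exp(res.x)
        il, theta, Hpen = self.integrated_loglik(sigmas)
        cov = np.linalg.inv(Hpen)[:self.p, :self.p]
        return {"beta": theta[:self.p], "cov": cov,
                "sigmas": {name: float(sg)
                           for (name, _), sg in zip(self.terms, sigmas)},
                "loglik": float(il), "converged": bool(res.success),
                "ranef": theta[self.p:]}
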
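"""Mixed-effects survival, fecundity and hurdle models against
independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from symsel.assays import (fit_cox_frailty, fit_daily_survival_glmm,
                           fit_fecundity_lmm, fit_hurdle,
                           pairwise_contrasts, ztnb_logpmf)
from symsel.coxfrailty import CoxFrailtyModel, efron_partial_loglik, \
    _risk_structures
from symsel.simulate import AssayEffects, simulate_fitness_assays


# -- Cox ---------------------------------------------------------------

def _naive_efron(eta, durations, events):
    """Direct textbook implementation of the Efron partial likelihood."""
    eta = np.asarray(eta, float)
    ll = 0.0
    for t in np.unique(durations[events.astype(bool)]):
        D = np.where((durations == t) & events.astype(bool))[0]
        R = np.where(durations >= t)[0]
        d = len(D)
        s_r = np.exp(eta[R]).sum()
        s_d = np.exp(eta[D]).sum()
        ll += eta[D].sum()
        for ell in range(d):
            ll -= np.log(s_r - ell / d * s_d)
    return ll


@pytest.fixture(scope="module")
def small_surv():
    surv, _, _ = simulate_fitness_assays(
        AssayEffects(n_crosses=2, vials_per_group=2, flies_per_vial=4),
        seed=31)
    return surv


def test_efron_loglik_matches_naive(small_surv):
    d = small_surv
    rng = np.random.default_rng(0)
    eta = rng.normal(size=len(d))
    times, rm, dm = _risk_structures(d["day"].to_numpy(float),
                                     d["event"].to_numpy(bool))
    got = efron_partial_loglik(eta, rm, dm)
    want = _naive_efron(eta, d["day"].to_numpy(float),
                        d["event"].to_numpy(float))
    assert got == pytest.approx(want, abs=1e-10)


def test_zero_frailty_cox_matches_direct_optimization(small_surv):
    """Plain Cox on <=30 individuals against brute-force maximization
    of the partial likelihood."""
    d = small_surv.sample(30, random_state=1)
    x = (d["clade"] == "III").to_numpy(float)
    model = CoxFrailtyModel(d["day"], d["event"], x[:, None])
    fit = model.fit()
    nll = lambda b: -_naive_efron(b[0] * x, d["day"].to_numpy(float),
                                  d["event"].to_numpy(float))
    oracle = optimize.minimize_scalar(lambda b: nll([b]), bounds=(-4, 4),
                                      method="bounded",
                                      options={"xatol": 1e-10})
    assert fit["beta"][0] == pytest.approx(oracle.x, abs=1e-6)
    assert fit["loglik"] == pytest.approx(-oracle.fun, abs=1e-6)


def test_cox_identical_groups_hazard_ratio_one():
    rng = np.random.default_rng(5)
    n = 80
    day = np.minimum(np.ceil(rng.exponential(8, n)), 20).astype(int)
    d = pd.DataFrame({
        "day": day, "event": (day < 20).astype(int),
        "clade": np.where(np.arange(n) % 2 == 0, "V", "III"),
        "cross": np.repeat([f"c{i}" for i in range(4)], n // 4),
        "vial": np.repeat([f"v{i}" for i in range(8)], n // 8)})
    fit = fit_cox_frailty(d)
    assert fit.extra["hazard_ratio"] == pytest.approx(1.0, abs=0.35)
    assert fit.p > 0.05


def test_cox_invariant_to_monotone_time_relabeling(small_surv):
    d = small_surv.copy()
    fit1 = fit_cox_frailty(d)
    d2 = d.assign(day=d["day"] ** 2 + 3)
    fit2 = fit_cox_frailty(d2)
    assert fit1.params.iloc[0] == pytest.approx(fit2.params.iloc[0],
                                                abs=1e-4)


def test_cox_requires_events():
    d = pd.DataFrame({"day": [20, 20], "event": [0, 0],
                      "clade": ["V", "III"], "cross": ["c", "c"],
                      "vial": ["a", "b"]})
    with pytest.raises(ValueError, match="no events"):
        fit_cox_frailty(d)


def test_cox_detects_generative_hazard(assay_tables):
    surv, _, _ = assay_tables
    fit = fit_cox_frailty(surv)
    assert fit.p < 0.001
    # generative log hazard ratio 0.7
    assert fit.params["clade[III]"] == pytest.approx(0.7, abs=0.25)


def test_factorial_cox_contrasts(factorial_tables):
    surv, _, _ = factorial_tables
    fit = fit_cox_frailty(surv)
    con = fit.contrasts.set_index("contrast")
    assert abs(con.loc["clade within wolbachia+", "z"]) > 3
    assert abs(con.loc["clade within wolbachia-", "z"]) < 2


# -- daily survival GLMM ----------------------------------------------

def test_daily_survival_null_effect():
    rng = np.random.default_rng(8)
    rows = []
    for j in range(6):
        for clade in ("V", "III"):
            for v in range(3):
                vial = f"{j}_{clade}_{v}"
                for i in range(10):
                    day = int(min(np.ceil(rng.exponential(9)), 20))
                    rows.append((vial, f"c{j}", clade, day,
                                 int(day < 20)))
    d = pd.DataFrame(rows, columns=["vial", "cross", "clade", "day",
                                    "event"])
    fit = fit_daily_survival_glmm(d, 7)
    assert fit.p > 0.01
    assert abs(fit.params["clade[III]"]) < 1.0


def test_daily_survival_single_cross_matches_plain_logistic():
    """One cross, no overdispersion: deviance equals the fixed-effects
    logistic MLE computed by direct optimization."""
    rng = np.random.default_rng(4)
    rows = []
    for clade, p_die in (("V", 0.3), ("III", 0.6)):
        for v in range(6):
            vial = f"{clade}_{v}"
            for i in range(10):
                day = 5 if rng.uniform() < p_die else 20
                rows.append((vial, "c0", clade, day, int(day < 20)))
    d = pd.DataFrame(rows, columns=["vial", "cross", "clade", "day",
                                    "event"])
    with pytest.warns(UserWarning, match="single group"):
        fit = fit_daily_survival_glmm(d, 7)
    # direct binomial logistic oracle at the vial level
    agg = d.assign(alive=((d["day"] > 7) | (d["event"] == 0)).astype(int))
    agg = agg.groupby("vial").agg(surv=("alive", "sum"),
                                  tot=("alive", "size"),
                                  clade=("clade", "first"))
    y = agg["surv"].to_numpy(float)
    n = agg["tot"].to_numpy(float)
    x = (agg["clade"] == "III").to_numpy(float)

    def nll(b):
        lp = b[0] + b[1] * x
        return -(np.sum(special.gammaln(n + 1) - special.gammaln(y + 1)
                        - special.gammaln(n - y + 1)
                        + y * lp - n * np.logaddexp(0, lp)))

    oracle = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12})
    assert fit.loglik >= -oracle.fun - 1e-4
    assert fit.params["clade[III]"] == pytest.approx(oracle.x[1], abs=0.05)


def test_daily_survival_detects_clade_effect(assay_tables):
    surv, _, _ = assay_tables
    for day in (5, 6, 7):
        fit = fit_daily_survival_glmm(surv, day)
        assert fit.p < 0.001


def test_lrt_invariant_to_reference_relabeling(assay_tables):
    surv, _, _ = assay_tables
    swapped = surv.assign(clade=surv["clade"].map({"V": "III", "III": "V"}))
    a = fit_daily_survival_glmm(surv, 6)
    b = fit_daily_survival_glmm(swapped, 6)
    assert a.chi2 == pytest.approx(b.chi2, abs=0.05)


# -- fecundity ---------------------------------------------------------

def test_fecundity_identical_counts_zero_effect():
    d = pd.DataFrame({
        "cross": np.repeat([f"c{i}" for i in range(5)], 8),
        "clade": np.tile(["V"] * 4 + ["III"] * 4, 5),
        "pupae": 30})
    fit = fit_fecundity_lmm(d)
    assert abs(fit.params["clade[III]"]) < 1e-6
    assert fit.chi2 < 1e-6


def test_fecundity_single_cross_equals_ols():
    rng = np.random.default_rng(2)
    d = pd.DataFrame({
        "cross": "c0",
        "clade": np.repeat(["V", "III"], 15),
        "pupae": np.concatenate([rng.poisson(45, 15),
                                 rng.poisson(30, 15)])})
    with pytest.warns(UserWarning, match="single cross"):
        fit = fit_fecundity_lmm(d)
    yv = d.loc[d["clade"] == "V", "pupae"].mean()
    yiii = d.loc[d["clade"] == "III", "pupae"].mean()
    assert fit.params["clade[III]"] == pytest.approx(yiii - yv, abs=1e-8)


def test_fecundity_detects_generative_effect(assay_tables):
    _, fec, _ = assay_tables
    fit = fit_fecundity_lmm(fec)
    assert fit.p < 0.001
    assert fit.params["clade[III]"] < 0


# -- hurdle ------------------------------------------------------------

@pytest.mark.parametrize("mu,alpha", [(3.0, 0.5), (20.0, 0.1), (1.0, 2.0)])
def test_ztnb_pmf_normalized(mu, alpha):
    k = np.arange(1, 3000)
    total = np.exp(ztnb_logpmf(k, mu, alpha)).sum()
    assert total == pytest.approx(1.0, abs=1e-8)


def test_hurdle_parameter_recovery():
    """Count-part clade log-ratio recovered within 2 SE at the design
    size; dispersion close to truth."""
    eff = AssayEffects(n_crosses=11, females_per_group=20,
                       fecundity_cross_sd=2.0)
    _, fec, _ = simulate_fitness_assays(eff, seed=13)
    fit = fit_hurdle(fec)
    true_logratio = np.log(eff.fecundity_ratio)
    est = fit.params["clade[III]"]
    se = fit.se()["clade[III]"]
    assert abs(est - true_logratio) < 2 * se + 0.05
    assert fit.extra["dispersion_alpha"] == pytest.approx(
        eff.nb_dispersion, rel=0.6)
    assert fit.extra["zero_part"] is not None


def test_hurdle_no_positive_counts_errors():
    d = pd.DataFrame({"cross": ["a", "b"], "clade": ["V", "III"],
                      "pupae": [0, 0]})
    with pytest.raises(ValueError, match="positive"):
        fit_hurdle(d)


def test_hurdle_no_zeros_skips_zero_part():
    rng = np.random.default_rng(3)
    d = pd.DataFrame({
        "cross": np.repeat([f"c{i}" for i in range(4)], 10),
        "clade": np.tile(["V"] * 5 + ["III"] * 5, 4),
        "pupae": rng.poisson(20, 40) + 1})
    with pytest.warns(UserWarning, match="zero part skipped"):
        fit = fit_hurdle(d)
    assert fit.extra["zero_part"] is None


def test_hurdle_poisson_limit_matches_truncated_poisson_oracle():
    """Data without overdispersion: the fitted count part approaches the
    zero-truncated Poisson MLE computed directly."""
    rng = np.random.default_rng(6)
    mu_true = 8.0
    y = rng.poisson(mu_true, 400)
    y = y[y > 0][:300]
    d = pd.DataFrame({"cross": np.tile([f"c{i}" for i in range(5)], 60),
                      "clade": np.tile(["V", "III"], 150), "pupae": y})

    def tp_nll(logmu):
        mu = np.exp(logmu)
        ll = (y * np.log(mu) - mu - special.gammaln(y + 1)
              - np.log1p(-np.exp(-mu)))
        return -ll.sum()

    oracle = optimize.minimize_scalar(tp_nll, bounds=(0.5, 4),
                                      method="bounded")
    fit = fit_hurdle(d)
    fitted_mu = np.exp(fit.params["intercept"])
    assert fitted_mu == pytest.approx(np.exp(oracle.x), rel=0.05)
    assert fit.extra["dispersion_alpha"] < 0.05


def test_factorial_hurdle_interaction(factorial_tables):
    _, fec, _ = factorial_tables
    fit = fit_hurdle(fec)
    con = fit.contrasts.set_index("contrast")
    assert con.loc["clade within wolbachia+", "p"] < 0.01
    assert con.loc["clade within wolbachia-", "p"] > 0.05


# -- pairwise contrasts ------------------------------------------------

def test_contrasts_identical_levels():
    est = [0.0, 0.0]
    cov = np.eye(2) * 0.04
    res = pairwise_contrasts(est, cov, labels=["a", "b"])
    assert abs(res["z"].iloc[0]) < 1e-12
    assert res["p_adj"].iloc[0] > 0.999


def test_contrasts_match_mc_mvn_oracle():
    """Three balanced groups: the single-step adjusted p equals the
    max-|Z| tail probability estimated by direct simulation."""
    est = np.array([0.0, 0.5, 1.2])
    cov = np.eye(3) * 0.09
    res = pairwise_contrasts(est, cov, labels=list("abc"))
    C = np.array([[1, -1, 0], [1, 0, -1], [0, 1, -1]], float)
    Vc = C @ cov @ C.T
    ses = np.sqrt(np.diag(Vc))
    R = Vc / np.outer(ses, ses)
    rng = np.random.default_rng(99)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(3))
    Z = rng.standard_normal((2_000_000, 3)) @ L.T
    for k, z in enumerate(res["z"]):
        mc = np.mean(np.abs(Z).max(axis=1) > abs(z))
        assert res["p_adj"].iloc[k] == pytest.approx(mc, abs=2e-3)


def test_contrasts_holm_fallback():
    est = [0.0, 0.5, 1.0]
    cov = np.eye(3) * 0.04
    res = pairwise_contrasts(est, cov, adjustment="holm")
    assert (res["p_adj"] >= res["p_raw"] - 1e-12).all()


def test_regime_contrasts_single_out_selected(study):
    """On the simulated study the Virus-Selected regime differs from
    every other regime; the others do not differ from each other."""
    from symsel.trajectory import compare_regime_frequencies

    res, fitted = compare_regime_frequencies(study["counts"])
    fit = res["fit"]
    levels = res["levels"]
    # reconstruct level means on the logit scale with covariance
    k = len(levels)
    A = np.zeros((k, k))
    A[:, 0] = 1.0
    for j in range(1, k):
        A[j, j] = 1.0
    est = A @ fit.beta
    cov = A @ fit.cov @ A.T
    con = pairwise_contrasts(est, cov, labels=levels).set_index("contrast")
    for name, row in con.iterrows():
        if "Virus-Selected" in name:
            assert row["p_adj"] < 0.05
        else:
            assert row["p_adj"] > 0.1
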
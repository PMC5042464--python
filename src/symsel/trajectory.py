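"""Haploid selection model and selection-coefficient estimation.

For a maternally transmitted symbiont, selection acts as in a haploid:
with relative fitness ``w = 1 - s`` of the counter-selected clade, its
odds decay geometrically,

    log(p_t / q_t) = log(p_0 / q_0) + t * log(w),

so the logit of its frequency is linear in generation with slope
``log(w)``.  The selection coefficient is estimated by mixed logistic
regression of clade-carrier counts on generation with replicate-level
random intercepts (the initial frequencies) and an observation-level
random effect for overdispersion.  Two slope-to-s conventions are
supported: ``"slope"`` reports ``s = -slope`` (the small-s
approximation ``log(1-s) ~ -s``, as printed in the study this design
follows), and ``"exact"`` inverts the odds recursion, ``s = 1 -
exp(slope)``.

A neutral-drift fixation null quantifies how unlikely parallel fixation
of the majority clade across replicates would be without selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import fit_binomial_mixed, lr_test
from .poolseq import fixation_correct_counts

__all__ = [
    "TrajectoryFit",
    "deterministic_trajectory",
    "fit_selection_glmm",
    "relative_fitness",
    "drift_fixation_null",
    "exact_fixation_markov",
    "compare_regime_frequencies",
]


def deterministic_trajectory(p0: float, s: float, t_max: int) -> np.ndarray:
    """Counter-selected clade frequency per generation, 0..t_max.

    Implements the haploid odds recursion ``odds_t = odds_0 *
    (1-s)**t``.  Frequencies 0 and 1 are absorbing and return constant
    trajectories.
    """
    if not (-1.0 < s < 1.0):
        raise ValueError("s must be in (-1, 1)")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must be in [0, 1]")
    t = np.arange(t_max + 1)
    if p0 in (0.0, 1.0):
        return np.full(t_max + 1, p0)
    odds = p0 / (1.0 - p0) * (1.0 - s) ** t
    return odds / (1.0 + odds)


@dataclass
class TrajectoryFit:
    """Selection-coefficient estimate from a clade-count time series."""

    s: float
    ci_low: float
    ci_high: float
    slope: float
    slope_se: float
    chi2: float
    p: float
    sigma_olre: float
    sigma_replicate: float
    n_replicates: int
    transform: str
    loglik: float

    @property
    def w(self) -> float:
        return 1.0 - self.s

    @property
    def w_ci(self) -> tuple[float, float]:
        return (1.0 - self.ci_high, 1.0 - self.ci_low)


def _slope_to_s(slope: float, transform: str) -> float:
    if transform == "slope":
        return -slope
    if transform == "exact":
        return 1.0 - np.exp(slope)
    raise ValueError("transform must be 'slope' or 'exact'")


def fit_selection_glmm(series: pd.DataFrame, transform: str = "slope",
                       generations=None) -> TrajectoryFit:
    """Estimate s from counter-selected clade counts over generations.

    ``series`` needs columns replicate, generation, count, n.  Fully
    fixed samples get the one-individual correction.  The logistic
    mixed model has a generation fixed effect (slope), replicate random
    intercepts and observation-level overdispersion; the generation
    effect is tested by likelihood ratio against the no-slope model and
    its 95% CI is Wald on the slope, transformed.
    """
    df = series.copy()
    for col in ("replicate", "generation", "count", "n"):
        if col not in df.columns:
            raise ValueError(f"series missing column {col!r}")
    if generations is not None:
        df = df[df["generation"].isin(generations)]
    if df["generation"].nunique() < 2:
        raise ValueError("need counts at >= 2 generations")
    if (df["count"] == 0).all():
        raise ValueError("no trajectory: all counts are zero")

    y = fixation_correct_counts(df["count"].to_numpy(float),
                                df["n"].to_numpy(float))
    n = df["n"].to_numpy(float)
    t = df["generation"].to_numpy(float)
    X = np.column_stack([np.ones_like(t), t])

    n_rep = df["replicate"].nunique()
    groups = df["replicate"].to_numpy() if n_rep > 1 else None
    if n_rep == 1:
        warnings.warn("single replicate: using a fixed intercept instead of "
                      "a replicate random intercept")
    full = fit_binomial_mixed(y, n, X, groups=groups,
                              beta_names=["intercept", "generation"])
    null = fit_binomial_mixed(y, n, X[:, :1], groups=groups)
    chi2, p = lr_test(full, null, df=1)

    slope, se = float(full.beta[1]), float(full.beta_se[1])
    if slope > 0:
        warnings.warn(
            "fitted slope is positive: the series should contain counts of "
            "the counter-selected (declining) clade; only that convention "
            "is supported")
    z = stats.norm.ppf(0.975)
    lo_slope, hi_slope = slope - z * se, slope + z * se
    s = _slope_to_s(slope, transform)
    s_lo = _slope_to_s(hi_slope, transform)
    s_hi = _slope_to_s(lo_slope, transform)
    return TrajectoryFit(
        s=float(s), ci_low=float(s_lo), ci_high=float(s_hi),
        slope=slope, slope_se=se, chi2=chi2, p=p,
        sigma_olre=full.sigma_olre, sigma_replicate=full.sigma_group,
        n_replicates=n_rep, transform=transform, loglik=full.loglik)


def relative_fitness(fit: TrajectoryFit) -> tuple[float, tuple[float, float]]:
    """Relative fitness w = 1 - s with 95% CI (endpoints 1 - s CI)."""
    return fit.w, fit.w_ci


def drift_fixation_null(census, p0: float, n_replicates: int = 4,
                        n_sims: int = 10_000, t_max: int = 20,
                        sample_n: int | None = 96,
                        seed: int | None = None):
    """Monte-Carlo probability of parallel fixation under neutrality.

    Simulates binomial (Wright-Fisher) drift of the majority clade at
    the given census size(s) for ``t_max`` generations, observes each
    replicate with an ``sample_n``-individual genotyping sample
    (``None`` to score the latent state), and estimates the probability
    that the majority clade appears fixed in *all* replicates.  Returns
    ``(estimate, mc_se)``.
    """
    census = np.asarray(census)
    if census.ndim == 0:
        census = np.full(t_max, int(census))
    if len(census) < t_max:
        raise ValueError("need a census size for every generation")
    if np.any(census < 1):
        raise ValueError("census must be >= 1")
    rng = np.random.default_rng(seed)
    p_major = max(p0, 1.0 - p0) if p0 not in (0.0, 1.0) else p0
    if p_major == 1.0:
        return 1.0, 0.0
    p = np.full((n_sims, n_replicates), p_major)
    for g in range(t_max):
        N = int(census[g])
        p = rng.binomial(N, p) / N
    if sample_n is None:
        fixed = p >= 1.0
    else:
        fixed = rng.binomial(sample_n, p) == sample_n
    all_fixed = fixed.all(axis=1)
    est = float(all_fixed.mean())
    se = float(np.sqrt(max(est * (1 - est), 1.0 / n_sims) / n_sims))
    return est, se


def exact_fixation_markov(N: int, p0: float, t_max: int) -> float:
    """Exact single-replicate fixation probability of the focal clade by
    generation ``t_max`` under binomial drift at constant size ``N``.

    Builds the (N+1)-state Wright-Fisher transition matrix; serves as
    the small-N oracle for :func:`drift_fixation_null`.
    """
    states = np.arange(N + 1)
    P = np.array([stats.binom.pmf(states, N, i / N) for i in states])
    v = stats.binom.pmf(states, N, p0)  # initial draw at census
    for _ in range(t_max - 1):
        v = v @ P
    return float(v[N])


def compare_regime_frequencies(counts: pd.DataFrame):
    """Regime effect on clade-carrier frequencies across populations.

    ``counts`` needs columns population, regime, count, n (one row per
    population, e.g. 96-fly genotyping samples).  Fits a binomial GLMM
    with regime fixed effects and observation-level overdispersion and
    tests the regime effect by likelihood ratio (df = levels - 1).
    Returns ``(MixedFitResult-like dict, per-level fitted
    frequencies)``; pairwise contrasts live in
    :func:`symsel.assays.pairwise_contrasts`.
    """
    for col in ("population", "regime", "count", "n"):
        if col not in counts.columns:
            raise ValueError(f"counts missing column {col!r}")
    levels = sorted(counts["regime"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 regimes")
    y = fixation_correct_counts(counts["count"].to_numpy(float),
                                counts["n"].to_numpy(float))
    n = counts["n"].to_numpy(float)
    dummies = np.column_stack(
        [np.ones(len(counts))]
        + [(counts["regime"] == lv).to_numpy(float) for lv in levels[1:]])
    names = ["intercept"] + [f"regime[{lv}]" for lv in levels[1:]]
    full = fit_binomial_mixed(y, n, dummies, beta_names=names)
    null = fit_binomial_mixed(y, n, dummies[:, :1])
    chi2, p = lr_test(full, null, df=len(levels) - 1)
    inv = lambda t: 1.0 / (1.0 + np.exp(-t))
    fitted = {levels[0]: inv(full.beta[0])}
    for j, lv in enumerate(levels[1:], start=1):
        fitted[lv] = inv(full.beta[0] + full.beta[j])
    return {"fit": full, "chi2": chi2, "df": len(levels) - 1, "p": p,
            "levels": levels}, fitted
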
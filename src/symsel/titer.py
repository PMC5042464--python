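"""Relative qPCR quantification and clade comparison of titers.

Viral (DCV) and symbiont (*wsp* gene) levels are quantified relative to
a host reference gene (Rpl32) by the efficiency-corrected ratio of
Pfaffl:

    ratio = E_target^(Ct_cal,target - Ct_sample,target)
          / E_ref^(Ct_cal,ref - Ct_sample,ref)

with amplification efficiencies E per primer pair (E = 2 is perfect
doubling, recovering the delta-delta-Ct formula).  Technical replicates
are averaged on the Ct scale.  Levels are compared between clades with
a linear mixed model on the log scale (cross random intercept); the
clade effect back-transforms to a fold difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .results import MixedFitResult

__all__ = ["pfaffl_ratio", "titer_lmm"]


def _mean_ct(records: pd.DataFrame, target: str) -> float:
    cts = records.loc[records["target"] == target, "ct"]
    if not len(cts):
        raise ValueError(f"no Ct values for target {target!r}")
    if (cts <= 0).any():
        raise ValueError("Ct values must be positive")
    return float(cts.mean())


def pfaffl_ratio(sample: pd.DataFrame, calibrator: pd.DataFrame,
                 target: str, reference: str = "Rpl32",
                 efficiencies: dict[str, float] | None = None) -> float:
    """Efficiency-corrected relative level of ``target`` in ``sample``
    vs ``calibrator``.

    Both inputs are record tables with columns ``target`` and ``ct``
    (technical replicates as rows, averaged on the Ct scale).
    Efficiencies default to 2.0 per primer pair and must lie in
    [1, 2.2].
    """
    eff = {target: 2.0, reference: 2.0}
    if efficiencies:
        eff.update(efficiencies)
    for t, e in eff.items():
        if not (1.0 <= e <= 2.2):
            raise ValueError(f"efficiency for {t!r} outside [1, 2.2]")
    d_target = _mean_ct(calibrator, target) - _mean_ct(sample, target)
    d_ref = _mean_ct(calibrator, reference) - _mean_ct(sample, reference)
    return float(eff[target] ** d_target / eff[reference] ** d_ref)


def titer_lmm(levels: pd.DataFrame, group_col: str = "clade",
              reference_level: str = "V") -> MixedFitResult:
    """Log-scale linear mixed model of relative levels between clades.

    ``levels`` needs columns ``level`` (positive relative quantity),
    ``cross`` and the grouping column.  Natural-log levels are modelled
    with a cross random intercept; the group effect is LR-tested and
    back-transformed to a fold difference with 95% CI.  The plain ratio
    of geometric means is reported alongside.  Nonpositive levels are
    rejected row-wise with a message.
    """
    import statsmodels.api as sm

    df = levels.copy()
    bad = df["level"] <= 0
    if bad.any():
        import warnings
        warnings.warn(f"dropping {int(bad.sum())} nonpositive level(s)")
        df = df[~bad]
    if df[group_col].nunique() != 2:
        raise ValueError("titer_lmm compares exactly two groups")
    other = [g for g in df[group_col].unique() if g != reference_level][0]
    y = np.log(df["level"].to_numpy(float))
    x = (df[group_col] == other).to_numpy(float)
    X = np.column_stack([np.ones_like(x), x])
    names = ["intercept", f"{group_col}[{other}]"]
    groups = df["cross"].to_numpy()
    full = sm.MixedLM(y, X, groups=groups).fit(reml=False)
    null = sm.MixedLM(y, X[:, :1], groups=groups).fit(reml=False)
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(chi2, 1))
    beta = np.asarray(full.fe_params)
    cov = np.asarray(full.cov_params())[:2, :2]
    se = np.sqrt(cov[1, 1])
    zq = stats.norm.ppf(0.975)
    fold = float(np.exp(beta[1]))
    fold_ci = (float(np.exp(beta[1] - zq * se)),
               float(np.exp(beta[1] + zq * se)))
    gm = (np.exp(y[x == 1].mean()) / np.exp(y[x == 0].mean()))
    return MixedFitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        ranef_var={"cross": float(np.asarray(full.cov_re)[0, 0]),
                   "residual": float(full.scale)},
        loglik=float(full.llf), chi2=chi2, df=1, p=p,
        converged=bool(full.converged), model="titer_log_lmm",
        extra={"fold": fold, "fold_ci": fold_ci,
               "geometric_mean_ratio": float(gm),
               "comparison": f"{other} vs {reference_level}"})
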
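"""Per-SNP allele-frequency testing and clade inference from pooled data.

Pooled sequencing of replicate populations yields, per polymorphic
position, a major-allele frequency and a weight (read depth, or number
of genotyped individuals for genotyping data).  Frequencies are
compared between selection regimes with a weighted binomial model on
the logit scale that includes an observation-level random effect for
overdispersion; significance is controlled by Benjamini-Hochberg FDR at
a 0.1% threshold.  Clade haplotype frequencies are then estimated from
clade-diagnostic SNPs: positions whose allele is present in all
described variants of one clade and absent from all variants of the
other clades in the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import fit_binomial_mixed, fit_binomial_olre_batch, lr_test

__all__ = [
    "SnpTable",
    "CladePanel",
    "weighted_binomial_test",
    "bh_fdr",
    "holm_adjust",
    "find_diagnostic_snps",
    "estimate_clade_frequencies",
    "classify_outcomes",
    "fixation_correct_counts",
]

_BASES = set("ACGT")


@dataclass
class SnpTable:
    """Wide per-position table of major-allele frequencies and weights.

    ``df`` holds columns POS, REF, ALT, MA_C0, one frequency column per
    population plus a matching ``<pop>_W`` weight column, optional
    ``Clade_<id>`` allele-annotation columns and optional Annotation /
    Codon / Effect columns.  ``populations`` maps population column
    name to its selection-regime label.
    """

    df: pd.DataFrame
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        d = self.df
        for col in ("POS", "REF", "ALT"):
            if col not in d.columns:
                raise ValueError(f"SnpTable missing required column {col!r}")
        if d["POS"].duplicated().any():
            raise ValueError("positions must be unique")
        for pop in self.populations:
            if pop not in d.columns or f"{pop}_W" not in d.columns:
                raise ValueError(f"missing frequency/weight column for {pop}")
            f = d[pop].to_numpy(dtype=float)
            if np.any((f < 0) | (f > 1)):
                raise ValueError(f"frequencies of {pop} outside [0, 1]")

    def pops_of(self, regime: str) -> list[str]:
        return [p for p, r in self.populations.items() if r == regime]

    def regimes(self) -> list[str]:
        return sorted(set(self.populations.values()))

    def clade_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("Clade_")]

    def freqs(self, pops) -> np.ndarray:
        return self.df[list(pops)].to_numpy(dtype=float)

    def weights(self, pops) -> np.ndarray:
        return self.df[[f"{p}_W" for p in pops]].to_numpy(dtype=float)


@dataclass
class CladePanel:
    """Alleles previously described for each wMel clade.

    ``alleles`` maps clade id to a set of ``(position, allele)`` pairs;
    a clade may list several alleles at one position if its described
    variants are polymorphic there (such positions cannot be diagnostic
    for it).
    """

    alleles: dict[str, set[tuple[int, str]]]

    def __post_init__(self):
        for clade, pairs in self.alleles.items():
            for pos, al in pairs:
                if al not in _BASES:
                    raise ValueError(
                        f"invalid allele {al!r} for clade {clade} at {pos}")

    def clades(self) -> list[str]:
        return sorted(self.alleles)

    def alleles_of(self, clade: str) -> set[tuple[int, str]]:
        return self.alleles[clade]

    def alleles_at(self, clade: str, pos: int) -> set[str]:
        return {a for (p, a) in self.alleles[clade] if p == pos}


def fixation_correct_counts(y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Reassign one read/individual to the absent allele in fully fixed
    samples so logit-scale models remain estimable."""
    y = np.asarray(y, dtype=float).copy()
    n = np.asarray(n, dtype=float)
    n_b = np.broadcast_to(n, y.shape)
    y[y <= 0] = 1.0
    hi = y >= n_b
    y[hi] = n_b[hi] - 1.0
    return y


def bh_fdr(pvalues, fdr_threshold: float = 0.001):
    """Benjamini-Hochberg step-up q-values and significance flags.

    Returns ``(qvalues, flags)`` with ``flags = q < fdr_threshold``
    (default 0.1%).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < fdr_threshold


def holm_adjust(pvalues) -> np.ndarray:
    """Sequential-Bonferroni (Holm) adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    _, adj, _, _ = multipletests(p, method="holm")
    return adj


def weighted_binomial_test(table: SnpTable, regime_a: str, regime_b: str,
                           maf_filter: float = 0.02,
                           fdr_threshold: float = 0.001,
                           olre: bool = True) -> pd.DataFrame:
    """Weighted binomial frequency comparison between two regimes.

    Per SNP, major-allele counts (``round(freq * weight)``, with the
    one-read fixation correction) are modelled as binomial with a
    logit-linear regime effect and an observation-level random effect
    for overdispersion; the regime effect is tested by likelihood ratio
    (chi-square, 1 df).  Positions with minor-allele frequency below
    ``maf_filter`` in every population are excluded before testing.
    Returns a DataFrame with position, effect estimate (logit scale),
    fitted per-regime frequencies, overdispersion SD, p, q and flags.
    """
    pops_a, pops_b = table.pops_of(regime_a), table.pops_of(regime_b)
    if not pops_a or not pops_b:
        raise ValueError(
            f"need populations in both regimes ({regime_a!r}, {regime_b!r})")
    pops = pops_a + pops_b
    freqs = table.freqs(pops)
    wts = table.weights(pops)
    if np.any(wts <= 0):
        bad = np.where(wts <= 0)
        warnings.warn(f"excluding {len(set(bad[0]))} rows with zero weight")
        keep_w = ~(wts <= 0).any(axis=1)
    else:
        keep_w = np.ones(len(freqs), dtype=bool)

    all_pops = list(table.populations)
    maf_all = np.minimum(table.freqs(all_pops), 1 - table.freqs(all_pops))
    polymorphic = (maf_all > maf_filter).any(axis=1)
    keep = keep_w & polymorphic

    x_regime = np.array([0.0] * len(pops_a) + [1.0] * len(pops_b))
    X = np.column_stack([np.ones_like(x_regime), x_regime])
    idx = np.where(keep)[0]
    n_mat = wts[idx]
    y_mat = fixation_correct_counts(np.round(freqs[idx] * n_mat), n_mat)
    if len(idx):
        beta_f, logsig, ll_full = fit_binomial_olre_batch(
            y_mat, n_mat, X, k_quad=15 if olre else 1)
        _, _, ll_null = fit_binomial_olre_batch(
            y_mat, n_mat, X[:, :1], k_quad=15 if olre else 1)
        chi2 = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
        pvals = stats.chi2.sf(chi2, 1)
        inv = lambda t: 1.0 / (1.0 + np.exp(-t))
        res = pd.DataFrame({
            "POS": table.df["POS"].to_numpy()[idx].astype(int),
            "beta": beta_f[:, 1],
            "chi2": chi2,
            "p": pvals,
            "freq_a": inv(beta_f[:, 0]),
            "freq_b": inv(beta_f[:, 0] + beta_f[:, 1]),
            "sigma_olre": np.exp(logsig),
        })
    else:
        res = pd.DataFrame(columns=["POS", "beta", "chi2", "p", "freq_a",
                                    "freq_b", "sigma_olre"])
    if len(res):
        res["q"], res["significant"] = bh_fdr(res["p"].to_numpy(),
                                              fdr_threshold)
    else:
        res["q"] = []
        res["significant"] = []
    res.attrs["comparison"] = (regime_a, regime_b)
    return res


def find_diagnostic_snps(table: SnpTable, panel: CladePanel,
                         clade: str) -> list[int]:
    """Positions diagnostic for ``clade``: its described variants all
    carry one allele there and no variant of any other clade in the
    panel carries that allele."""
    clade_cols = table.clade_columns()
    if not clade_cols:
        raise ValueError("table has no per-clade allele annotations")
    others = [c for c in panel.clades() if c != clade]
    out = []
    for pos in table.df["POS"].astype(int):
        own = panel.alleles_at(clade, pos)
        if len(own) != 1:
            continue  # absent or polymorphic within the clade
        allele = next(iter(own))
        other_alleles = [panel.alleles_at(o, pos) for o in others]
        if not any(other_alleles):
            continue  # nothing to distinguish from
        if any(allele in s for s in other_alleles):
            continue  # violates the "only" condition
        out.append(int(pos))
    return out


def estimate_clade_frequencies(table: SnpTable, diagnostics, population: str,
                               clade: str = "V", panel: CladePanel = None,
                               spread_tol: float = 0.15):
    """Clade frequency in one population from diagnostic SNPs.

    The clade frequency is the depth-weighted mean of the
    diagnostic-allele frequencies across diagnostic positions, with a
    binomial (Wilson) CI at the summed depth.  A warning reports the
    per-SNP frequencies when their spread exceeds ``spread_tol``
    (conflicting diagnostics).
    """
    diagnostics = list(diagnostics)
    if not diagnostics:
        raise ValueError("need at least one diagnostic SNP")
    sub = table.df.set_index("POS").loc[diagnostics]
    freqs = sub[population].to_numpy(dtype=float)
    wts = sub[f"{population}_W"].to_numpy(dtype=float)
    # stored frequency refers to the major allele (MA_C0); flip where the
    # clade's diagnostic allele is the other one
    diag_allele = None
    flip = np.zeros(len(sub), dtype=bool)
    col = f"Clade_{clade}"
    if col in sub.columns:
        flip = sub[col].astype(str).to_numpy() != sub["MA_C0"].astype(
            str).to_numpy()
    elif panel is not None:
        for k, pos in enumerate(diagnostics):
            al = panel.alleles_at(clade, pos)
            flip[k] = bool(al) and next(iter(al)) != str(sub["MA_C0"].iloc[k])
    freqs = np.where(flip, 1.0 - freqs, freqs)
    if freqs.max() - freqs.min() > spread_tol:
        report = ", ".join(f"{p}:{f:.3f}" for p, f in zip(diagnostics, freqs))
        warnings.warn(f"diagnostic SNPs disagree beyond {spread_tol} "
                      f"({report})")
    w = wts / wts.sum()
    est = float(np.sum(w * freqs))
    n_eff = float(wts.sum())
    lo, hi = _wilson_ci(est, n_eff)
    return est, (lo, hi)


def _wilson_ci(p: float, n: float, level: float = 0.95):
    z = stats.norm.ppf(0.5 + level / 2)
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return float(centre - half), float(centre + half)


def classify_outcomes(results: dict[str, pd.DataFrame], table: SnpTable,
                      clade: str = "V", fixed_regime: str = "Virus-Selected",
                      fixed_at: float = 0.995) -> dict:
    """Summary counts across the pairwise regime comparisons.

    Returns significant-SNP counts per comparison, their Venn overlap
    sets, the number of SNPs significant in at least one comparison,
    and — among significant SNPs of each comparison — those fixed in
    ``fixed_regime`` (all its populations at raw frequency >=
    ``fixed_at``, i.e. fixed before the one-read correction) with the
    fixed allele matching the clade's described allele.
    """
    sig_sets = {cmp: set(df.loc[df["significant"], "POS"].astype(int))
                for cmp, df in results.items()}
    counts = {cmp: len(s) for cmp, s in sig_sets.items()}
    union = set().union(*sig_sets.values()) if sig_sets else set()

    fixed_pops = table.pops_of(fixed_regime)
    d = table.df.set_index("POS")
    col = f"Clade_{clade}"
    fixed_match = {}
    for cmp, s in sig_sets.items():
        k = 0
        for pos in s:
            row = d.loc[pos]
            fr = np.array([row[p] for p in fixed_pops], dtype=float)
            if not len(fr) or fr.min() < fixed_at:
                continue
            major = str(row["MA_C0"])
            if col in d.columns and str(row[col]) == major:
                k += 1
        fixed_match[cmp] = k

    overlaps = {}
    keys = list(sig_sets)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            overlaps[f"{a} & {b}"] = len(sig_sets[a] & sig_sets[b])
    if len(keys) == 3:
        overlaps[" & ".join(keys)] = len(
            sig_sets[keys[0]] & sig_sets[keys[1]] & sig_sets[keys[2]])
    return {
        "significant": counts,
        "any_comparison": len(union),
        "overlaps": overlaps,
        "fixed_matching_clade": fixed_match,
        "sets": sig_sets,
    }
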
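"""SNP frequency testing, multiple-testing control and clade logic."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symsel.poolseq import (CladePanel, SnpTable, bh_fdr, classify_outcomes,
                            estimate_clade_frequencies, find_diagnostic_snps,
                            fixation_correct_counts, holm_adjust,
                            weighted_binomial_test)
from symsel.simulate import (SimPopulationState, make_clade_panel,
                             simulate_poolseq)


def _table(freqs, weights, regimes, clade_cols=None, ma=None):
    """Small wide SnpTable from per-population frequency arrays."""
    pops = list(regimes)
    n_snps = len(next(iter(freqs.values())))
    df = pd.DataFrame({
        "POS": np.arange(1, n_snps + 1) * 100,
        "REF": ["A"] * n_snps,
        "ALT": ["G"] * n_snps,
        "MA_C0": (ma or ["A"] * n_snps),
    })
    for p in pops:
        df[p] = freqs[p]
        df[f"{p}_W"] = weights[p]
    for col, vals in (clade_cols or {}).items():
        df[col] = vals
    return SnpTable(df, populations=regimes)


# -- multiple testing --------------------------------------------------

def test_bh_stepup_by_hand():
    q, flags = bh_fdr([0.001, 0.02, 0.9], fdr_threshold=0.001)
    assert np.allclose(q, [0.003, 0.03, 0.9])
    assert not flags.any()


def test_bh_all_ones_no_flags_and_empty():
    q, flags = bh_fdr(np.ones(10))
    assert not flags.any()
    q0, f0 = bh_fdr([])
    assert len(q0) == 0 and len(f0) == 0


def test_holm_by_hand():
    assert np.allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
    assert holm_adjust([0.3]) == pytest.approx([0.3])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
def test_qvalues_monotone_and_permutation_invariant(pvals):
    p = np.array(pvals)
    q, flags = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q >= p - 1e-12).all()
    perm = np.random.default_rng(0).permutation(len(p))
    q_perm, flags_perm = bh_fdr(p[perm])
    assert np.allclose(q_perm, q[perm])
    assert (flags_perm == flags[perm]).all()


# -- weighted binomial test --------------------------------------------

REGIMES = {"A1": "Ancestral", "A2": "Ancestral",
           "V1": "Virus-Selected", "V2": "Virus-Selected"}


def test_identical_counts_give_null_result():
    tbl = _table({p: [0.5, 0.3] for p in REGIMES},
                 {p: [100, 100] for p in REGIMES}, REGIMES)
    res = weighted_binomial_test(tbl, "Ancestral", "Virus-Selected")
    assert np.allclose(res["beta"], 0.0, atol=1e-4)
    assert (res["p"] > 0.99).all()


def test_major_allele_relabel_flips_sign_only():
    rng = np.random.default_rng(3)
    f = {p: rng.uniform(0.2, 0.8, 6) for p in REGIMES}
    w = {p: np.full(6, 150.0) for p in REGIMES}
    res = weighted_binomial_test(_table(f, w, REGIMES), "Ancestral",
                                 "Virus-Selected")
    flipped = weighted_binomial_test(
        _table({p: 1 - f[p] for p in REGIMES}, w, REGIMES),
        "Ancestral", "Virus-Selected")
    assert np.allclose(res["beta"].to_numpy(),
                       -flipped["beta"].to_numpy(), atol=5e-3)
    assert np.allclose(res["p"].to_numpy(), flipped["p"].to_numpy(),
                       atol=1e-4)


def test_strong_difference_detected_and_maf_filter_applied():
    f = {"A1": [0.9, 0.995], "A2": [0.88, 0.999],
         "V1": [1.0, 1.0], "V2": [1.0, 0.995]}
    w = {p: [200, 200] for p in REGIMES}
    res = weighted_binomial_test(_table(f, w, REGIMES), "Ancestral",
                                 "Virus-Selected")
    # second SNP is never below 0.98 major frequency -> filtered out
    assert list(res["POS"]) == [100]
    assert res["p"].iloc[0] < 0.01


def test_missing_regime_errors():
    tbl = _table({p: [0.5] for p in REGIMES}, {p: [50] for p in REGIMES},
                 REGIMES)
    with pytest.raises(ValueError):
        weighted_binomial_test(tbl, "Ancestral", "Bacteria-Selected")


def test_fixation_correction_bounds():
    y = fixation_correct_counts(np.array([0.0, 5.0, 96.0]),
                                np.array([96.0, 96.0, 96.0]))
    assert list(y) == [1.0, 5.0, 95.0]


# -- diagnostic SNPs and clade frequencies -----------------------------

def test_find_diagnostic_set_logic():
    """5 constructed diagnostics among 50 positions, one 'only'
    violation and one within-clade polymorphism excluded."""
    n = 50
    positions = (np.arange(n) + 1) * 10
    clade_v = [""] * n
    clade_i = [""] * n
    true_diag = [3, 11, 20, 33, 47]
    for k in true_diag:
        clade_v[k] = "A"
        clade_i[k] = "G"
    clade_v[5] = "C"
    clade_i[5] = "C"          # violates "only": shared allele
    clade_v[7] = "T"          # no other clade annotated: not diagnostic
    panel = CladePanel({
        "V": {(int(positions[k]), clade_v[k]) for k in range(n)
              if clade_v[k]},
        "I": {(int(positions[k]), clade_i[k]) for k in range(n)
              if clade_i[k]},
    })
    # a position polymorphic within clade V cannot be diagnostic
    panel.alleles["V"].add((int(positions[11]), "G"))
    df = pd.DataFrame({"POS": positions, "REF": "A", "ALT": "G",
                       "MA_C0": "A", "Clade_V": clade_v,
                       "Clade_I": clade_i, "P1": 0.5, "P1_W": 100})
    tbl = SnpTable(df, populations={"P1": "Ancestral"})
    got = find_diagnostic_snps(tbl, panel, "V")
    expected = sorted(int(positions[k]) for k in true_diag if k != 11)
    assert sorted(got) == expected


def test_find_diagnostic_requires_annotations():
    tbl = _table({"P1": [0.5]}, {"P1": [50]}, {"P1": "Ancestral"})
    with pytest.raises(ValueError):
        find_diagnostic_snps(tbl, CladePanel({"V": set()}), "V")


def test_clade_frequency_weighted_mean_and_trivial():
    clade_cols = {"Clade_V": ["A", "A"]}
    tbl = _table({"P1": [0.9, 0.86]}, {"P1": [100, 100]},
                 {"P1": "Ancestral"}, clade_cols=clade_cols)
    est, ci = estimate_clade_frequencies(tbl, [100, 200], "P1")
    assert est == pytest.approx(0.88, abs=1e-12)
    assert ci[0] < 0.88 < ci[1]
    tbl1 = _table({"P1": [1.0, 1.0]}, {"P1": [100, 100]},
                  {"P1": "Ancestral"}, clade_cols=clade_cols)
    est1, _ = estimate_clade_frequencies(tbl1, [100, 200], "P1")
    assert est1 == 1.0


def test_clade_frequency_conflict_warns():
    tbl = _table({"P1": [0.95, 0.55]}, {"P1": [100, 100]},
                 {"P1": "Ancestral"}, clade_cols={"Clade_V": ["A", "A"]})
    with pytest.warns(UserWarning, match="disagree"):
        estimate_clade_frequencies(tbl, [100, 200], "P1")


def test_clade_frequency_recovers_generative_truth():
    """Estimated clade frequency on simulated pooled reads is within 3
    binomial SEs of the latent truth."""
    panel = make_clade_panel(5, seed=2)
    truth = 0.88
    st_ = SimPopulationState(0, 0, (1 - truth, truth), 600)
    tbl = simulate_poolseq([st_], panel, depth=200, seed=6)
    diags = find_diagnostic_snps(tbl, panel, "V")
    est, _ = estimate_clade_frequencies(tbl, diags, "P1")
    se = np.sqrt(truth * (1 - truth) / (200 * len(diags)))
    assert abs(est - truth) < 3 * se


# -- outcome classification --------------------------------------------

def test_classify_outcomes_set_oracle():
    pos = np.arange(1, 11) * 100
    sig = {
        "anc_vs_vir": {100, 200, 300, 400},
        "ctl_vs_vir": {200, 300, 500},
        "anc_vs_ctl": {600},
    }
    results = {}
    for cmp, s in sig.items():
        results[cmp] = pd.DataFrame({
            "POS": pos, "p": 0.5, "q": 0.5,
            "significant": [p in s for p in pos]})
    regs = {"V1": "Virus-Selected", "V2": "Virus-Selected"}
    freqs = {"V1": np.where(pos <= 300, 1.0, 0.7),
             "V2": np.where(pos <= 300, 1.0, 0.6)}
    tbl = _table({k: v for k, v in freqs.items()},
                 {k: np.full(10, 100.0) for k in regs}, regs,
                 clade_cols={"Clade_V": ["A"] * 10})
    out = classify_outcomes(results, tbl)
    assert out["significant"] == {k: len(v) for k, v in sig.items()}
    assert out["any_comparison"] == 6
    assert out["overlaps"]["anc_vs_vir & ctl_vs_vir"] == 2
    # fixed (freq 1 in both Virus-Selected pops) and matching clade V
    assert out["fixed_matching_clade"]["anc_vs_vir"] == 3
    assert out["fixed_matching_clade"]["anc_vs_ctl"] == 0


def test_classify_no_significant():
    res = {"a_b": pd.DataFrame({"POS": [100], "significant": [False]})}
    tbl = _table({"V1": [0.5]}, {"V1": [50]}, {"V1": "Virus-Selected"})
    out = classify_outcomes(res, tbl)
    assert out["significant"] == {"a_b": 0}
    assert out["any_comparison"] == 0


# -- end-to-end on the simulated study ---------------------------------

def test_study_diagnostics_significant_and_ancestral_freq(study):
    snp, panel = study["snp"], study["panel"]
    res = weighted_binomial_test(snp, "Ancestral", "Virus-Selected")
    diags = find_diagnostic_snps(snp, panel, "V")
    sig_pos = set(res.loc[res["significant"], "POS"])
    assert set(diags) <= sig_pos
    anc = [estimate_clade_frequencies(snp, diags, p)[0]
           for p in snp.pops_of("Ancestral")]
    assert np.mean(anc) == pytest.approx(0.88, abs=0.05)
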
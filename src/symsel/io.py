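"""Readers/writers for the study's tabular formats and the pipeline
driver.

All tables are plain text (tab- or comma-separated, auto-detected) with
named headers.  The SNP table follows the supplementary-style wide
schema (POS/REF/ALT/MA_C0, one frequency column per population with a
matching ``<pop>_W`` weight column, optional ``Clade_<id>`` columns);
clade-count, survival, fecundity and titer tables are long format, one
row per population x generation, fly, female or qPCR sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .poolseq import SnpTable

__all__ = ["read_supplementary_table", "write_snp_table", "RunConfig",
           "run_pipeline", "load_run_config"]

_SCHEMAS = {
    "clade_counts": {"replicate", "generation", "count", "n"},
    "survival": {"vial", "cross", "clade", "day", "event"},
    "fecundity": {"cross", "clade", "pupae"},
    "titer": {"cross", "clade", "level"},
    "qpcr": {"sample", "target", "ct"},
}


def _read_any(path) -> pd.DataFrame:
    """Header-named read with tab/comma auto-detection."""
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_supplementary_table(path, kind: str, default_weight: float = 96.0):
    """Read and validate a typed table.

    ``kind`` is one of ``snp``, ``clade_counts``, ``survival``,
    ``fecundity``, ``titer``, ``qpcr``.  Schema mismatches raise with
    the missing column names; malformed numeric rows are reported with
    their line numbers.  For ``snp`` tables without ``<pop>_W`` weight
    columns, ``default_weight`` is filled in (e.g. individuals
    genotyped).
    """
    path = Path(path)
    df = _read_any(path)
    if kind == "snp":
        missing = {"POS", "REF", "ALT"} - set(df.columns)
        if missing:
            raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
        if "MA_C0" not in df.columns:
            df["MA_C0"] = df["REF"]
        for c in df.columns:
            if c.startswith("Clade_"):
                df[c] = df[c].fillna("").astype(str)
        reserved = {"POS", "REF", "ALT", "MA_C0", "Annotation", "Codon",
                    "Effect"}
        pops = [c for c in df.columns
                if c not in reserved and not c.startswith("Clade_")
                and not c.endswith(("_W", "_CI"))
                and pd.api.types.is_numeric_dtype(df[c])]
        for p in pops:
            if f"{p}_W" not in df.columns:
                df[f"{p}_W"] = default_weight
        regimes = {}
        for p in pops:
            base = p.split("_")[0]
            regimes[p] = {"C0": "Ancestral", "C20": "Control",
                          "V20": "Virus-Selected",
                          "B20": "Bacteria-Selected"}.get(base, base)
        return SnpTable(df, populations=regimes)
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    missing = _SCHEMAS[kind] - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)} "
                         f"for kind {kind!r}")
    bad_lines = []
    for col in _SCHEMAS[kind]:
        if col in ("vial", "cross", "clade", "sample", "target"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((np.where(coerced.isna() & df[col].notna())[0]
                          + 2).tolist())
        df[col] = coerced
    if bad_lines:
        raise ValueError(f"{path.name}: malformed numeric values on lines "
                         f"{sorted(set(bad_lines))}")
    return df


def write_snp_table(table: SnpTable, path, sep: str = "\t") -> None:
    table.df.to_csv(path, sep=sep, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    With no input paths the pipeline simulates the full study at the
    design defaults and analyses its own output; any subset of tables
    can instead be supplied from files.
    """

    snp_table: str | None = None
    clade_counts: str | None = None
    survival: str | None = None
    fecundity: str | None = None
    titer: str | None = None
    fdr_threshold: float = 0.001
    adjustment: str = "mvn"
    seed: int = 0
    out_dir: str | None = None
    sim: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must be in (0, 1)")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Run pooled-SNP testing, clade inference and selection estimation
    (plus fitness models when data are available) and return a report.

    Every stage that fails is recorded in the report under ``errors``
    with its context; completed stages are unaffected.
    """
    from . import assays, poolseq, titer as titer_mod, trajectory
    from .simulate import SimConfig, simulate_fitness_assays, simulate_study

    report: dict = {"seed": config.seed, "errors": {}}
    panel = None
    if config.snp_table:
        snp = read_supplementary_table(config.snp_table, "snp")
        counts = (read_supplementary_table(config.clade_counts,
                                           "clade_counts")
                  if config.clade_counts else None)
    else:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        snp, counts, panel, _ = simulate_study(sim_cfg)
        report["simulated"] = True
        report["generative_s"] = sim_cfg.s

    regimes = snp.regimes()
    results = {}
    for a, b in [(x, y) for i, x in enumerate(regimes)
                 for y in regimes[i + 1:]]:
        key = f"{a}_vs_{b}"
        try:
            results[key] = poolseq.weighted_binomial_test(
                snp, a, b, fdr_threshold=config.fdr_threshold)
        except Exception as exc:   # recorded, not raised
            report["errors"][key] = str(exc)
    if results:
        summary = poolseq.classify_outcomes(results, snp)
        report["snp_tests"] = {
            "significant": summary["significant"],
            "any_comparison": summary["any_comparison"],
            "overlaps": summary["overlaps"],
            "fixed_matching_clade": summary["fixed_matching_clade"],
        }

    try:
        if panel is not None:
            diags = poolseq.find_diagnostic_snps(snp, panel, "V")
        else:
            diags = [int(p) for p in snp.df.loc[
                snp.df.get("Clade_V", pd.Series(dtype=str)).astype(bool),
                "POS"]] if "Clade_V" in snp.df.columns else []
        if diags:
            anc = snp.pops_of("Ancestral")
            ests = [poolseq.estimate_clade_frequencies(snp, diags, p)[0]
                    for p in anc]
            report["ancestral_clade_v_freq"] = float(np.mean(ests))
    except Exception as exc:
        report["errors"]["clade_frequencies"] = str(exc)

    if counts is not None:
        try:
            if "regime" in counts.columns:
                virus = counts[counts["regime"] == "Virus-Selected"]
                # counter-selected clade carriers out of n
                series = virus.assign(count=virus["n"] - virus["count"])
                # ancestral samples provide generation 0 per replicate
                anc = counts[counts["regime"] == "Ancestral"].assign(
                    generation=0)
                anc = anc.assign(count=anc["n"] - anc["count"])
                series = pd.concat([anc, series], ignore_index=True)
            else:
                series = counts
            fit = trajectory.fit_selection_glmm(series)
            report["selection"] = {
                "s": fit.s, "ci": [fit.ci_low, fit.ci_high],
                "w": fit.w, "w_ci": list(fit.w_ci),
                "chi2": fit.chi2, "p": fit.p,
                "significant": bool(fit.p < 0.05),
            }
            if "regime" in counts.columns:
                reg, fitted = trajectory.compare_regime_frequencies(counts)
                report["regime_effect"] = {
                    "chi2": reg["chi2"], "df": reg["df"], "p": reg["p"],
                    "fitted": {k: float(v) for k, v in fitted.items()}}
        except Exception as exc:
            report["errors"]["selection"] = str(exc)

    surv = fec = tit = None
    if config.survival:
        surv = read_supplementary_table(config.survival, "survival")
    if config.fecundity:
        fec = read_supplementary_table(config.fecundity, "fecundity")
    if config.titer:
        tit = read_supplementary_table(config.titer, "titer")
    if surv is None and fec is None and tit is None and config.snp_table \
            is None:
        surv, fec, tit = simulate_fitness_assays(seed=config.seed + 17)
    for name, fn, data in (
            ("survival_day7", lambda d: assays.fit_daily_survival_glmm(d, 7),
             surv),
            ("cox", assays.fit_cox_frailty, surv),
            ("fecundity", assays.fit_fecundity_lmm, fec)):
        if data is None:
            continue
        try:
            fit = fn(data)
            report[name] = {"chi2": fit.chi2, "df": fit.df, "p": fit.p,
                            "params": fit.params.to_dict()}
        except Exception as exc:
            report["errors"][name] = str(exc)
    if tit is not None:
        try:
            for target in (tit["target"].unique()
                           if "target" in tit.columns else ["level"]):
                sub = tit[tit["target"] == target] if "target" in tit.columns \
                    else tit
                fit = titer_mod.titer_lmm(sub)
                report[f"titer_{target}"] = {
                    "fold": fit.extra["fold"],
                    "fold_ci": list(fit.extra["fold_ci"]),
                    "chi2": fit.chi2, "p": fit.p}
        except Exception as exc:
            report["errors"]["titer"] = str(exc)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        with open(out / "report.txt", "w") as fh:
            fh.write(summarize_report(report))
    return report


def summarize_report(report: dict) -> str:
    lines = ["symsel pipeline report", "======================"]
    if report.get("simulated"):
        lines.append(f"(simulated study, generative s = "
                     f"{report['generative_s']})")
    if "snp_tests" in report:
        for cmp, n in report["snp_tests"]["significant"].items():
            lines.append(f"significant SNPs {cmp}: {n}")
    if "ancestral_clade_v_freq" in report:
        lines.append(f"ancestral clade V frequency: "
                     f"{report['ancestral_clade_v_freq']:.3f}")
    if "selection" in report:
        s = report["selection"]
        lines.append(f"selection coefficient s = {s['s']:.3f} "
                     f"({s['ci'][0]:.3f}-{s['ci'][1]:.3f}), "
                     f"chi2 = {s['chi2']:.2f}, p = {s['p']:.3g}")
        lines.append(f"relative fitness w = {s['w']:.3f} "
                     f"({s['w_ci'][0]:.3f}-{s['w_ci'][1]:.3f})")
    if "regime_effect" in report:
        r = report["regime_effect"]
        lines.append(f"regime effect chi2_{r['df']} = {r['chi2']:.2f}, "
                     f"p = {r['p']:.3g}")
    for key in ("survival_day7", "cox", "fecundity"):
        if key in report:
            r = report[key]
            lines.append(f"{key}: chi2_{r['df']} = {r['chi2']:.2f}, "
                         f"p = {r['p']:.3g}")
    for key, r in report.items():
        if key.startswith("titer_"):
            lines.append(f"{key}: fold = {r['fold']:.2f} "
                         f"({r['fold_ci'][0]:.2f}-{r['fold_ci'][1]:.2f}), "
                         f"p = {r['p']:.3g}")
    for stage, err in report.get("errors", {}).items():
        lines.append(f"FAILED {stage}: {err}")
    return "\n".join(lines) + "\n"
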
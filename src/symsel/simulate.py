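"""Forward simulation of endosymbiont selection during host experimental
evolution.

The generative model mirrors a virus-selection experiment on *Drosophila*
populations fixed for a maternally transmitted *Wolbachia* (wMel)
infection that segregates for two competing clades of variants: a
counter-selected clade (I/III-like) and a favoured clade (V-like).
Each generation,

1. a fixed census of flies is challenged (pricked) with virus,
2. each fly survives with a clade-specific probability,
3. survivors reproduce with clade-specific mean fecundity, and
4. the next generation is a multinomial draw from the offspring pool at
   the census size.

Transmission is strictly maternal and perfect, so symbiont prevalence
stays at 1 and selection acts as in a haploid: with total fitness ratio
``w = 1 - s`` per generation the expected odds of the counter-selected
clade follow ``odds_t = odds_0 * (1 - s)**t``.

Observation layers — individual genotyping samples, pooled sequencing of
clade-diagnostic SNPs, and survival / fecundity / titer assays — are
generated on top of the latent trajectories and stamped with the
generative truth so that every downstream estimator can be tested for
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "AssayEffects",
    "SimPopulationState",
    "SimExperiment",
    "simulate_experiment",
    "simulate_study",
    "sample_genotyped_individuals",
    "simulate_poolseq",
    "simulate_null_snp_table",
    "simulate_fitness_assays",
    "make_clade_panel",
]

#: wMel reference position whose restriction polymorphism separates
#: clades I-IV from clades V/VI; anchors the default diagnostic panel.
DIAGNOSTIC_ANCHOR_POS = 805_011


@dataclass(frozen=True)
class SimConfig:
    """Design constants of the selection experiment.

    Defaults are the study conditions: 4 replicate populations, 620
    flies (310 males + 310 females) challenged per generation, 66%
    average infection mortality, 12% initial frequency of the
    counter-selected clade, selection coefficient s against it, and
    96-fly genotyping samples.
    """

    n_replicates: int = 4
    n_generations: int = 20
    census_infected: int = 620
    p0_counter: float = 0.12
    s: float = 0.263
    mortality_overall: float = 0.66
    fecundity_ratio: float = 1.0
    genotype_sample_n: int = 96
    poolseq_depth: float = 200.0
    n_diagnostic_snps: int = 5
    genotype_generations: tuple[int, ...] = (0, 5, 10, 20)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p0_counter <= 1.0):
            raise ValueError("p0_counter must be in [0, 1]")
        if not (-1.0 < self.s < 1.0):
            raise ValueError("s must be in (-1, 1)")
        if not (0.0 <= self.mortality_overall < 1.0):
            raise ValueError("mortality_overall must be in [0, 1)")
        if self.fecundity_ratio <= 0:
            raise ValueError("fecundity_ratio must be positive")
        for name in ("n_replicates", "n_generations", "census_infected",
                     "genotype_sample_n", "n_diagnostic_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.poolseq_depth < 1:
            raise ValueError("poolseq_depth must be >= 1")
        self.clade_survival()  # validates the decomposition

    def clade_survival(self) -> tuple[float, float]:
        """Per-clade survival probabilities (counter-selected, favoured).

        Chosen so that (a) the initial-frequency mixture survival equals
        ``1 - mortality_overall`` and (b) combined with the fecundity
        ratio the per-generation fitness ratio is exactly ``1 - s``:
        ``(S_c F_c) / (S_f F_f) = 1 - s``.  By default all of the
        fitness differential is carried by survival.
        """
        r = (1.0 - self.s) / self.fecundity_ratio
        surv_mix = 1.0 - self.mortality_overall
        s_fav = surv_mix / (1.0 - self.p0_counter * (1.0 - r))
        s_cnt = r * s_fav
        if not (0.0 < s_fav <= 1.0 and 0.0 <= s_cnt <= 1.0):
            raise ValueError(
                "selection/mortality/fecundity decomposition implies a "
                f"survival probability outside [0, 1]: ({s_cnt:.3f}, "
                f"{s_fav:.3f})")
        return s_cnt, s_fav


@dataclass(frozen=True)
class SimPopulationState:
    """Latent state of one replicate at one generation."""

    replicate_id: int
    generation: int
    clade_freqs: tuple[float, ...]  # (counter-selected, favoured)
    census: int
    extinct: bool = False

    def __post_init__(self):
        f = np.asarray(self.clade_freqs)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("clade_freqs must be nonnegative and sum to 1")

    @property
    def freq_counter(self) -> float:
        return self.clade_freqs[0]

    @property
    def prevalence(self) -> float:
        """Symbiont prevalence; always 1 under perfect maternal
        transmission."""
        return 1.0


@dataclass
class SimExperiment:
    """Simulated experiment: latent states plus observation tables."""

    config: SimConfig
    states: list[SimPopulationState]
    clade_counts: pd.DataFrame        # replicate, generation, count, n
    extinct_replicates: list[int]
    true_freqs: pd.DataFrame          # replicate, generation, freq_counter

    def state(self, replicate: int, generation: int) -> SimPopulationState:
        for st in self.states:
            if st.replicate_id == replicate and st.generation == generation:
                return st
        raise KeyError((replicate, generation))


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _step(p: float, cfg: SimConfig, rng: np.random.Generator | None):
    """One generation: challenge, clade-specific survival, reproduction,
    census multinomial.  ``rng is None`` gives the deterministic
    (infinite-population) expectation."""
    s_cnt, s_fav = cfg.clade_survival()
    if rng is None:
        surv_c = p * s_cnt
        surv_f = (1.0 - p) * s_fav
    else:
        n_c = rng.binomial(cfg.census_infected, p)
        n_f = cfg.census_infected - n_c
        surv_c = rng.binomial(n_c, s_cnt)
        surv_f = rng.binomial(n_f, s_fav)
        if surv_c + surv_f == 0:
            return p, True
    off_c = surv_c * cfg.fecundity_ratio
    off_f = surv_f * 1.0
    total = off_c + off_f
    if total == 0:
        return p, True
    p_next = off_c / total
    if rng is not None and 0.0 < p_next < 1.0:
        p_next = rng.binomial(cfg.census_infected, p_next) / cfg.census_infected
    return float(p_next), False


def simulate_experiment(config: SimConfig,
                        deterministic: bool = False) -> SimExperiment:
    """Run the full selection experiment for all replicates.

    With ``deterministic=True`` drift and all sampling are disabled and
    the trajectory equals the closed-form odds recursion exactly.
    """
    rngs = _spawn(config.seed, config.n_replicates + 1)
    geno_rng = rngs[-1]
    states: list[SimPopulationState] = []
    rows = []
    count_rows = []
    extinct_reps: list[int] = []
    geno_gens = sorted(g for g in set(config.genotype_generations)
                       if g <= config.n_generations)
    for rep in range(config.n_replicates):
        rng = None if deterministic else rngs[rep]
        p = config.p0_counter
        extinct = False
        for gen in range(config.n_generations + 1):
            st = SimPopulationState(rep, gen, (p, 1.0 - p),
                                    config.census_infected, extinct)
            states.append(st)
            rows.append((rep, gen, p, extinct))
            if gen in geno_gens:
                if deterministic:
                    cnt = p * config.genotype_sample_n
                else:
                    cnt = sample_genotyped_individuals(
                        st, config.genotype_sample_n, rng=geno_rng)
                count_rows.append((rep, gen, cnt, config.genotype_sample_n))
            if gen < config.n_generations and not extinct:
                p, died = _step(p, config, rng)
                if died:
                    extinct = True
                    extinct_reps.append(rep)
    true_freqs = pd.DataFrame(
        rows, columns=["replicate", "generation", "freq_counter", "extinct"])
    clade_counts = pd.DataFrame(
        count_rows, columns=["replicate", "generation", "count", "n"])
    return SimExperiment(config, states, clade_counts, extinct_reps,
                         true_freqs)


def sample_genotyped_individuals(state, n: int,
                                 seed: int | None = None,
                                 rng: np.random.Generator | None = None):
    """Binomial genotyping sample: carriers of the counter-selected
    clade out of ``n`` flies at the state's true frequency."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = state.freq_counter if hasattr(state, "freq_counter") else float(state)
    return int(rng.binomial(n, p))


def make_clade_panel(n_per_clade: int = 5, seed: int = 0):
    """Synthetic clade allele panel for clades I, III and V.

    Each position carries one allele shared by the counter-selected
    clades (I and III) and a different allele fixed in clade V, so every
    position is diagnostic for clade V against I/III.  The restriction
    anchor position is always included.  Returns a
    :class:`symsel.poolseq.CladePanel`.
    """
    from .poolseq import CladePanel

    rng = np.random.default_rng(seed)
    positions = {DIAGNOSTIC_ANCHOR_POS}
    while len(positions) < n_per_clade:
        positions.add(int(rng.integers(10_000, 1_200_000)))
    positions = sorted(positions)
    alleles = {}
    bases = np.array(list("ACGT"))
    for pos in positions:
        a, b = rng.choice(4, size=2, replace=False)
        alleles[pos] = (bases[a], bases[b])  # (clade V, clades I/III)
    panel = {
        "V": {(pos, alleles[pos][0]) for pos in positions},
        "I": {(pos, alleles[pos][1]) for pos in positions},
        "III": {(pos, alleles[pos][1]) for pos in positions},
    }
    return CladePanel(panel)


def simulate_poolseq(states, panel, depth: float,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     pop_names: list[str] | None = None,
                     regimes: dict[str, str] | None = None,
                     n_noise_snps: int = 0):
    """Pooled-sequencing observation of clade-diagnostic SNPs.

    Per SNP and population the read depth is Poisson around ``depth``
    (min 1) and the major-allele read count is binomial at the
    clade-implied allele frequency.  Optional non-diagnostic noise SNPs
    at stationary frequencies support false-discovery testing.  Returns
    a :class:`symsel.poolseq.SnpTable`.
    """
    from .poolseq import SnpTable

    if depth < 1:
        raise ValueError("depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    states = list(states)
    if pop_names is None:
        pop_names = [f"P{i+1}" for i in range(len(states))]
    if regimes is None:
        regimes = {name: "Unknown" for name in pop_names}

    clades = panel.clades()
    v_alleles = {pos: a for (pos, a) in panel.alleles_of("V")}
    other_alleles = {pos: a for cl in clades if cl != "V"
                     for (pos, a) in panel.alleles_of(cl)}
    positions = sorted(v_alleles)
    rows = []
    for pos in positions:
        row = {"POS": pos, "REF": v_alleles[pos],
               "ALT": other_alleles[pos], "MA_C0": v_alleles[pos]}
        for cl in clades:
            al = {p: a for (p, a) in panel.alleles_of(cl)}.get(pos)
            row[f"Clade_{cl}"] = al if al is not None else ""
        for st, name in zip(states, pop_names):
            # major allele (clade V) frequency = 1 - counter frequency
            f_true = 1.0 - st.freq_counter
            d = max(1, int(rng.poisson(depth)))
            k = rng.binomial(d, f_true)
            row[name] = k / d
            row[f"{name}_W"] = d
        rows.append(row)
    noise_positions = []
    if n_noise_snps:
        lo, hi = 1, 1_267_782
        taken = set(positions)
        while len(noise_positions) < n_noise_snps:
            cand = int(rng.integers(lo, hi))
            if cand not in taken:
                taken.add(cand)
                noise_positions.append(cand)
        bases = np.array(list("ACGT"))
        for pos in noise_positions:
            a, b = rng.choice(4, size=2, replace=False)
            f0 = rng.uniform(0.1, 0.9)
            row = {"POS": pos, "REF": bases[a], "ALT": bases[b],
                   "MA_C0": bases[a]}
            for cl in clades:
                row[f"Clade_{cl}"] = ""
            for name in pop_names:
                d = max(1, int(rng.poisson(depth)))
                row[name] = rng.binomial(d, f0) / d
                row[f"{name}_W"] = d
            rows.append(row)
    df = pd.DataFrame(rows).sort_values("POS").reset_index(drop=True)
    return SnpTable(df, populations=dict(zip(pop_names,
                                             [regimes[n] for n in pop_names])))


def simulate_null_snp_table(n_snps: int, pops: dict[str, str],
                            depth: float = 200.0, n_pool: int = 200,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None):
    """SNP table under the global null: every population's allele
    frequency is binomially sampled (pool of ``n_pool`` individuals,
    then reads) around one shared stationary frequency per SNP."""
    from .poolseq import SnpTable

    if rng is None:
        rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    rows = []
    for i in range(n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        f0 = rng.uniform(0.1, 0.9)
        row = {"POS": 1000 + i, "REF": bases[a], "ALT": bases[b],
               "MA_C0": bases[a]}
        for name in pops:
            f_pool = rng.binomial(n_pool, f0) / n_pool
            d = max(1, int(rng.poisson(depth)))
            row[name] = rng.binomial(d, f_pool) / d
            row[f"{name}_W"] = d
        rows.append(row)
    return SnpTable(pd.DataFrame(rows), populations=dict(pops))


def simulate_study(config: SimConfig, n_noise_snps: int = 50):
    """Simulate the three sequenced regimes of the study design.

    Ancestral populations are generation-0 snapshots; Control
    populations evolve 20 generations with s = 0 (drift only);
    Virus-Selected populations evolve under the configured s.  Returns
    ``(snp_table, clade_counts, panel, experiments)`` where
    ``clade_counts`` holds 96-fly genotyping samples of every
    population with ``count`` = clade V (favoured) carriers, and
    ``snp_table`` spans all 12 populations.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    virus = simulate_experiment(replace(config, seed=config.seed + 1))
    control = simulate_experiment(replace(config, s=0.0, seed=config.seed + 2))
    panel = make_clade_panel(config.n_diagnostic_snps, seed=config.seed)
    rng = np.random.default_rng(seeds[3])

    states, names, regimes = [], [], {}
    for rep in range(config.n_replicates):
        st = virus.state(rep, 0)
        names.append(f"C0_{rep+1}")
        regimes[names[-1]] = "Ancestral"
        states.append(st)
    for rep in range(config.n_replicates):
        states.append(control.state(rep, config.n_generations))
        names.append(f"C20_{rep+1}")
        regimes[names[-1]] = "Control"
    for rep in range(config.n_replicates):
        states.append(virus.state(rep, config.n_generations))
        names.append(f"V20_{rep+1}")
        regimes[names[-1]] = "Virus-Selected"
    snp = simulate_poolseq(states, panel, config.poolseq_depth, rng=rng,
                           pop_names=names, regimes=regimes,
                           n_noise_snps=n_noise_snps)

    crows = []
    for st, name in zip(states, names):
        cnt_counter = sample_genotyped_individuals(
            st, config.genotype_sample_n, rng=rng)
        # recorded as clade V carriers, the convention of the
        # individual-genotyping datasets and trajectory figures
        crows.append((name, regimes[name], st.replicate_id, st.generation,
                      config.genotype_sample_n - cnt_counter,
                      config.genotype_sample_n))
    clade_counts = pd.DataFrame(
        crows, columns=["population", "regime", "replicate", "generation",
                        "count", "n"])
    return snp, clade_counts, panel, {"virus": virus, "control": control}


@dataclass(frozen=True)
class AssayEffects:
    """Generative parameters of the fitness assays.

    Survival: exponential baseline hazard with log-normal cross and vial
    frailties and a clade log-hazard difference, administratively
    censored at the assay horizon.  Fecundity: hurdle — Bernoulli
    non-reproduction, zero-truncated negative-binomial pupae counts.
    Titers: log-normal with a clade fold-change.  Defaults emulate the
    study design (11 reciprocal cross pairs, 10 vials x 10 flies, 20
    females per cross, 20-day horizon, 66%-scale mortality) with effect
    sizes a protective symbiont difference of the reported kind implies
    (hazard ratio ~2, fecundity ratio ~0.6, 5.4-fold viral load).
    """

    log_hazard_clade: float = 0.7
    baseline_hazard: float = 0.065
    cross_sd: float = 0.3
    vial_sd: float = 0.3
    horizon: int = 20
    n_crosses: int = 11
    vials_per_group: int = 10
    flies_per_vial: int = 10
    fecundity_mean: float = 45.0
    fecundity_ratio: float = 0.6
    zero_inflation: float = 0.15
    nb_dispersion: float = 0.3
    females_per_group: int = 20
    fecundity_cross_sd: float = 4.0
    dcv_fold: float = 5.4
    wsp_fold: float = 0.5
    titer_sd: float = 0.8
    titer_cross_sd: float = 0.3
    titer_flies: int = 3
    factorial: bool = False   # cytotype x Wolbachia-presence design

    def __post_init__(self):
        for name in ("cross_sd", "vial_sd", "fecundity_cross_sd",
                     "titer_sd", "titer_cross_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ValueError("zero_inflation must be in [0, 1)")


def simulate_fitness_assays(effects: AssayEffects = AssayEffects(),
                            seed: int = 0):
    """Simulate survival, fecundity and titer assays on reciprocal-cross
    progeny.

    Returns ``(survival, fecundity, titers)`` DataFrames.  In the
    factorial design the clade effect applies only in the presence of
    the symbiont (its protection, not the co-inherited mitochondria,
    drives the difference).
    """
    rng = np.random.default_rng(seed)
    e = effects
    presences = [True, False] if e.factorial else [True]
    surv_rows, fec_rows, titer_rows = [], [], []
    ind = 0
    for j in range(e.n_crosses):
        c_j = rng.normal(0.0, e.cross_sd)
        c_fec = rng.normal(0.0, e.fecundity_cross_sd)
        c_tit = rng.normal(0.0, e.titer_cross_sd)
        for presence in presences:
            for clade in ("V", "III"):
                lp_clade = e.log_hazard_clade if (clade == "III" and presence) \
                    else 0.0
                for v in range(e.vials_per_group):
                    vial = f"c{j}_{clade}_{'w' if presence else 'nw'}_v{v}"
                    b_v = rng.normal(0.0, e.vial_sd)
                    rate = e.baseline_hazard * np.exp(lp_clade + c_j + b_v)
                    t = rng.exponential(1.0 / rate, size=e.flies_per_vial)
                    day = np.ceil(t).astype(int)
                    event = day <= e.horizon
                    day = np.minimum(day, e.horizon)
                    for d, ev in zip(day, event):
                        surv_rows.append((f"fly{ind}", vial, f"cross{j}",
                                          clade, presence, int(d), int(ev)))
                        ind += 1
                mu = e.fecundity_mean * (
                    e.fecundity_ratio if (clade == "III" and presence) else 1.0)
                mu = max(mu + c_fec, 1.0)
                nb_n = 1.0 / e.nb_dispersion
                nb_p = nb_n / (nb_n + mu)
                for f in range(e.females_per_group):
                    if rng.uniform() < e.zero_inflation:
                        pupae = 0
                    else:
                        pupae = 0
                        while pupae == 0:   # zero-truncated draw
                            pupae = rng.negative_binomial(nb_n, nb_p)
                    fec_rows.append((f"f{j}_{clade}_{presence}_{f}",
                                     f"cross{j}", clade, presence, True,
                                     int(pupae)))
                if presence:
                    for f in range(e.titer_flies):
                        for target, fold in (("DCV", e.dcv_fold),
                                             ("wsp", e.wsp_fold)):
                            lvl = np.exp(
                                (np.log(fold) if clade == "III" else 0.0)
                                + c_tit + rng.normal(0.0, e.titer_sd))
                            titer_rows.append(
                                (f"s{j}_{clade}_{f}", f"cross{j}", clade,
                                 target, lvl))
    survival = pd.DataFrame(
        surv_rows, columns=["individual", "vial", "cross", "clade",
                            "wolbachia", "day", "event"])
    fecundity = pd.DataFrame(
        fec_rows, columns=["female", "cross", "clade", "wolbachia",
                           "infected", "pupae"])
    titers = pd.DataFrame(
        titer_rows, columns=["sample", "cross", "clade", "target", "level"])
    return survival, fecundity, titers
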
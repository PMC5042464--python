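# Methods

## The generative model

`symsel.simulate` is a forward model of experimental evolution of a
*Drosophila* population whose *Wolbachia* (wMel) infection segregates
for two clades of variants: a counter-selected clade (I/III-like) at
initial frequency `p0_counter` (default 0.12) and a favoured clade
(V-like).  Each generation

1. `census_infected` flies (default 620, i.e. 310 males + 310 females)
   are challenged with virus;
2. each fly survives with a clade-specific probability;
3. survivors reproduce with clade-specific mean fecundity;
4. the next generation is drawn multinomially from the offspring pool
   at the census size.

Transmission is strictly maternal and perfect, so symbiont prevalence
is identically 1 and the sex structure collapses to the female line;
males carry but do not transmit.  With fitness ratio w = 1 − s per
generation the expected dynamics are the haploid selection recursion

    odds_t = odds_0 · (1 − s)^t ,   odds = p/(1 − p),

which the simulator reproduces exactly in deterministic mode (drift and
sampling disabled); this identity is tested to 1e-12.

**Fitness decomposition.**  The experiment measures survival and
fecundity separately but the trajectory identifies only their compound
s.  The simulator therefore takes total s plus a `fecundity_ratio`
splitting it into components, with all of the differential in survival
by default.  Clade-specific survival probabilities are solved from two
constraints: the initial-frequency mixture survival equals
1 − `mortality_overall` (default 0.66), and
(S_counter·F_counter)/(S_fav·F_fav) = 1 − s.  The decomposition is a
configuration choice, not an inference.

**Drift.**  No effective population size is imposed; variance enters
through the binomial challenge composition, binomial survival and the
multinomial census draw, matching the protocol in which survivors mate
randomly and the census is restored each generation.  A replicate with
zero survivors is flagged extinct, not raised.

**Observation layers.**  Genotyping samples are binomial draws of
`genotype_sample_n` flies (default 96) at the latent carrier frequency.
Pooled sequencing draws a Poisson read depth per SNP per population
(mean `poolseq_depth`, default 200) and a binomial major-allele count
at the clade-implied frequency; the noise model is pure binomial read
sampling with no sequencing-error term (none is identified by the
data), plus optional non-diagnostic SNPs at stationary frequencies for
false-discovery testing.  Fitness assays mirror the reciprocal-cross
design: 11 cross pairs, 10 vials × 10 flies per clade for survival
(exponential baseline hazard, log-normal cross and vial frailties,
administrative censoring at day 20), 20 females per cross for
fecundity (Bernoulli non-reproduction + zero-truncated negative
binomial counts), and three qPCR'd females per cross per clade for
titers (log-normal, 5.4-fold DCV and 0.5-fold symbiont defaults, the
effect sizes the phenotyped clade difference implies).

**Randomness.**  One master seed; all streams are spawned
deterministically from it (`numpy` `SeedSequence`), so identical seeds
give bit-identical outputs.

## Pooled SNP frequency tests

Per position, major-allele counts are reconstructed as
round(frequency × weight) — the input tables store frequencies, not
counts — and modelled as binomial with a logit-linear selection-regime
effect and an observation-level normal random effect ε_i capturing
overdispersion between replicate populations.  The marginal likelihood
integrates ε_i by Gauss–Hermite quadrature (the integral factorises
over observations); the regime effect is tested by likelihood ratio
against the intercept-only model on a χ² with 1 df.  Positions with
minor-allele frequency ≤ 2% in every population are excluded before
testing, and fully fixed samples receive the one-read fixation
correction (one read reassigned to the absent allele) so the logit
model stays estimable.  Benjamini–Hochberg q-values are thresholded at
0.1% FDR; regime-frequency pairwise comparisons use sequential
Bonferroni (Holm).

The production path fits all positions at once with a batched damped
Newton iteration; it is the same model as the scalar fitter and the
two agree to optimizer tolerance (asserted in tests, max |Δp| ≈ 4e-7).
The scalar fitter itself matches R's `glmer` (Laplace) to four decimals
in slope and SE on reference data.

**Clade inference.**  A position is diagnostic for a clade when the
panel lists exactly one allele for that clade there, at least one other
clade is annotated, and no other clade's allele set contains it.  The
clade frequency of a population is the depth-weighted mean of its
diagnostic-allele frequencies with a Wilson interval at the summed
depth.  The aggregation rule across diagnostic SNPs is this package's
choice; a spread diagnostic warns when the per-SNP frequencies disagree
by more than a tolerance (default 0.15), which would indicate
recombination, annotation error or paralogy.

## Selection-coefficient estimation

Carrier counts of the counter-selected clade over generations are fit
by mixed logistic regression: generation as fixed slope, replicate
random intercepts (the initial frequencies), and an observation-level
random effect for overdispersion, maximized by nested Gauss–Hermite
quadrature.  The generation effect is likelihood-ratio tested; the 95%
CI is Wald on the slope.  Fully fixed samples receive the
one-individual correction per population–timepoint (the minimal
perturbation consistent with the stated rule).

Two slope-to-s conventions are exposed.  `transform="slope"` (default)
reports s = −slope, using the small-s approximation log(1 − s) ≈ −s
under which the published estimates of this model family are
constructed.  `transform="exact"` inverts the recursion,
s = 1 − e^slope, and is the consistent estimator when data are
generated by the odds recursion; parameter-recovery tests use it.  Note
that under the w = 1 − s parameterization the two differ by
−log(1 − s) − s (0.042 at s = 0.263).

**Known limitation — attenuation at strong selection.**  With 96-fly
samples the fixation correction floors observed frequencies at
1/96 ≈ 0.0104.  For s ≥ ~0.25 the true counter-clade frequency falls
below that floor by generation ~8, so later timepoints pull the logit
slope toward the floor and the estimate saturates near ŝ ≈ 0.16
regardless of the true s; CIs centred on the attenuated estimate then
undercover badly.  This is a property of the corrected-count model
family at this sample size, not of the implementation (the fit matches
`lme4` exactly on the same data), and it is reported as measured by the
calibration test: at s = 0.1 the bias is −0.006 with 83% coverage; at
s = 0.263, −0.11; at s = 0.4, −0.24.  Estimates from data of this
design should be read as lower bounds once fixation is reached.
Consistently, dropping the fixed final timepoint *raises* the estimate
(the 0/5/10-generation fit exceeds the all-generation fit).

The relative fitness is reported as w = 1 − s with CI endpoints
1 − CI(s); no other transform of the point estimate is applied.

**Drift null.**  The probability that the majority clade (initial
frequency p0, e.g. 0.88) appears fixed in all replicates by generation
T without selection is estimated by Monte-Carlo Wright–Fisher binomial
resampling at the stated census sizes, observed through the 96-fly
genotyping layer; an exact (N+1)-state Markov-chain computation serves
as the small-N oracle.  At census ≥ 300, T = 20 and four replicates the
estimate is ≈ 0 (≪ 0.05), so parallel fixation under neutrality can be
excluded.

## Fitness-component models

All fixed-effect tests are likelihood-ratio tests of the model against
its counterpart without the focal term, on full maximum-likelihood
fits — REML likelihoods are not comparable across fixed-effect
structures.  In the factorial (cytotype × symbiont presence) design
the focal term is the clade main effect plus its interaction with
presence, and within-presence clade contrasts are Wald z-tests.

- **Daily survival**: per vial, flies alive after day d (d ∈ {5,6,7})
  out of the initial count; binomial GLMM with clade fixed effect,
  cross random intercept and vial-level overdispersion.  The
  overdispersion term is placed at the vial level (the observation
  level of this model), matching its per-vial indexing.
- **Survival dynamics**: mixed-effects Cox model,
  H(t) = H0(t)·exp(xβ + c_cross + e_vial), estimated by penalized
  partial likelihood (Efron ties) with Newton inner iterations and
  Nelder–Mead outer maximization of the Laplace-approximate integrated
  partial likelihood over the two variance components.  With variances
  at zero it reduces to the standard Cox fit (matches lifelines and a
  brute-force partial-likelihood optimum to 1e-6).
- **Fecundity**: linear mixed model of pupae counts with cross random
  intercept (statsmodels MixedLM, ML); a single cross falls back to
  OLS with a warning.
- **Hurdle**: mixed logistic zero part; zero-truncated negative
  binomial count part with cross random intercept integrated by
  Gauss–Hermite quadrature.  Dispersion is parameterized as
  Var = μ + αμ²; α → 0 recovers the truncated Poisson (tested against
  a direct truncated-Poisson MLE).  The zero part is skipped with a
  notice when no zeros exist.
- **Pairwise contrasts**: single-step adjustment over the whole
  contrast family using the multivariate-normal distribution of the
  contrast estimates (the Tukey-type least-squares-means procedure);
  scipy's QMC rectangle integrator with a fixed seed, with a direct
  simulation fallback for rank-deficient contrast covariances; Holm
  available as a cheaper alternative.

## Relative quantification

Pfaffl ratios with per-primer amplification efficiencies (default 2.0
= perfect doubling, in which case the ratio equals 2^−ΔΔCt exactly;
efficiencies must lie in [1, 2.2]); technical replicates are averaged
on the Ct scale before the ratio.  Titer comparisons fit a linear
mixed model to natural-log levels with a cross random intercept; the
clade effect back-transforms to a fold difference (base-independent),
reported with the ratio of geometric means alongside, since it is not
generally identical to the mixed-model back-transform.

## Numerical choices

- Gauss–Hermite: 15 nodes per dimension by default (21 for scalar
  OLRE-only fits); differences beyond 1e-6 in log-likelihood were not
  observed against a 4001-point trapezoid oracle.
- Variance components are optimized on the log-SD scale, bounded to
  [e^-8, e^4]; boundary fits report SEs from the pseudo-inverse of the
  observed information (flat directions dropped).
- LRT statistics are clipped at 0 (boundary/optimizer noise).
- The batched Newton uses finite-difference derivatives with a
  Levenberg-style ridge and elementwise step halving.
- Ties in survival times (daily monitoring makes them ubiquitous) use
  the Efron approximation throughout.

## What the simulations do and do not show

The generator reproduces the design quantities of the study —
replicate counts, census, mixture mortality, sampling sizes and
depths, cross/vial structure, censoring horizon — and its observation
noise is exactly binomial/Poisson/log-normal.  Real data add
biological and technical structure the generator omits: linked host
adaptation, sequencing error and mapping bias, vial microenvironment
trends, non-proportional hazards, day-to-day assay drift.  Passing
recovery tests therefore validates the estimators under the stated
stochastic model, not the field realism of that model; conversely the
attenuation analysis above is a genuine property any analysis of this
design inherits.
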
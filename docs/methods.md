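# Methods

This note documents the models behind `seabream`, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real monitoring data.

## The monitoring problem

A long-running marine stock-enhancement program releases hatchery-reared
juveniles (red sea bream, *Pagrus major*, in the motivating system) into a
semi-closed bay.  Monitoring asks four quantitative questions:

1. **How much of the catch is hatchery fish?**  Landings surveys score a
   morphological hatchery mark; survey counts are expanded into the hatchery
   fraction P_h.
2. **Is the fitness of hatchery cohorts declining?**  Cumulative recapture
   rates of release cohorts, standardized by fishing effort, are regressed
   on release year; an exponential decline rate converts to a
   per-generation survival loss.
3. **What is the genetic footprint?**  Microsatellite and mtDNA surveys feed
   diversity statistics, differentiation tests, pairwise F_ST for weakly
   differentiated populations, and a mixture model estimating how much of
   the wild gene pool derives from hatchery broodstock.
4. **What drove the wild population's recovery?**  Annual wild catch is
   regressed on habitat and fishery covariates with AIC-based variable
   selection.

## Mark-survey expansion (stocking module)

P_h = (n_marked / n_checked) / q with mark incidence q (default 1.0: the
deformity mark is treated as fully penetrant among hatchery fish; q is a
parameter because real marks are imperfect), SE = sqrt(phat(1-phat)/n)/q on
the raw fraction.  Strata (markets, areas, years) pool by landings-weighted
averaging.  Catch expansion divides landed mass by a weight-at-age key to
get numbers-at-age, split into hatchery/wild by P_h; landed mass is
conserved exactly.

## Recapture decline and fitness conversion

The cumulative recapture rate of the cohort released in year y, up to age a,
is the sum of its age-1..a recaptures, each multiplied by E_ref/E(catch
year), divided by the number released.  Across release years the rates are
fit with y = a·exp(-λx) by nonlinear least squares initialized from the
log-linear OLS fit.

**Weighting.**  Recapture-rate dispersion grows with the rate itself
(survey expansion noise is multiplicative), so the default fit weights
residuals by 1/y ("relative" weighting; `weights="absolute"` disables it).
Under study-scale simulations (λ = 0.14, lognormal noise sd 0.2, 25
cohorts) the relative-error fit's 95% CI covers the true rate in ~96/100
replicates versus ~81/100 for the unweighted fit, whose asymptotic SEs are
anchored to the large early rates.

Two decline rates (age-1 and age-8 horizons) are compared with
z = |λ₁-λ₂|/sqrt(SE₁²+SE₂²) and a **one-sided** normal p-value, then
combined as a simple average (SE by quadrature/2) and as an
inverse-variance-weighted mean; both are reported because field reports use
the simple average.

The per-generation survival reduction is 1 - exp(-λG) at generation time
G (4.8 years for the motivating stock).  Two uncertainty propagations are
exposed: the exact delta method, SE = G·exp(-λG)·SE_λ, and the first-order
form SE = G·SE_λ (exact only when λG is small; at λ = 0.139, G = 4.8 the
two differ by a factor ~2).  Published figures for this quantity follow the
first-order convention, so both are reported rather than silently choosing
one.

## Wild-gene replacement model

A deterministic single-locus recursion for a semelparous, closed population
under continued stocking.  Genotypes WW (wild, fitness 1), WH (hybrids,
fitness (1+f)/2 — additive effects), HH (hatchery, fitness f ∈ [0,1]).
One generation:

1. reproductive weights (1, (1+f)/2, f) applied to adult genotype
   proportions;
2. gamete wild-allele frequency p* from the weighted pool;
3. wild-born offspring at Hardy-Weinberg in p*;
4. stocked HH recruits added at R per wild-born recruit:
   next = (HWE(p*) + R·[0,0,1]) / (1+R).

With f = 1 this collapses to the closed form p_t = (1+R)^(-t) (used as an
exactness test to 1e-12 over 100 generations).  Linearizing at p → 0 gives
the wild-gene growth factor (1+f)/(2f(1+R)): above 1 the wild gene persists
at an interior equilibrium, below 1 it is replaced completely.  Generation
0 is the pre-stocking state and thresholds are tested strictly (<).  R is
stocked recruits *per wild-born recruit* (not the stocked fraction of the
total); with the neutral case f = 1, R = 0.1 the wild gene crosses 50% at
generation 8 and 1% at generation 49, and complete replacement (<1%) occurs
for f ≥ 0.6 combined with R ≥ 0.4 — the regime boundaries the published
summaries of this model report.  Grid equilibria are iterated (vectorized
over the grid) to max change < 1e-12; cells on the critical boundary
(1+f) = 2f(1+R) decay algebraically (~1/t) and are flagged non-converged
rather than iterated indefinitely.

## Genetic diversity and differentiation (popgen module)

* **Rarefaction richness** (alleles or haplotypes): for N gene copies with
  N_a of allele a, expected distinct alleles in a subsample of g copies is
  Σ_a [1 - C(N-N_a, g)/C(N, g)], computed with exact integer binomials so it
  matches exhaustive enumeration to float precision.  g defaults to the
  smallest per-cell copy count.
* **Unbiased expected heterozygosity** N/(N-1)(1 - Σp²); haplotype
  diversity n/(n-1)(1 - Σp²); nucleotide diversity as mean pairwise
  differences per site after **complete deletion** of alignment columns
  containing a gap or N in any sequence (the conservative default; the
  choice matters only for alignments with indels/ambiguities).
* **Differentiation test**: a permutation test with the multinomial G
  statistic over the 2×A allele-count table, gene copies permuted between
  the two samples, p = (1 + #{perm ≥ obs})/(n_perm + 1) with ties counted
  against rejection; per-locus p-values combine by Fisher's method and
  multiple testing across population pairs uses Bonferroni.  This replaces
  the Markov-chain exact test of older toolchains with an asymptotically
  equivalently calibrated but directly verifiable procedure; measured
  type-I error at α = 0.05 over 500 null replicates is within Monte-Carlo
  error of nominal.

## Empirical-Bayes pairwise F_ST

For weakly differentiated (high gene flow) populations, raw pairwise F_ST
estimates are dominated by sampling noise.  The hierarchy used here: at
each locus the true frequency vector of population i is
Dirichlet(θ·κ) around a hyper-mean κ, and observed counts are multinomial
given the truth, so the marginal of the counts is Dirichlet-multinomial and
F_ST = 1/(1+θ) on the hyper-scale.

* **Hyper-mean κ**: pooled frequencies — over *all* populations when a full
  matrix is computed (the empirical-Bayes borrowing step), over the pair
  when only two samples exist.
* **Hyper-scale θ**: method of moments on pairwise frequency differences,
  using E[Σ_a (p̂_ia - p̂_ja)²] = H·[2F + (1/n_i + 1/n_j)(1-F)] with
  H = 1 - Σκ².  Differences cancel κ, so the estimate has none of the
  shrinkage bias that plugging an estimated mean into the marginal
  likelihood induces (that likelihood is still evaluated and reported per
  pair).  A non-positive moment estimate (no detectable divergence) clamps
  θ to its upper bound and flags the result.
* **Reported pairwise value**: the posterior-mean pairwise Wright F_ST.
  Population i's posterior is Dirichlet(θκ + x_i) with mean μ_i and
  variance V_i; the estimate is Σ[(μ_i-μ_j)² + V_i + V_j] / Σ 2H over loci,
  which folds in the two-population (r/(r-1) = 2) correction.  At the true
  hyperparameters its expectation is exactly 1/(1+θ): the posterior
  variances add back precisely what shrinkage of the means removes.

Calibration: island-model worlds at F_ST = 0.01 (20 populations, 5 loci of
~30 alleles, 50 fish per sample) are recovered without detectable bias
(mean pairwise estimate ≈ 0.010, replicate sd ≈ 0.001).  UPGMA clustering
of the matrix uses average linkage with heights at half the merge distance
and a deterministic tie-break toward the lexicographically smallest member
tuple; children are ordered by smallest leaf label so serialized trees are
reproducible byte for byte.

## Genetic stock identification (gsi module)

Conditional-ML mixture model: L(π) = Π_i Σ_k π_k f_k(x_i) with f_k the HWE
multilocus genotype probability under source k's allele-frequency
estimates, held fixed (the "conditional" formulation).  Frequencies are
smoothed as (x+1)/(N+A) over the union of alleles seen in baselines and
mixture, so private mixture alleles keep positive likelihood.  EM: E-step
posteriors, M-step π = mean posterior, stop at max|Δπ| < 1e-7 (max 10,000
iterations), 10 starts (uniform + Dirichlet-random) with the best optimum
kept; the observed-data log-likelihood is asserted non-decreasing at every
iteration.  On every small two-source problem tested, the EM optimum
matches a 0.001-step grid search of the likelihood within 0.005.

Standard errors decompose as SE² = SE_info² + SE_baseline²: the inverse
observed information of the mixture likelihood at π̂ (mixture sampling) plus
the empirical variance of re-estimates under parametric resampling of
baseline allele counts (baseline sampling; 200 resamples, EM restarted at
π̂).  In the diagnostic-allele limit SE_info reduces to the binomial
sqrt(π(1-π)/n).  Percentile bootstrap CIs (default 1,000 replicates)
resample mixture individuals and baseline gene copies jointly.  Calibration
at the study's scale (two baselines at F_ST = 0.05, 80 fish each; mixture
of 167 at true π = (0.423, 0.577)): the estimate falls within 3 reported
SEs of truth in ≥95/100 replicates.

## Recovery regression (regression module)

Plain OLS with an intercept; AIC uses the full Gaussian convention
n·ln(RSS/n) + n(ln2π + 1) + 2(p+2) so levels are comparable with mainstream
stepwise tools (selection of course depends only on differences, which are
asserted to match statsmodels').  Stepwise search is greedy backward by
default (forward and bidirectional available), ties broken toward the
smaller model then alphabetically, with the full path logged.  No time-lag
terms are used: lags between effort and recruitment are unidentifiable in
an overlapping-generations catch series, so effort enters contemporaneously.

## Synthetic data: what it emulates, what it does not

Generators share one global seed fanned out through `SeedSequence` spawn
keys (stream per generator), so adding a generator never shifts another's
draws; identical seeds reproduce byte-identical outputs.

* **Genotypes**: Dirichlet island model — per-locus hyper-mean κ ~
  Dirichlet(1), population frequencies ~ Dirichlet(κ·(1-F)/F), HWE
  genotypes.  Defaults mirror the monitoring design: 8 samples × 80 fish,
  5 loci totalling 157 alleles, F_ST ≈ 0.011.  No linkage, no mutation
  model, no null alleles or scoring error: passing tests show estimator
  correctness under the stated model, not robustness to genotyping
  artefacts.
* **Mixtures**: origins drawn from the true proportions, genotypes from the
  source's *estimated* frequencies — one sampling step removed from the
  baselines, as in a real assignment problem.
* **Release cohorts**: cohort y's true cumulative rate r₀·e^(-λy)
  (defaults r₀ = 0.14, λ = 0.139, 25 cohorts) with multiplicative lognormal
  noise (sd 0.2, our choice — the effort-noise model is not specified by
  any source); within-cohort recaptures decline geometrically over ages
  1–8 and scale with the catch-year effort (linearly declining series).
  Recaptures are continuous (market-expansion scale), not Poisson counts,
  which also keeps the zero-noise cases exactly log-linear.  Because one
  cohort-level rate drives all ages, age-1 and age-8 horizons share a
  decline rate by construction; differential decline across horizons is
  not modelled.
* **Covariates**: habitat proxy trending up, effort declining, plus an
  uninformative SST and a declining-but-inactive hatchery fraction;
  response = linear signal + Gaussian noise.  Trend-free variation and the
  residual sd (60 t) are sized so the active effects carry t ≈ 2 and 4 at
  n = 27 — the strengths the recovery-period regression reports — giving
  R² ≈ 0.7.

## Numerical conventions

Rarefaction uses exact integer binomials (no log-gamma rounding).  EM
likelihoods are computed in log space with logsumexp.  θ is clamped to
[1e-4, 1e6] and reported F_ST to [1e-6, 1-1e-6].  Alignment positions are
reported 1-based.  Missing genotypes are (0, 0); a half-missing pair is
normalized to fully missing on construction.  All randomized routines take
explicit seeds; derived streams stay below 2³¹.

## Known limitations

Conditional GSI ignores baseline uncertainty in the point estimate (it
enters the SEs only); a joint-likelihood or Bayesian mixture estimator is
out of scope.  The replacement model is deterministic, single-locus,
semelparous, with no age structure or migration — it brackets regimes, it
does not forecast.  The permutation differentiation test is an
approximation to an exact test; its guarantee is calibration, not
identical p-values.  Effective-population-size (Ryman-Laikre) modelling is
deliberately not implemented.
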
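# seabream

Analyses for long-term monitoring of marine stock-enhancement programs:
does releasing hatchery-reared juveniles rebuild a fished population, and
at what genetic cost?

The package implements, as a tested library plus numbered analysis drivers,
the computational core of such a monitoring study (the motivating system is
red sea bream, *Pagrus major*, in a semi-closed Japanese bay):

* **Stocking effect** — expansion of hatchery-mark surveys into the
  hatchery fraction of landings (P_h); effort-corrected cumulative
  recapture rates of release cohorts; exponential-decline fits
  y = a·e^(−λx) with a z-test comparing decline rates; conversion of λ to a
  per-generation survival loss 1 − e^(−λG).
* **Wild-gene replacement** — a deterministic single-locus recursion for a
  semelparous population under continued stocking: wild WW (fitness 1),
  hybrids WH ((1+f)/2), hatchery HH (f), Hardy–Weinberg reproduction, R
  stocked HH recruits per wild-born recruit.  The wild-gene growth factor
  (1+f)/(2f(1+R)) separates persistence from complete replacement.
* **Population genetics** — rarefaction allelic/haplotype richness,
  unbiased heterozygosity, haplotype and nucleotide diversity, permutation
  G-tests of differentiation, empirical-Bayes pairwise F_ST for weakly
  differentiated populations (Dirichlet-multinomial hierarchy, posterior-
  mean pairwise Wright F_ST), and UPGMA dendrograms with deterministic
  tie-breaks.
* **Genetic stock identification** — conditional-ML EM estimation of
  mixture proportions from baseline allele frequencies, with standard
  errors split into mixture-sampling and baseline-sampling components and
  percentile bootstrap intervals.
* **Recovery regression** — Pearson tests and backward stepwise-AIC OLS
  attributing wild-catch recovery to habitat and fishing-effort covariates.
* **Synthetic data** — generators for all inputs (island-model genotypes,
  mixtures with known composition, release cohorts with known decline,
  covariate series with known coefficients) so every estimator is testable
  against its own truth.

Formats: Genepop for genotypes, aligned FASTA for haplotypes, CSV for time
series, Newick for trees.

## Worked example

The replacement model, from the command line:

```sh
$ seabream replace --f 1 --r 0.1 --thresholds 0.5,0.01
wild gene < 0.5: generation 8
wild gene < 0.01: generation 49

$ seabream replace --f 0.6 --r 0.3 --thresholds 0.01
wild gene < 0.01: never (persists)
```

With hatchery fish as fit as wild fish (f = 1) and one stocked recruit per
ten wild-born (R = 0.1), half the wild genes are replaced within 8
generations and 99% within 49 — stocking alone rewrites the gene pool even
with no fitness cost.  At f = 0.6, R = 0.3 the growth factor is
1.026 > 1, so a wild-gene fraction (~7.7%) persists at an interior
equilibrium.

The full synthetic pipeline (generate → analyze → compare to truth):

```sh
$ python analysis/01_simulate_datasets.py --seed 1
$ python analysis/05_stock_identification.py
mixture of 167 fish over sources ['P1', 'P2'] (11 EM iterations, logL -4237.8)
  P1: 44.9 +/- 4.7% (95% CI 35.6-54.3%)  [truth 42.3%]
  P2: 55.1 +/- 4.7% (95% CI 45.7-64.4%)  [truth 57.7%]
```

The mixture was simulated with 42.3% of fish drawn from the P1 baseline;
the conditional-ML estimate recovers it well within one reported standard
error (which includes the baseline-sampling component).  The other drivers
(`02` recapture decline and fitness loss, `03` stepwise regression, `04`
diversity / EB F_ST / UPGMA, `06` replacement surface) print analogous
truth comparisons and write their tables under `results/`.

`seabream demo --seed 7` runs everything end to end and writes a single
report with a reproducibility manifest.

## Layout

```
src/seabream/      library: io, simulate, popgen, gsi, stocking,
                   regression, pipeline, cli
analysis/          numbered drivers over the library (01 simulate ... 06
                   replacement)
scripts/           acceptance script
tests/             pytest suite incl. oracle-based and calibration tests
docs/methods.md    models, assumptions, calibration results, limitations
```
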
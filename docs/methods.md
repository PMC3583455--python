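# Methods

This note documents the models, defaults, and numerical choices behind
`gsalloc`, and what the simulation does and does not capture.

## The breeding system being simulated

A single biparental maize-like cross: two fully homozygous inbred
parents, polymorphic at every locus, produce an F1; doubled-haploid (DH)
lines are extracted from F1 gametes, so every line is fully homozygous
and one generation removed from the F1. Because only two parental
alleles segregate, every locus is biallelic and alleles are tracked by
parental origin. All genetic variance is additive; there is no
dominance, epistasis, mutation, or genotype-by-environment interaction.

### Genome and map

* 10 chromosomes, 1796 cM total. Only the total length is pinned down by
  the source composite map, so the default uses ten equal chromosomes of
  179.6 cM; per-chromosome lengths are configurable. Total map length is
  what drives both the expected crossover count and the effective-loci
  count, so this simplification does not touch the quantities studied.
* 500 SNP loci per chromosome, evenly spaced over (0, L] cM.
* Meiosis is the no-interference model: crossover counts per chromosome
  are Poisson with mean L/100 (length in Morgans), breakpoints uniform,
  starting strand fair. Recombination between loci d Morgans apart is
  therefore Haldane's r = (1 - exp(-2d))/2, which the test suite checks
  against simulated gametes.

### Trait architecture

* 200 markers: 20 per chromosome, evenly spaced among that chromosome's
  loci (a remainder, when the marker count is not divisible by the
  chromosome count, goes to the lowest-index chromosomes).
* 100 QTL drawn uniformly from the non-marker loci, so marker and QTL
  sets are disjoint (the conservative reading; whether the original
  implementation allowed overlap is unknown, and with 100/5000 loci the
  difference is small).
* QTL effect magnitudes follow a geometric series a^k with
  a = (l - 1)/(l + 1), l = 100; each QTL's favorable allele goes to
  parent 1 or 2 with probability 1/2, so the parental means are equal in
  expectation.

### Phenotypes and budgets

Single-plot values are the genetic value plus normal noise with variance
`sigma_a^2 (1/h2plot - 1)`; entry means average r plots. `sigma_a^2` is
the realized (sample) variance of the current C0 DH population's true
genetic values, recomputed per replicate, so the nominal plot
heritability holds for the population actually simulated rather than for
a hypothetical expectation. In cross-validation runs the variance is
taken over all simulated DH lines (training pool plus validation set).

Budget cells resolve as `n = round(B / (C + r F))`,
`nPh = round(F n)`, both rounded half-to-even — the convention that
reproduces every printed line count in the source tables (e.g.
0.5×167 → 84 but 0.5×333 → 166). The realized cost may exceed B by less
than one plot equivalent. When F < 1 the phenotyped subset is a uniform
random subset of the genotyped lines.

## Marker-effect models

All models fit entry means `y_i = mu + sum_j z_ij u_j d_j + e_i` with
codes z in {-1, 0, +1} (DH lines are never 0).

**RR-BLUP.** d = 1 everywhere, u ~ N(0, sigma_u2 I). The variance ratio
lambda = sigma_e2/sigma_u2 is profiled out of the restricted likelihood
on an orthonormal basis of the intercept's complement (QR of the ones
column), using one eigendecomposition of the projected marker
cross-product; zero eigenvalues (when n exceeds the marker count) are
genuine residual-only directions and are kept. The scalar optimization
runs over log-lambda in [-12, 12] (bounded Brent, xatol 1e-8). Effects
then solve the mixed-model equations at the estimated ratio; a dense MME
solve is the test oracle at 1e-8. An ML option exists; REML is the
default and the two agree closely at the population sizes used here.
Constant phenotypes return the degenerate fit (all effects zero).

**BayesC-pi.** Gibbs sampler, single chain, update order per sweep:
intercept; loci in index order with (d_j, u_j) sampled jointly from the
marginal inclusion odds; sigma_u2 from its conjugate scaled-inverse-
chi-square posterior (nu = 4) over the currently included markers;
sigma_e2 with a flat prior (posterior SSR/chi2_{n-2}); pi from
Beta(m - k + 1, k + 1) under a Uniform(0, 1) prior. The prior scale is
S_u2 = (nu - 2)/nu × sigma_tilde_u2 with
sigma_tilde_u2 = var(y) / (m (1 - pi) mean-marker-variance), evaluated at
the current pi and floored at (1 - pi) >= 1/m — the reading of the
(typographically damaged) printed scale formula under which the scale is
the per-locus share of phenotypic variance. Defaults: 3000 iterations,
1000 burn-in, initialization pi = 0.5, effects 0, sigma_e2 = var(y)/2.
Reported effects are posterior means of d_j u_j. With inclusion forced
on and variances fixed the posterior mean reproduces the ridge solution
at the same ratio (tested). Diagnostic freezes (`fixed_pi`,
`fixed_sigma_u2`, `fixed_sigma_e2`, `include_all`) exist for exactly
such checks.

**Stepwise OLS.** Forward step: each excluded marker's partial t-test
(equivalently partial F with 1 df) when added to the current model; the
smallest p enters if p <= 0.20, ties to the lowest marker index (exact
duplicates produce bitwise-equal statistics, so argmin settles ties
deterministically). After each entry, backward elimination repeatedly
drops the worst included marker with refit p > 0.20. The model size is
capped at n - 2 so one residual degree of freedom remains. Candidates
whose residual sum of squares given the model falls below a relative
tolerance of 1e-10 are skipped as collinear; a candidate absorbing all
residual variation gets p = 0. The search runs on the sweep operator
over the centered cross-product matrix (O(m^2) per step), and the final
coefficients are recomputed by least squares on the selected subset.
Forward candidates are tested conditionally on the current model — the
standard reading of the source's ambiguous "individually fitted again".

GEBVs are `Z @ effects`, excluding the intercept; every reported
accuracy is a Pearson correlation, so the intercept is irrelevant.
Zero-variance GEBVs (e.g. an empty OLS model) yield NaN accuracy, which
the experiment drivers carry through and exclude from summaries.

## Deterministic theory

* Effective number of loci: me = chromosome number + map length in
  Morgans = 27.96, used real-valued everywhere; 28 is reporting only.
* Expected accuracy: r_hat = sqrt(lam/(lam+1)), lam = n h2 / me, with h2
  the entry-mean heritability r·h2plot/(r·h2plot + 1 - h2plot).
* Adjusted accuracy: r_adj = r_hat - 0.5 r_hat^4 (me/n). The source
  prose describes "an approximate adjustment of 0.5 r^4 (me/n)" but the
  printed equation is unreadable; the two candidate placements are on
  r_hat or on r_hat^2. The placement on r_hat is used because it puts
  the deterministic curves 0.01-0.03 above the simulated accuracies on
  the high-heritability grid, which is how the adjustment's quality is
  characterized in the source; the placement on r_hat^2 roughly doubles
  that gap. Neither placement reproduces the source's r = 1 and r = 2
  average gaps simultaneously (see Known limitations).
* Selection intensity: infinite-population i = phi(z)/p. The printed
  study intensities (2.15 at 10/250, 1.99 at 10/167, 1.75 at 10/100)
  match this formula; a finite-sample order-statistic correction would
  not (10/250 would give about 2.13).
* Optimal allocation: for each candidate r, the budget resolves to
  n = B/(C + rF) lines; candidates are ranked by the *unadjusted*
  accuracy evaluated at n truncated to a whole line count. This
  combination reproduces all 12 printed optimal strategies; ranking by
  the adjusted value instead flips the two cells where n·h2 ties exactly
  between r = 1 and r = 2 (the me/n term then favors the larger n).
  Both accuracy columns are reported per row so the choice is visible.

## Experiment drivers

* Seeds: a master seed spawns one child stream per replicate
  (`numpy.random.SeedSequence`), so results are bit-reproducible and any
  replicate can be regenerated alone. Identical seeds give identical
  summary tables, byte-for-byte through the CSV writer.
* Cross-validation: per replicate, one fresh genome architecture and one
  DH population of max(n grid) + 500 lines; the first n lines are
  phenotyped and train the model, the last 500 are the validation set.
  All cells of a grid share the replicate's population (training sets
  nested, validation fixed), a paired design that sharpens cell
  contrasts such as the r = 1 -> 2 accuracy gain.
* Random-mating decay: C0 DH lines are randomly mated (distinct parents,
  with replacement) into 1000 F1s, then 1000 C1 S0, C2, C3; the
  C0-trained model is scored within each cycle's 1000 individuals.
* Recurrent selection: RR-BLUP trained once on C0; top 10 of all n lines
  by GEBV paired into 5 random crosses (each line used once); 200 C1 S0
  from random F1 matings; top 20 by GEBV recombined into 200 progeny per
  later cycle (the "repeat the procedure" reading fixes later cycle
  sizes at 200). Gains are reported in units of the C0 genetic SD.
  When F = 1 there are no nonphenotyped C0 lines, and that accuracy
  column is reported only for F < 1 cells.
* Summaries: mean and standard error (sample sd / sqrt(reps)) per cell,
  NaN replicates excluded.

## Problem sizes

Default replicate counts follow the study conditions (200 for accuracy
experiments, 500 for gain runs). The test suite and the acceptance
script run the same pipelines at 40-150 replicates, chosen so that every
stochastic check carries a three-standard-error tolerance at its own
replicate count; the acceptance script reports each quantity with the
replicate count used.

## Known limitations

* The simulator emulates an idealized biparental DH program: fully
  polymorphic parents, exactly biallelic loci, no missing genotypes or
  phenotypes, no genotype-by-environment interaction, no cost for DH
  line production. Agreement of the reproduction tests therefore speaks
  to the model system, not to field data.
* Equal chromosome lengths are an approximation; only the 1796 cM total
  is authoritative.
* The theory-vs-simulation gap depends on the committed reading of the
  adjusted-accuracy formula. With the reading used here the r = 1 grid
  average gap at plot heritability 0.6 is about 0.03; the r = 2 average
  is about 0.00 rather than the reported 0.013, and no algebraic
  placement of the adjustment matches both reported averages while the
  per-cell simulated accuracies match the source's printed tables. At
  plot heritability 0.2 the formulas overshoot simulated accuracy by
  0.05-0.10 under any reading — visible in the source's own per-cell
  accuracies — so low-heritability cells are excluded from that
  comparison's averages.
* The stepwise-OLS accuracy at small n is sensitive to the exact
  selection rules (conditional vs marginal candidate tests, elimination
  order); the implemented rules are the standard reading, and its
  low-n accuracies sit somewhat below the source's, which inflates the
  relative advantage of maximizing population size for OLS.
* BayesC-pi runs a single chain with no formal convergence diagnostics,
  matching its role here (it tracks RR-BLUP closely and is not used in
  gain runs); the equivalence and inclusion tests are its guardrails.
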
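# Methods

## The design question

Genotyping every individual in a quantitative-trait association study is
expensive.  An *extreme sampling* (selective genotyping) design genotypes
only the individuals in the two tails of the trait distribution — the
upper tail as "cases", the lower as "controls" — and tests genotype
against tail membership.  This package quantifies, by simulation, what
that trade costs in power and buys in power per genotyped individual,
across genetic models, effect sizes, minor-allele frequencies, sampling
fractions and (un)balanced case:control ratios, and provides the matching
per-SNP scan for tabular data.

## Trait model

A single biallelic locus has minor (risk) allele B with frequency
`p = maf` and major allele A with frequency `q = 1 - p`.  Genotypes are
drawn under Hardy–Weinberg equilibrium — each individual's dosage is the
sum of two independent Bernoulli(p) allele draws, so (AA, AB, BB) have
frequencies (q², 2pq, p²).  The trait is normal within genotype,
`y | g ~ N(mu_g, sd²)`, with genotype means set by the inheritance model:

| model          | mu_AA | mu_AB | mu_BB |
|----------------|-------|-------|-------|
| dominant       | 1     | δ     | δ     |
| recessive      | 1     | 1     | δ     |
| multiplicative | 1     | δ     | δ²    |

δ = 1 is the null of no association.  The within-genotype standard
deviation defaults to `sd = 1` and variances are assumed homogeneous
across genotypes.  `sd` is not independently identified by the reference
power table, but `sd = 1` reproduces its full-data column through the
closed-form noncentral-F check (e.g. dominant δ = 1.2 gives analytic
power 0.319 against the printed 0.3188, δ = 1.3 gives 0.634 vs 0.6297),
so it is the default and exposed as a parameter.

Deliberately out of scope: linkage disequilibrium between loci,
covariates, polygenic background, non-normal traits, and rare-variant
burden-style extensions.

## Sampling designs and tests

Four analysis arms share one calibrated-significance framework:

* **full_quantitative** — one-way fixed-effects ANOVA of the trait on the
  genotype classes present (2 df when all three occur).
* **extreme_case_control** — the top `round(n*f_upper)` and bottom
  `round(n*f_lower)` phenotypes by *rank* (ties broken by ascending
  index, so selected counts are exact and selection is deterministic),
  then Fisher's exact test on the 2×3 tail-by-genotype count table.  The
  default test is the conditional exact test on the uncollapsed 2×3 table
  (the Freeman–Halton extension, i.e. what R's `fisher.test` computes on
  a 2×3 matrix): this is the variant that reproduces the reference power
  table, which model-specific collapsing does not (it is uniformly more
  powerful than the published extreme-sampling powers).  Collapsed 2×2
  modes — dominant {AA} vs {AB∪BB}, recessive {AA∪AB} vs {BB}, and the
  allelic 2×2 with two alleles per individual — and a logistic mode are
  available when a model-directed test is wanted.
* **random_quantitative** — a uniform random subset of the same
  genotyping cost as the matched extreme design, analysed by ANOVA on the
  retained quantitative phenotypes.  How the random comparator is
  analysed is an inference: at fraction 0.5 the subset is the entire
  cohort and the reference table's random-sampling column then coincides
  with its full-data column within Monte-Carlo error (e.g. 0.8777 vs
  0.8755 at δ = 1.4), and at fraction 0.1, δ = 1.3 dominant the subset
  ANOVA closed form (~0.155) matches the printed 0.1546.
* **median_dichotomy** — the extreme design with both fractions 0.5:
  every individual is labelled by a median split.

All two-sided exact p-values use the point-probability convention: sum
the conditional probabilities of every table (same margins) whose
probability does not exceed the observed table's.  A relative tie
tolerance of 1e-9 guards against floating-point near-ties; tables are
enumerated in log-space with `gammaln` factorials.  A zero column margin
carries no information and yields p = 1.

## Calibrated type-I error

Fisher-type p-values are discrete, so the rule "reject at p ≤ 0.05" does
not attain a 5% type-I error, and comparing arms at nominal α would be
unfair.  Each arm is therefore calibrated: simulate `n_null_reps` null
(δ = 1) replicates, and take as cutoff the largest attained null p-value
whose empirical null rejection proportion does not exceed α.  With
continuous p-values this is the `floor(alpha * n_null_reps)`-th order
statistic; with heavily tied discrete p-values it steps down so the
attained level never exceeds α on the calibration sample (the attained
level can sit slightly below α — e.g. ~0.044–0.050 for the 2×3 exact
test on 30 + 30 individuals).  Power is the fraction of effect
replicates with p ≤ cutoff, reported with its binomial standard error
`sqrt(power*(1-power)/R)` and as power per genotyped individual
(power divided by cases+controls, subset size, or n — the genotyping
cost the design is meant to reduce).

The null p-value distribution does not depend on the effect size or on
the generating model's label (under δ = 1 genotype and phenotype are
independent), so one calibration per (arm configuration, n, maf, sd) is
shared across an effect-size grid.  Default sizes are 100,000
calibration replicates and 10,000 power replicates per cell, making
cutoff noise negligible against power Monte-Carlo error; the test suite
runs a fast mode (20,000 / 2,000) and the examples are smaller still.

An analytic oracle cross-checks the simulation: full-data ANOVA power in
closed form from the noncentral F with noncentrality
`lambda = n * sum_g f_g (mu_g - mu_bar)^2 / sd^2`.

## Implementation of the Monte-Carlo engine

Replicates are simulated in vectorized blocks (default 20,000 cohorts per
chunk).  Exact-test p-values are obtained from precomputed lookup
structures: for 2×2 collapses, a table of two-sided p-values indexed by
(column margin, cell count) at fixed row sums; for the 2×3 test, an
evaluator that groups replicates by column margins and enumerates each
margin's conditional distribution once (cached).  The scalar public API
(`simulate_cohort → select_extremes → build_contingency → fisher_*`)
defines the semantics; the test suite asserts the vectorized engine
agrees with it to 1e-10 on shared inputs.

Randomness: every grid cell draws from a dedicated stream derived from
(seed, cell key) via `SeedSequence`, so results are bit-for-bit
reproducible and independent of evaluation order; within a cell the
vectorized replicate block consumes one stream.

## Per-SNP pipeline

The scan mirrors a real-data workflow.  Thresholds are empirical
percentiles by the nearest-rank rule with inclusive boundaries: controls
are `trait ≤` the T1-th percentile value, cases `trait ≥` the T2-th,
individuals strictly between are excluded, and ties at a shared
threshold go to the control side so the sets stay disjoint at a median
split.  Per SNP: missing genotypes are dropped (complete case, no
imputation), MAF is computed among tested individuals, the chosen test
runs (Fisher collapses, the 2×3 exact test, or univariate logistic
regression on dosage with Wald inference), and an exact Hardy–Weinberg
test — full enumeration of heterozygote counts conditional on allele
counts — is attached from all genotyped individuals.  Bonferroni uses
m = the number of SNPs actually tested in that cell; monomorphic SNPs
are emitted with p = 1 and flagged rather than raised, and excluded from
m.  Logistic fits that hit complete or quasi-complete separation are
likewise flagged (p = 1) so scans never abort.  The genomic inflation
factor is the median implied 1-df chi-square over its null median.

Genotype input is a dosage TSV or a biallelic VCF (GT fields; 0/0, 0/1,
1/1 → 0, 1, 2; ./. → missing; multiallelic records skipped with a
logged count), with per-SNP re-orientation so the coded allele is the
minor allele (optional, on by default).  The upper tail is labelled
"case" throughout; for traits where the lower tail is the clinically
interesting one the labels are a convention, not a claim that controls
are healthy.

## Synthetic fixtures

`make_fixture` writes a phenotype TSV and genotype TSV (optionally a
VCF) for n individuals: one causal SNP simulated under the requested
spec drives the phenotype, plus a chosen number of independent HWE null
SNPs with MAFs drawn Uniform(0.05, 0.5), and a truth sidecar JSON naming
the causal SNP.  This emulates a small association panel with exactly
one signal and no structure; real data adds linkage disequilibrium,
relatedness, stratification, genotyping error and phenotype covariates,
none of which the fixture generates — passing the fixture checks
validates the machinery, not robustness to those features.  Default
validation conditions: a spiked fixture (δ = 2, dominant, maf 0.3,
n = 500, 99 null SNPs) where the causal SNP should attain the smallest
p-value in ≥95% of runs, and all-null fixtures (δ = 1) where raw
rejections should run at ~5% and λ_GC near 1.

## Problem sizes and reproduction

`scripts/acceptance.py` recomputes the headline quantities at the full
scale (10,000 power replicates, 100,000 calibration replicates per arm;
n = 300, maf = 0.3 for the reference cells — the recessive column is
also run at n = 300 — plus the unbalanced-design scan at n = 500,
maf = 0.2, and 120 pipeline fixture runs); it completes in a few minutes
on one CPU.  The pytest suite uses the fast mode (2,000 / 20,000) and
reduced grids so the whole suite runs in under two minutes.

## Known limitations

* Power for the extreme/Fisher arm is simulation-only; no analytic
  approximation is provided.
* The calibrated cutoff is conservative under heavy discreteness (small
  tails), so attained type-I error can sit a few thousandths below α.
* The optimal unbalanced ratio is estimated from a grid of control
  fractions; adjacent grid cells can be within Monte-Carlo error of the
  argmax at the default replicate counts.
* Published real-cohort analyses (methadone dose, cattle yearling
  weight) are not reproducible here — those datasets are not deposited —
  so the pipeline is validated exclusively on synthetic fixtures.
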
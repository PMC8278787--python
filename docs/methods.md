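# Methods

## The weighted de novo load model

The core statistic tests whether a genomic region carries an excess of de
novo single-nucleotide variants (DNVs) in a cohort of sequenced trios,
weighting each possible variant by a functional score.

For a region annotated against a reference sequence, every internal site
with a full trinucleotide context contributes three (site, alternate-allele)
entries. Under the null, the DNV count at entry *e* is an independent
Poisson variable with intensity

    lambda_e = 2 * N * mu(context_e, alt_e)

where *N* is the number of trios (the factor 2 counts the two transmitted
haplotypes) and mu is the per-site, per-generation, per-haploid-genome
substitution probability from a 64-context x 3-alt rate table. The test
statistic is the weighted load

    T = sum_e w_e * X_e,   X_e ~ Poisson(lambda_e),   w_e in [0, 1],

a compound-Poisson sum. The reported p-value is the upper tail
P(T >= t_obs). Recurrent identical DNVs count with multiplicity: each
proband-level event is an independent draw under the null. Indels and MNVs
are excluded from testing (the rate model is substitution-only) but kept in
an excluded-records report.

`lambda = 2 N mu` is used rather than `1 - (1 - mu)^(2N)`; for mu ~ 1e-8
and cohort-scale N the relative difference is below 1e-6.

Weights default to 1, which reduces T to a rate-weighted event count and
the p-value to the Poisson(Lambda) upper tail. A per-allele score file is
accepted and min-max scaled into [0, 1]; entries missing from a supplied
score map get weight 0 (unscored alleles then contribute neither to T nor
to its null distribution, keeping the two sides consistent).

## Tail probability computation

Three routes compute P(T >= t), and they deliberately cross-check each
other:

**Exact lattice convolution.** Whenever the weights lie on a rational
lattice (uniform weights, or scores with fixed decimal precision), entries
sharing a lattice weight are merged (a sum of independent Poissons is
Poisson), and the distribution of T is built by convolving truncated
Poisson point masses on the integer lattice. Cost scales with the number of
*distinct weights*, not grid size, so exactness is routinely available even
for multi-kilobase regions. Per-entry truncation points are chosen so the
total discarded mass stays below the requested tolerance (default 1e-12);
mass convolved past the needed support is folded into the tail, which can
only overstate p by less than that tolerance. Arbitrary-precision weights
are quantized to a 1/1000 lattice first (each weight moves by < 5e-4); a
support guard (500,000 lattice points) routes pathological cases to Monte
Carlo.

**Saddlepoint approximation.** The scalable route follows the classical
construction for the compound-Poisson cumulant generating function

    K(s) = sum_e lambda_e (exp(s w_e) - 1).

K'(s) is strictly increasing, so the saddlepoint K'(s_hat) = t is found by
growing the bracket geometrically until K'(s_max) > t and bisecting
(tolerances 1e-12/1e-14). The tail is then the Lugannani-Rice formula with
the lattice continuity correction

    u_hat = (1 - exp(-s_hat * delta)) / delta * sqrt(K''(s_hat)),

where delta is the detected common lattice span of the weights (the
continuous form s_hat * sqrt(K'') is used when no lattice is detected), and
t is first snapped up to the attainable lattice.

The saddlepoint is an asymptotic device whose relative accuracy improves
with the number of contributing entries. A pre-registered accuracy sweep
against the exact convolution (lattice weights 0.30-1.00, intensities
U(0.05, 1)) measured the maximum |log10 p_sp - log10 p_exact| by entry
count: about 0.23 at 3 entries, 0.044 at 8, and at most 0.018 from 9
entries up. Tiny grids fail because their tails are dominated by single
large-weight atoms that no smooth tilted approximation can represent.
Accordingly `saddlepoint_pvalue` computes the exact convolution instead of
the approximation when a grid has fewer than 9 positive-weight entries,
when t is within three lattice steps of the null mean E[T] (the w_hat -> 0
singularity region), or when all weights are equal (T is then a scaled
Poisson count and the Poisson tail is returned directly, which is what
makes the uniform-weight reduction exact to 1e-10). Real regions have
thousands of entries and sit comfortably in the approximation's domain.

**Monte Carlo.** A seeded estimator draws per-entry Poisson counts,
reports (1 + #{T_sim >= t}) / (n_sims + 1), and attaches a 95%
Clopper-Pearson interval. It serves as the assumption-free oracle wherever
exact convolution is infeasible.

`region_pvalue` (the route used by the per-region driver `test_regions`)
prefers the exact convolution whenever the lattice guard admits it and
falls back to the saddlepoint otherwise, so reported region p-values are
exact in the common fixed-precision-score case.

A conditional variant P(T >= t | total count = n_obs) is also exposed:
given the total, event locations are i.i.d. with probabilities
lambda_e / Lambda, so the conditional distribution is an n-fold lattice
convolution of the single-draw weight distribution (guarded to n_obs <= 50).

**Cohort pooling.** `test_regions` always adds a pooled cohort: DNV lists
are concatenated and trio counts summed, so Lambda is recomputed for the
pooled sample size rather than meta-combining p-values. Multiplicity is
adjusted per cohort across regions (Benjamini-Hochberg by default,
Bonferroni optionally).

## Type-I calibration and the role of continuous weights

The calibration study simulates cohorts at enrichment gamma = 1 and checks
that the fraction of region-tests with p < 0.05 falls inside the exact
binomial 95% band around 0.05 (2000 tests: [0.0405, 0.0600]).

This check is only meaningful with a continuous-valued weight map. With
uniform weights T is a Poisson count, the attainable p-values are a sparse
discrete set, and the test is conservative by construction — the rejection
rate at alpha = 0.05 lands around 0.015-0.035 depending on Lambda, below
alpha but far below the band. With per-allele scores drawn uniformly on a
0.01 lattice over [0.05, 1] (the generator's functional-score model,
resembling min-max-scaled deleteriousness scores), the null distribution of
T is nearly continuous: the largest single atom near the rejection
threshold carries about 0.002 of mass, so the rejection rate is pinned just
under alpha. Region p-values in this study are exact (lattice convolution),
so the measured rate reflects the model, not approximation error.
Conservativeness under uniform weights is a property, not a defect, and is
asserted separately (rate <= alpha).

## Synthetic-data generator

The generator produces every input class with the statistical structure the
pipeline assumes, deterministically under a seed. Defaults are the study
conditions: a 516-trio discovery cohort and a 2155-trio replication cohort
(2671 trios pooled), 20 enhancer-scale regions of 2-3 kbp on a random
contig at GC fraction 0.41, and the bundled demonstration rate table
(transitions 1.5e-8, transversions 5e-9 — order 1e-8 with the canonical
~3:1 ratio, context-independent and strand-closed; it is illustrative
package data, not an empirical estimate).

* **DNVs** are drawn entry-wise as Poisson(gamma_region * lambda_e) and
  assigned to uniformly chosen proband identifiers. gamma multiplies the
  Poisson intensity, the simplest alternative consistent with the null;
  gamma = 1 *is* the null of the load test, so calibration and power
  studies consume exactly this generator.
* **Copy-number windows** are a diploid baseline 2 + N(0, 0.05) per 1-kbp
  window, with planted events overwriting the windows over a region at the
  event level plus the same noise.
* **Expression** has linear age effects and additive brain-region shifts on
  every gene, plus a planted module sharing a latent factor with the target
  gene through a Gaussian copula: latent Pearson r = 2 sin(pi * rho / 6)
  yields the requested Spearman rho (default 0.8, 40 module genes, 500
  background genes, 200 samples).
* **Phenotypes** are independent Bernoulli draws per phenotype per group
  with NA masking at a configurable missingness rate.

What the generator does **not** emulate: mutation-rate heterogeneity beyond
the 3-mer context (no CpG-methylation or 7-mer effects, no regional
divergence scaling), sequencing/calling artifacts and coverage-dependent
DNV sensitivity, sibling or parental genotypes, linkage between regions,
correlated phenotypes, or heavy-tailed expression noise. Passing tests
demonstrate the statistical machinery is correct under its stated model,
not that the model captures every property of real cohort data.

The ranking-power study (one gamma = 20 region among 20, discovery +
replication pooled) was sized by a pre-registered power analysis: at 2-3 kbp
regions the enriched region's pooled Lambda is ~5-8, giving a predicted
~98-99% chance of uniquely topping the combined ranking; at the length of
the motivating 1.1-kbp enhancer the same gamma yields Lambda ~1.5 and no
method could rank it first 95% of the time (the probability of drawing at
most one DNV alone is 0.57).

## Copy-number classification

Mean copy number over a region is the unweighted arithmetic mean of all
overlapping windows (bedtools-map `mean` semantics: any overlap counts, no
length pro-rating). Calls use strict thresholds: deletion below 1.3 copies,
duplication above 2.7, the boundary values themselves being normal — a
literal reading of the thresholds as published. A `min_windows` guard
(default 1) rejects calls from too few windows.

## Promoters and enrichment

Promoters are the 5-kbp strand-aware upstream flank of each TSS, clamped at
contig edges. Geneset enrichment builds the 2x2 table over a declared gene
universe and applies a one-sided (greater) Fisher test. Odds ratios are
reported in both conventions — the sample OR (a*d)/(b*c), infinite on zero
cells, and the conditional-MLE OR from the noncentral hypergeometric model
— because published ORs alongside Fisher p-values usually derive from the
latter.

## Phenotype comparisons

Phenotype tables use `+` / `-` / `NA` codes; individuals missing an
assessment are excluded per phenotype, never globally. Comparisons are
one-sided Fisher tests on present/absent counts. The symptom count per
individual is (#neurological present) + (#other diagnoses present) + 1 if
at least one craniofacial abnormality is present; missing entries
contribute nothing.

The published coding-vs-enhancer comparison table is not redistributable,
so a synthetic reconstruction (built in code, labelled synthetic) encodes
the reported margins: 20 coding vs 3 enhancer probands; ID/GDD present in
all 17 assessed coding probands and absent in all 3 enhancer probands
(one-sided p = 1/C(20,17) = 8.77e-4); autism in 3/3 enhancer vs 2/17
assessed coding probands (p = 10/C(20,3) = 8.77e-3); two coding probands
missing the ataxia assessment. Individual-level assignments beyond these
margins are arbitrary.

## Co-expression screen

The screen is regression-first: each gene is residualized by OLS on numeric
age plus one-hot brain region (reference level dropped; rank-deficient
designs are rejected naming the collinear columns), then Spearman
correlation (midrank ties) is computed between every gene's residuals and
the target's. Genes with zero residual variance are excluded and reported.
Selection is strict: |rho| > 0.6. Survivors are clustered agglomeratively
with average linkage on the signed distance 1 - rho, which keeps
anti-correlated genes maximally distant so a 2-cut separates the positively
from the negatively correlated groups; scipy's deterministic lowest-index
merge ordering makes results reproducible given input order. Expression
cutoffs for calling a gene expressed are strict (> 2 on the declared
scale).

## Problem sizes and tolerances in the validation studies

The validation studies use: 250 randomized grids (2-12 entries, ~870
comparisons in the p range [1e-8, 0.5]) for saddlepoint/exact agreement;
100 uniform-weight grids for the Poisson reduction (tolerance 1e-10); 40
regions x 50 replicates = 2000 region-tests for calibration; 100 replicates
of the 20-region screen for ranking power; 150 sample-region pairs with 4
planted CNVs for copy-number recovery; one 540-gene x 200-sample matrix for
module recovery; and 1000 random 2x2 tables (counts < 30) against an
exact-rational hypergeometric oracle (tolerance 1e-12). All studies are
seeded and re-derive every number at run time.

## Known limitations

* The rate table is an input; no estimation from data, no 7-mer or
  CpG-aware models, and no regional scaling are provided.
* The unconditional Poisson null is primary; the conditional variant is
  exposed but enumeration-guarded to small observed counts.
* The exact route requires lattice-representable weights; truly irrational
  weight patterns fall back to the saddlepoint/Monte-Carlo pair.
* Fisher tests are unadjusted for covariates by design; no
  logistic-regression burden modelling.
* No liftover, VCF parsing, or read-level simulation.
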
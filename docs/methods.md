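# Methods

This note records the statistical conventions the package implements, the
defaults it ships, the choices that were genuinely open, and what its tests
do and do not establish.

## Catalog filtering and LD pruning

An association survives filtering when its *P*-value is strictly below the
genome-wide threshold (default 5×10⁻⁸), its risk allele frequency (RAF) is
numeric and in [0, 1], its study matches the requested ancestry, and its
phenotype counts as a disease. Ancestry is inferred by case-insensitive
keyword search ("european" by default) in the initial-sample-size
description — the same inspection a curator performs — and the
disease/trait distinction is supplied as an explicit allow/deny list,
because that curation is not algorithmic. Filters count removals per
criterion and never raise.

LD blocks are the connected components of the graph joining SNVs of the
same disease with pairwise r² strictly greater than the threshold (default
0.8) — single-linkage transitive closure. This is deterministic and
order-independent; "blockness" is not claimed to match any particular
clumping tool. Each block is represented by its lowest-*P* member (ties by
lexicographic SNV id), whose RAF represents the block. Pairs absent from
the LD table are treated as unlinked (r² = 0), so partial tables degrade
gracefully. Pruning is exposed as an optional stage: the enrichment
machinery accepts either the full association set or the pruned block set,
and a `unique_snvs` flag additionally collapses SNVs reported for several
diseases to their most significant association, since published tallies
are ambiguous between the two conventions.

## Risk-allele classification and MAF bins

A risk allele is *minor* when RAF < 0.5 and *major* when RAF > 0.5. A RAF
of exactly 0.5 (or a missing one) is *ambiguous* and excluded from
minor/major tallies with a reported count — the partition is defined only
away from 0.5. MAF = min(RAF, 1 − RAF) is binned into five equal intervals
(0–0.1), …, (0.4–0.5), half-open [lower, upper) with the last bin closed
at 0.5 so every polymorphic record lands in exactly one bin. A MAF of
exactly 0 is monomorphic, cannot carry an association, and is excluded
with a logged count. Boundary values carry a 10⁻¹² guard against the
one-ulp float representation error of decimals like 0.3.

## Exact binomial machinery

The two-sided binomial test uses the minimum-likelihood rule — the sum of
P(X = j) over all outcomes no more likely than the observed one — which is
the convention of R's `binom.test` and scipy's `binomtest`, and coincides
with tail-doubling at p₀ = 0.5. Intervals are Clopper–Pearson from beta
quantiles. Empty bins report missing statistics, never 0 or 1. The per-bin
significance level is Bonferroni-corrected, 0.05/5 = 0.01 by default.

## Penetrance simulation

Given baseline penetrance d₁ and per-allele odds ratio r, the heterozygote
and homozygote penetrances are chained so that adjacent genotype classes
differ by exactly r on the odds scale. Genotypes are indexed by risk-allele
count; with risk-allele frequency q their HWE weights are (1−q)², 2q(1−q),
q². Case proportions weight each genotype by its penetrance, control
proportions by its complement. Expected counts round half-to-even per cell
(cell sums may differ from the nominal cohort size by one and are used
as-is). The logistic fit regresses disease status on allele dose (0/1/2)
**with an intercept** — an interceptless model cannot represent the
baseline penetrance the generator uses — on the grouped table, which is
identical to the fit on expanded per-individual data. The default test is
the Wald z-test on the dose coefficient; a likelihood-ratio variant is
available. Degenerate tables (empty arm, constant dose, perfect
separation) return a flagged result with P = 1 rather than raising, and
are excluded (with a count) from curve integration.

S′ compares the minor-risk and major-risk scenarios over the MAF grid
0.05…0.50 (step 0.05): with A the trapezoidal integral of −log₁₀ P over
the grid, S′ = (A_minor − A_major)/A_minor. This is zero for identical
curves, 0.5 when the minor-risk curve is uniformly twice as deep, and
positive whenever minor-risk P-values are systematically smaller. Other
normalizations of the same area gap are possible; this one is adopted for
its sign-correctness and scale-invariance. P-values are floored at
10⁻³²⁰ before logs. Default sweep grids: d₁ from 0.01 to 0.25 (step 0.01)
by r from 1.06 to 2.00 (step 0.01) at 1000 cases/1000 controls; and
controls from 200 to 1800 (step 100) at total cohort 2000, d₁ = 0.03. The
full grids cost ~50,000 logistic fits (about a minute per thousand on one
core); tests and routine checks use thinned grids of the same ranges,
which preserve the monotone-in-r behavior and the weak-effect regions.

**Near-ties and rounding.** On the exact expected tables the minor-risk
P-value never exceeds the major-risk one (no violations in 1000 random
parameter draws). Rounding expected counts to integers perturbs each cell
by up to half a count, which can flip the ordering when the two scenarios
are nearly tied (~2% of random draws; always near-ties). The dominance
property is therefore asserted on exact tables (`round_counts=False`),
while the default chain keeps the rounding convention; a dedicated test
documents that every rounded-chain violation is an exact-chain near-tie.

## One-stage power

For multiplicative (RRs 1, r, r²) and additive (1, r, 2r−1; additivity on
the penetrance scale) models, power is that of the allele-count
two-proportion z-test: baseline penetrance f₀ solved from prevalence,
expected risk-allele frequencies in cases/controls, variance under the
alternative, two-sided α. This formulation reproduces every published
multiplicative worked value checked to printed precision. Dominant and
recessive models collapse genotypes to carrier/non-carrier and apply the
same computation to individuals; published dominant/recessive values are
matched only approximately (within a few points), so the package documents
this convention as its own rather than claiming equivalence with any
specific online calculator.

The power-imbalance correction represents each MAF bin by its midpoint
frequency (0.05, …, 0.45) and its mirror for the major allele, computes
y_minor and y_major, and retests the observed minor count against
expected = y_minor/(y_minor + y_major) with the same exact binomial test;
the reported interval is the Clopper–Pearson interval of the observed
proportion. At a 0.5 expected proportion the corrected test reduces to the
original one.

The Monte-Carlo oracle (`synthetic.empirical_power`) samples genotype
tables from the case/control distributions and thresholds the allele-
frequency gap. Its `variance="design"` mode uses the standard error at the
true frequencies — exactly the event whose probability the analytic
formula computes — and agrees within Monte-Carlo noise. The
`variance="plugin"` mode uses the per-replicate estimated standard error
(the test as actually run); for small unbalanced cohorts such as 190/1064
its rejection rate sits ~0.01 below the analytic approximation, a known
small-sample limitation of the normal-approximation power formula.

## Synthetic data

The catalog generator draws, per disease, a Poisson number of SNVs (mean
11.7 over 280 diseases by default, echoing the scale of a filtered public
catalog); each SNV gets a MAF bin (weights proportional to the observed
bin occupancies 476:616:698:723:771), a MAF uniform within the bin (a
monotone-decreasing alternative is available for realism checks), a
minor-risk indicator Bernoulli(π_b) with defaults (0.79, 0.63, 0.60, 0.61,
0.59) echoing the observed per-bin fractions, and a log-uniform
genome-wide-significant P-value. Contaminants — invalid RAF strings,
non-European studies, sub-threshold P-values, non-disease traits — are
injected at fractions 0.08/0.28/0.10/0.05 (the ancestry fraction matches
the share of non-European associations in public catalogs; the others are
round numbers of the right order) such that the default filter removes
exactly the contaminated rows. The generator emits ground truth (bin,
risk-class, contaminant reason) alongside, and the disease allowlist used
for trait filtering.

What the generator does *not* emulate: realistic LD decay, array
ascertainment, population structure, effect-size/frequency correlation, or
the discoverability bias against very rare alleles. Passing recovery tests
therefore shows the pipeline is faithful to its inputs, not that real
catalogs satisfy the generator's assumptions.

## Problem sizes in routine checks

The test suite runs the dominance property at 200 random parameter draws
(1000/1000 cohorts), the S′ checks on thinned 6×5 and corner grids, the
Monte-Carlo power comparison at 20,000 replicates for three designs, and
synthetic-catalog recovery at ~10,000 SNVs — sizes chosen to pin each
property with comfortable statistical margin on a single core.

## Known limitations

- The dominant/recessive power convention is approximate (see above).
- The corrected-test interval convention (Clopper–Pearson of the observed
  proportion) is one of several possible; it does not depend on the
  expected proportion.
- The deterministic simulator speaks to expected tables; cohort-to-cohort
  sampling variability enters only through the Monte-Carlo oracle.
- Headline fractions from real catalogs (e.g. what share of all reported
  risk alleles are minor) require the external catalog itself and are out
  of scope; the package supplies the machinery, not the data.
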
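# riskallele

Are the risk alleles reported by genome-wide association studies (GWAS)
more often the *minor* allele at their locus than the major one — and if
so, how much of that asymmetry is an artifact of the studies' statistical
power rather than biology (e.g. purifying selection keeping risk alleles
rare)?

`riskallele` is a Python package for analysts of GWAS catalog data who want
to quantify this frequency asymmetry honestly. It provides:

- **Catalog handling** — parsing of NHGRI-EBI-dialect association TSVs,
  genome-wide-significance / risk-allele-frequency / ancestry / disease
  filtering, and LD-block pruning (single-linkage blocks at pairwise
  r² > 0.8, each represented by its lowest-*P* SNV).
- **Enrichment model** — `MinorAlleleEnrichment`, a statsmodels-style model
  whose `fit()` bins SNVs into five equal MAF intervals (0–0.1 … 0.4–0.5)
  and tests each bin's minor-risk fraction with the exact minimum-likelihood
  two-sided binomial test, Clopper–Pearson 95% intervals, and a Bonferroni
  level of 0.05/5.
- **Detectability simulation** — a deterministic penetrance-model pipeline
  (HWE genotype frequencies → case/control genotype distributions →
  rounded expected counts → logistic regression on allele dose) that
  compares the association *P*-value when the minor versus the major allele
  is the risk allele, and the S′ statistic summarizing the gap over a
  frequency sweep.
- **Power calculator** — one-stage case-control GWAS power for
  multiplicative/additive (allele-count two-proportion test) and
  dominant/recessive (carrier-collapsed) models, given cases, controls,
  prevalence *K*, genotype relative risk and significance level.
- **Power-imbalance correction** — replaces the naive null proportion of
  0.5 with *y*<sub>minor</sub>/(*y*<sub>minor</sub>+*y*<sub>major</sub>),
  the minor fraction expected from detection power alone, and retests.
- **Synthetic data** — seeded generators for catalog-like tables (known
  per-bin minor-risk probabilities π_b, injected contaminants),
  block-structured LD tables, and sampled cohorts, so the whole pipeline is
  testable offline with ground truth.

## The model in brief

For a biallelic locus with risk-allele frequency *q* under Hardy–Weinberg
equilibrium, penetrances for 0/1/2 risk alleles are chained from a baseline
d₁ and a per-allele odds ratio *r*:

    d₂ = d₁r / (1 − d₁ + rd₁),   d₃ = d₂r / (1 − d₂ + rd₂)

Case genotype proportions are ∝ dᵢ·HWEᵢ(q), control proportions
∝ (1 − dᵢ)·HWEᵢ(q). Expected counts are rounded and fitted with
logit P(case) = β₀ + β·dose; the Wald test of β = 0 gives the *P*-value.
S′ = (A_minor − A_major)/A_minor, with A the trapezoidal integral of
−log₁₀*P* over the MAF grid 0.05…0.50.

For power, the baseline penetrance f₀ solves
K = f₀·Σ_g HWE_g(q)·RR_g; expected risk-allele frequencies in cases and
controls follow, and power is Φ(z − z*) + Φ(−z − z*) for the two-proportion
z statistic with variance under the alternative and z* = Φ⁻¹(1 − α/2).

## Worked example

The myopia-style design (190 cases, 1064 controls, prevalence 0.25,
genotype relative risk 1.6, α = 5×10⁻⁸) applied to a catalog of 31 SNVs of
which all 18 in the rarest MAF bin have minor risk alleles:

```python
from riskallele import AssociationRecord, MinorAlleleEnrichment, STUDIES

rafs = [0.05]*18 + [0.15]*3 + [0.85]*3 + [0.25]*2 + [0.75]*2 + [0.65]*2 + [0.55]
records = [
    AssociationRecord(snv_id=f"rs{i:04d}", disease="myopia", risk_allele="A",
                      risk_allele_frequency=raf, p_value=1e-9)
    for i, raf in enumerate(rafs)
]
print(MinorAlleleEnrichment(records).fit(power_spec=STUDIES["myopia"]).summary())
```

```
Minor-allele enrichment by MAF bin
==================================
records: 31   ambiguous (RAF missing or 0.5): 0   monomorphic: 0
null: proportion = 0.5   Bonferroni level: 0.01
power-corrected null: 190 cases / 1064 controls, K=0.25, GRR=1.6, alpha=5e-08, multiplicative

  maf_bin  n_total  n_minor_risk  proportion  ci_lower  ci_upper   p_value  significant  power_minor  power_major  expected_prop  p_corrected  significant_corrected
  (0-0.1)       18            18           1    0.8147         1 7.629e-06         True     0.001948    0.0009661         0.6685     0.001514                   True
(0.1-0.2)        6             3         0.5    0.1181    0.8819         1        False      0.09988      0.05981         0.6255        0.678                  False
(0.2-0.3)        4             2         0.5   0.06759    0.9324         1        False       0.3307       0.2494         0.5701            1                  False
(0.3-0.4)        2             0           0         0    0.8419       0.5        False       0.5088       0.4459         0.5329       0.2182                  False
(0.4-0.5)        1             0           0         0     0.975         1        False        0.581       0.5594         0.5095       0.4905                  False
```

Reading the first row: 18/18 minor-risk SNVs rejects a fair-coin null at
*P* = 7.6×10⁻⁶; the design's power imbalance alone predicts a minor
fraction of 0.67, and the observed excess is still significant against that
corrected null (*P* = 0.0015) at the Bonferroni level 0.01 — so detection
bias does not explain the excess in the rarest bin.

A CLI mirrors the library (`riskallele synth | filter | prune | enrich |
simulate | power | correct | run`), e.g.:

```
riskallele power --study alzheimers_late_onset --raf 0.05 --raf 0.10 --raf 0.90
0.05    0.325827
0.1     0.921531
0.9     0.878198
```

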
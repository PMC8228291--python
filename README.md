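# tierdx

Diagnostic yield and cost-effectiveness of tiered ("dynamic") genetic-testing
pathways, for clinical geneticists and health-economics analysts evaluating
stepwise exome-based workups.

## The problem

In unexplained epilepsy with comorbid neurodevelopmental disorders (NDD) or
developmental and epileptic encephalopathy (DEE), a common workup sequences
the proband's exome once and then interprets it through successively wider
*virtual gene panels*: a first curated panel, a broader reanalysis panel for
inconclusive cases, and finally the unrestricted exome. Two questions follow:

1. **Does each reanalysis tier add diagnoses?** Each proband carries the tier
   at which a molecular diagnosis was first achieved (or none). Under the
   monotone-diagnosis assumption — a patient diagnosed by a narrow panel would
   also be diagnosed by any wider one — the tier indicators are *k* paired
   binary outcomes on the same *n* subjects. The omnibus comparison is
   Cochran's Q,

   Q = (k−1) · [k·Σⱼ Cⱼ² − (Σⱼ Cⱼ)²] / [k·Σᵢ Rᵢ − Σᵢ Rᵢ²] ~ χ²(k−1),

   with column sums Cⱼ and row sums Rᵢ of the marginal indicator matrix, and
   the post-hoc pairwise comparison is McNemar's test on the discordant
   counts *b*, *c*: χ² = (b−c)²/(b+c) on 1 df, no continuity correction.

2. **What does each diagnosis cost?** Each performed NGS analysis is
   reimbursed at a single public tariff *c* (default 2072.74 €). Three
   strategies are costed on the same cohort: the two-step panels reference,
   panels followed by a separately reimbursed exome (Model 1), and
   exome-first with free in-silico reanalysis (Model 2). Strategies are
   compared by cost per diagnosis and by the incremental cost-effectiveness
   ratio ICER = Δcost/Δdiagnoses; uncertainty comes from a patient-level
   bootstrap whose (Δdiagnoses, Δcost) replicates are plotted on the
   cost-effectiveness plane, where the lower-right quadrant (more diagnoses,
   lower cost) is dominant.

A bundled cohort of 72 probands (21 diagnosed at tier 1, 4 at tier 2, 2 at
tier 3, 45 undiagnosed, with gene and genotype annotations) exercises the
whole pipeline, and a seeded multinomial simulator generates synthetic
cohorts of the same form.

## Worked example

```python
import tierdx

cohort = tierdx.epilepsy_ndd_cohort()          # n = 72
analysis = tierdx.DiagnosticPathwayAnalysis(cohort)  # k=3, 2072.74 EUR, alpha=0.05
results = analysis.fit(n_replicates=500, seed=1)
print(results.summary())
```

prints (abridged):

```
Diagnostic yield
  overall: 27/72 (37.5%)
  tier1: 21/72 (29.2%)   cumulative 21/72 (29.2%)
  tier2: 4/72 (5.6%)   cumulative 25/72 (34.7%)
  tier3: 2/72 (2.8%)   cumulative 27/72 (37.5%)
Paired-proportion tests (marginal tier indicators)
  Cochran's Q = 24.222 (df=2), p = <0.001
  McNemar tiers 1 vs 2: b=21, c=4, chi2 = 11.560, p = 0.001 *
  McNemar tiers 1 vs 3: b=21, c=2, chi2 = 15.696, p = <0.001 *
  McNemar tiers 2 vs 3: b=4, c=2, chi2 = 0.667, p = 0.414
Pathway costs
  two-step-panels: 123 tests, total 254,947.02 EUR, 25 diagnoses, 10,197.88 EUR per diagnosis
  panels-then-exome: 170 tests, total 352,365.80 EUR, 27 diagnoses, 13,050.59 EUR per diagnosis
  exome-first: 72 tests, total 149,237.28 EUR, 27 diagnoses, 5,527.31 EUR per diagnosis
Incremental vs two-step-panels
  panels-then-exome: delta cost +97,418.78 EUR, delta diagnoses +2; ICER 48,709.39 EUR per additional diagnosis
  exome-first: delta cost -105,709.74 EUR, delta diagnoses +2; dominant (no fewer diagnoses at no greater cost)
```

Read: reanalysis tiers add significantly to the 29% first-panel yield
(overall 37.5%), and sequencing the exome first is *dominant* — two more
diagnoses than the panel-only reference while saving 105,709.74 € on the
cohort. In the bootstrap, every replicate of the exome-first strategy lands
in the cost-saving half-plane.

The same analysis from the shell:

```sh
tierdx run --fixture --seed 1 --outdir out --figure   # full bundle + CE-plane PNG
tierdx fixture -o cohort.tsv                          # dump the bundled cohort
tierdx simulate -n 500 --probs 0.29,0.06,0.03,0.62 --seed 7 -o sim.tsv
tierdx plane --points out/bootstrap_points.csv -o plane.svg
```

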
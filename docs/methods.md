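# Methods

## Data model and assumptions

The unit of analysis is the proband, reduced to a single categorical
outcome: the tier of a k-step genetic workup at which a molecular diagnosis
was first achieved (1..k), or 0 for no diagnosis. Undiagnosed is an explicit
value, not a missing one, so cohort TSVs round-trip without sentinel
ambiguity. Variant-level information (gene, genotype class, HGVS strings in
the bundled cohort's annotations) is opaque text: the package does not
validate HGVS grammar, model pathogenicity, or touch sequencing data.

Everything downstream rests on the **monotone-diagnosis assumption**: a
patient diagnosed by an earlier, narrower tier would also have been
diagnosed by any later, more inclusive tier. This is what licenses
evaluating every tier's yield on the full cohort of n subjects rather than
on the shrinking pool of still-undiagnosed patients, and it is encoded as
the running row-wise maximum of the marginal indicator matrix (the
cumulative indicators are monotone along tiers for every patient, by
construction). It is an assumption, not an observation: a wider panel could
in principle bury a true positive in interpretation noise, and nothing in
the data can check this.

## Paired-proportion tests

With marginal indicator matrix M (n×k, entry 1 iff patient i was first
diagnosed at tier j; every row sums to at most 1), the omnibus test is
Cochran's Q with column sums C and row sums R,

    Q = (k-1) [k ΣC² - (ΣC)²] / [k ΣR - ΣR²],  p = P(χ²(k-1) ≥ Q).

A matrix whose rows are all concordant has a zero denominator; the
implementation returns Q=0, p=1 with a logged warning instead of raising, so
bootstrap replicates stay total. Post-hoc pairwise comparisons use McNemar's
test on the **marginal** indicators (diagnosed *at* tier j), not the
cumulative ones: the pairwise question is "do the tiers contribute equally",
and only the marginal form treats the two tiers symmetrically. The statistic
is the uncorrected (b-c)²/(b+c) on 1 df. Both choices matter numerically:
on the bundled cohort, tiers 2 vs 3 give b=4, c=2 and p=0.414, whereas
cumulative indicators would give b=2, c=0 (p≈0.157) and the
continuity-corrected statistic would give p≈0.683. Asymptotic chi-square
tails are used even at small discordant counts, which is the convention this
kind of retrospective yield analysis follows in practice; an exact binomial
variant (`mcnemar_test(..., exact=True)`) is available but is not the
default. When b+c=0 the test returns statistic 0 and p=1. No
multiple-testing correction is applied across the pairwise tests, and no
confidence intervals are attached to yields. The significance level defaults
to α=0.05.

For k=2, Q reduces algebraically to the uncorrected McNemar statistic; the
suite checks this identity on random matrices, checks both tests against the
statsmodels implementations, and checks the chi-square tail against direct
numerical integration of the density.

## Cost model

Every performed NGS analysis is reimbursed at one tariff (default
2072.74 EUR, the regional public tariff per NGS analysis regardless of
technique; per-tier overrides are possible through `TierDefinition`). A
pathway is an ordered list of tiers with disjoint detection sets; each
patient undergoes tiers in order and exits after the first tier whose
cumulative detection set contains their diagnostic level; patients whose
level is never covered — including all undiagnosed — undergo every tier.
The three standard strategies for k=3:

* **two-step-panels** (reference): panel detecting level 1, then panel
  detecting level 2; two reimbursable acts, tier-3-only diagnoses missed.
* **panels-then-exome** (Model 1): the two panels plus exome sequencing as a
  third, separately reimbursed act.
* **exome-first** (Model 2): one reimbursed exome whose virtual panels are
  reapplied in silico, so reanalysis is free and all levels are detected for
  a single tariff. Its total cost is therefore always n × unit_cost.

Money is kept as unrounded floating-point euros internally; display rounds
half-up to cents (`round_eur`). Cost per diagnosis with zero diagnoses is an
explicit `None`, not infinity, so replicate results serialise cleanly. The
incremental comparison reports Δcost, Δdiagnoses and the ICER
Δcost/Δdiagnoses; a strategy with Δdiagnoses ≥ 0 and Δcost ≤ 0 (not both
zero) is flagged dominant and its ICER suppressed, since a negative ratio is
meaningless on the CE plane. Out of scope by design: discounting, QALYs,
downstream-care offsets, and pre-NGS workup costs — the model prices the
NGS reimbursement only.

## Bootstrap cost-effectiveness plane

Uncertainty is assessed by a nonparametric bootstrap whose resampling unit
is the **patient**: the whole outcome vector is resampled with replacement,
preserving the within-patient pairing across tiers (resampling tier
indicators independently would destroy it). In each of B replicates
(default B=500) the reference and every comparator are costed on the *same*
resampled cohort, so each replicate yields properly paired (Δdiagnoses,
Δcost) points. Points are classified by sign into the four CE-plane
quadrants, with any zero coordinate labelled `axis`; summaries report
quadrant proportions, means, nearest-rank 2.5/97.5 percentiles (no
interpolation, so intervals are reproducible order statistics), and the
dominance proportion. A single seedable generator owned by the call drives
all resampling; the default seed (2021) is a documented constant and every
entry point accepts an override. Replicate clouds from other software will
differ point-by-point (bootstrap seeds are implementation-specific); the
structural properties — both strategies in the right half-plane,
exome-first in the cost-saving half-plane — are the reproducible content.
On the bundled cohort these are not merely empirical: Δdiagnoses equals the
count of resampled tier-3 patients (≥ 0 always), Model 1's Δcost is
unit_cost × (n − n₁ − n₂) ≥ 0, and Model 2's is unit_cost × (n₁ − n) ≤ 0,
strict unless a resample contains only tier-1 patients (probability
(21/72)⁷² ≈ 10⁻³⁹).

## Synthetic cohorts

`simulate_cohort` draws each proband's outcome independently from a
multinomial over (tier 1, …, tier k, none). Its defaults emulate the bundled
cohort's conditions (n=72, probabilities 21/72, 4/72, 2/72, 45/72 when the
caller passes them); identical specs reproduce identical cohorts
bit-for-bit. The simulator reproduces exactly the structure the analysis
consumes — independent probands with a categorical tier-of-diagnosis — and
nothing else: no covariates, no family structure, no correlation between
diagnosis tier and phenotype, no secular drift in panel content. Passing
tests on simulated cohorts therefore validates the arithmetic and the
contracts, not the clinical realism of any particular cohort.

## Numerical and design choices

* Yields are exact rational counts divided by n; the percent formatter
  supports both half-up rounding and truncation at a chosen precision
  because published summaries of this kind mix the two conventions (5.555…%
  shown as 5.5, 2.777…% shown as 3); raw proportions are always carried
  alongside the formatted strings.
* p-values are displayed rounded to 3 decimals, as `<0.001` only when the
  rounded value would be 0.000.
* k defaults to 3 everywhere but is a parameter: `standard_pathways(k)`
  builds k−1 panel steps plus the exome variants, so the engine generalises
  to other tier counts.
* Validation errors carry the offending row/field; degenerate statistical
  inputs (no discordance, zero diagnoses) return defined values rather than
  raising, so that bootstrap replicates and simulated cohorts never abort a
  run.
* Report bundles contain no timestamps and use sorted JSON keys and fixed
  column orders: two runs with the same configuration are byte-identical
  (figures excepted).

## Problem sizes

The bundled cohort (n=72, k=3) makes every deterministic quantity instant;
the default bootstrap (B=500) takes well under a second. The simulator's
law-of-large-numbers checks use n=7,200 (3 SE band) and n=100,000 (4 SE
band), sizes at which the binomial standard error is small enough for the
checks to be sharp while the whole suite stays in seconds.

## Limitations

* The monotone-diagnosis assumption is untestable from the outcome data.
* Costs are a single payer's reimbursement tariff; no societal perspective.
* Asymptotic tests at small discordant counts are a convention, not an
  endorsement; use the exact variant when counts are very small.
* The bundled cohort's undiagnosed records carry no demographic annotations
  (ages and sexes were not recorded for them), so any covariate-level use of
  the fixture is restricted to the 27 diagnosed probands.
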
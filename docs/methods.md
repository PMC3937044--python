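# Methods

This note documents the statistical model behind `famhx`, the defaults
it ships with, and the choices made where the design was genuinely open.

## Pedigree model

Pedigrees are *relation-coded*: each relative carries a label from a
20-code vocabulary describing their relationship to the proband, and no
explicit parent–child links are stored.  Degree of relatedness,
generation offset and lineage are pure functions of the code.  This is
how patient-facing FHH tools collect data, and it is sufficient for
every statistic the package computes; explicit links are synthesized
only for the linkage-PED export, with placeholder founders for
structural parents that have no row of their own (an aunt's spouse, the
parents of a niece when no sibling is listed).

Conventions where the vocabulary under-determines the mapping:
half-siblings are second degree and cousins third degree (standard
kinship coefficients 1/4 and 1/8); full and half siblings are assigned
lineage `both` (an unqualified half-sibling code cannot say which side);
descendants and unqualified cousins have lineage `not_applicable`.
Unknown gender is representable — digitally collected pedigrees always
have gender, but chart-review-style records do not, and the gender
criterion must be able to fail.

## Quality scoring

Seven completeness criteria are scored per pedigree.  The two
death-related criteria are *not applicable* (None, excluded from both
numerator and denominator) in pedigrees without a deceased relative, so
criterion percentages for cause/age of death are quoted out of
deceased-containing pedigrees.

The per-relative high-quality rule uses **vacuous satisfaction**: a
criterion that does not apply to a relative (onset for the unaffected,
death fields for the living) counts as met, so an unaffected living
relative with reported data and known gender is high quality.  This is
the only reading under which near-universal high-quality pedigree rates
can coexist with pedigree-level onset reporting near 70%, and it matches
the intent of the rule — the pedigree must contain at least one relative
whose record is complete *for them*.  The onset criterion is count-once:
one onset age among several diseases suffices.  Criteria C2–C7 and the
high-quality rule are evaluated over relatives only; including the
proband's complete self-report would make the rule vacuous at the
pedigree level.

Pertinent negatives (C4) are a property of the record *format*: the
criterion is met when the record distinguishes "unaffected with data"
from "no data", inferred as "some unaffected relative has data
reported".  For inputs where that inference is wrong (e.g. chart-review
records that never note negatives) a per-pedigree boolean override is
provided.

The onset-reporting proportion defaults to affected relatives as its
denominator (the criterion concerns onset *in affected relatives*); an
all-relatives denominator is available by configuration and every output
names the denominator used.

## Aggregation semantics

Every cohort statistic declares `by_proband` (compute within pedigree,
then summarize the distribution across pedigrees) or `by_individual`
(pool persons).  The two collapse to the same number when all pedigrees
have equal within-pedigree denominators, which the tests exploit.
No-data relatives always sit in denominators and never in numerators;
they cannot be distinguished from healthy-but-unreported relatives, which
is precisely why they are tracked as their own category rather than
counted as unaffected *reports*.

## Sibling recurrence-risk ratio

For disease *d*, `lambda_s = P(sib affected | proband affected) / p`
where *p* is prevalence among eligible probands (the enrolled population
is the reference).  The numerator pools full siblings (`sister`,
`brother`; half-siblings excluded) of affected probands.  For diseases
conventionally restricted to one sex (breast, ovarian cancer) the
estimator can restrict both the proband denominator and the sibling pool
to the susceptible sex; this is configurable off.

The CI method is a percentile bootstrap resampling *pedigrees* with
replacement — distribution-free, respects within-family dependence, and
naturally truncates at the zero lower bound that a ratio of rates
requires.  Default 2,000 resamples; resamples in which the ratio is
undefined (no affected probands or no siblings drawn) are dropped.
Degenerate inputs (no eligible probands, zero prevalence, no siblings)
yield a flagged undefined estimate, never an exception.  The point
estimate depends only on pooled counts, hence is invariant to pedigree
order and to the bootstrap seed.

## Synthetic cohort generator

The generator's purpose is to emulate the statistical structure of a
primary-care FHH cohort so the whole pipeline can be exercised and its
estimators validated by parameter recovery.

* **Sizes and structure.**  Pedigree size is a discretized log-normal
  (median 21, sigma 0.35) clipped to [8, 71].  Every pedigree has a
  fixed skeleton — proband, both parents, four grandparents — and the
  remainder is multinomial over siblings, aunts/uncles, children,
  nieces/nephews and grandchildren (weights 0.25/0.35/0.25/0.10/0.05;
  family-composition distributions are not reported for such cohorts, so
  these are a documented arbitrary default).
* **Familial clustering.**  A two-point family frailty: with probability
  `1/lambda` the family is at risk and each member is independently
  affected with probability `lambda * p`; otherwise nobody is.  Then the
  marginal prevalence is exactly `p` and the induced recurrence-risk
  ratio between any two members — siblings in particular — is exactly
  `lambda`.  The calibration is closed-form and feasible iff
  `lambda >= 1` and `lambda * p <= 1`; infeasible disease entries are
  rejected by name.  A liability-threshold model would be more
  biological but does not admit exact closed-form calibration; the
  analysis needs asserted lambdas, not a genetic mechanism.
* **Disease table defaults** carry the cohort-style prevalences
  (breast 4.71% of females, colon 1.37%, diabetes 6.36%, heart attack
  8.76%, ...) with recurrence ratios 2.61 (breast), 27.86 (colon), 5.89
  (heart attack), 2.49 (diabetes); for the remaining diseases no cohort
  estimate exists and field-typical values are used once (ovarian 3,
  hereditary cancer syndromes 5, thrombosis/asthma/dementia 2).
  "Heart attack" and "heart disease" are distinct labels and never
  merged.
* **Mortality** rises with ancestral generation (0.97 grandparents, 0.65
  parents' generation, 0.22 proband's, 0.03/0.01 below), giving ~43–45%
  deceased overall.
* **Missing data.**  Per-relative no-data probability by stratum
  (FDR 0.014, non-grandparent SDR 0.13, grandparents 0.22 for probands
  who did not contact relatives), multiplied by 0.46 when the proband
  talked to relatives (~54% do) and by `exp(-0.15 * (knowledge - 4.3))`
  for the proband's self-rated FHH knowledge (Likert 1–7, mean 4.3,
  SD 1.3) — reproducing the observed orderings: grandparents most
  missing, talkers ~5% vs non-talkers ~11%, knowledge negatively
  correlated with missingness.  No-data relatives keep their relation
  code, gender and vital status (family structure is known) but lose all
  health fields, matching the data-model invariants.
* **Field completeness.**  Onset recorded for 30% of affected relatives,
  cause of death for 12% and age of death for 88% of deceased relatives —
  chosen to land pedigree-level criterion rates in the observed regime
  (onset ~72%, cause ~59%, age of death ~98% of deceased-containing
  pedigrees).
* **Covariates** follow the emulated enrollment margins: 58.6% female
  probands, mean age 58.8 (SD 11.8), 81.8%/13.5%/4.7%
  white/black/other, 4-level education.

What the generator does **not** emulate: realistic age-at-onset
epidemiology (onsets are clipped normals per disease), survival
processes behind deceased status, correlation between disease status and
mortality, ascertainment bias in enrollment, and reporting error in
relation codes.  Passing recovery tests therefore demonstrate estimator
correctness under the stated missing-data and clustering mechanisms, not
robustness to misreported pedigrees.

A separate deterministic builder, `make_fixture`, constructs minimal
cohorts hitting exact requested counts (criterion quotas, per-disease
numerators/denominators, female/deceased totals).  It is how the
published-style summary percentages are reproduced exactly:
`STUDY_SUMMARY_COUNTS` bundles the emulated cohort's printed counts and
`study_fixture()` builds that cohort.  Non-high-quality quota pedigrees
are realized as "every relative affected without an onset age" with the
pertinent-negatives override asserted, the only configuration that fails
the high-quality rule while leaving the four structural criteria intact.

## Numerical and reporting choices

* Undefined proportions and ratios are NaN in memory and `null` in JSON;
  they are flags, never exceptions, and never silently zero.
* The subgroup share for onset reporting is quoted out of *all*
  pedigrees, while the death-related subgroup shares are quoted out of
  deceased-containing pedigrees — matching how such tables are
  conventionally printed.
* The high-quality threshold sweep defaults to thresholds 0.00, 0.05,
  ..., 1.00; its value at 0 is exactly 1 and it is monotone
  non-increasing (property-tested).
* Bootstrap seeds are explicit everywhere; the same seed yields
  identical CI endpoints.
* CSV serialization uses empty strings for missing values and integer
  years for ages; the `lineage` column is redundant with the relation
  code and is verified against it on read.

## Test problem sizes

Parameter-recovery tests run 200 generator replicates of 1,600 pedigrees
(three diseases, recurrence ratios 1/2.5/5) with 500 bootstrap resamples
per replicate, checking <10% relative bias of the mean estimate and
>=90% CI coverage; the independence limit and structure checks use
single cohorts of 1,184–1,600 pedigrees.  These sizes give Monte-Carlo
noise comfortably below the asserted tolerances.
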
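# Methods

## Screening model

The package evaluates categorical screening rules for falls occurring
within 14 days of admission to a convalescent rehabilitation ward. A fall
is an event in which a body part other than the soles touches the ground
against the patient's will; each patient contributes one binary outcome
(any fall in the window), not a time-to-event.

Three predictors are modelled, all strictly categorical (no probabilistic
risk scores):

1. **SIDE cutoff.** The SIDE level is an ordinal grade 0 < 1 < 2a < 2b <
   3 < 4 derived from a stop-at-first-failure stance sequence. A cutoff is
   an adjacent boundary on this scale; levels at or below the boundary's
   left side are risk-positive. All five boundaries are evaluated and the
   Youden-maximal one selected; ties break toward higher sensitivity
   (screening favours catching fallers), then toward the lower boundary.
2. **Memory & instruction adherence item**, positive = at risk.
3. **Combined two-stage rule.** Stage 1 removes good-balance patients
   (SIDE above a configurable boundary, default 2b/3) as negative; stage 2
   classifies the rest by the memory item. The two SIDE boundaries — 2a/2b
   for the single-predictor cutoff, 2b/3 for the combined rule's balance
   stage — deliberately coexist and are configured independently.

Missing data are handled by exclusion with an explicit reason, never by
imputation: a not-testable SIDE excludes the patient from any rule that
needs balance (including the combined rule — such patients are not routed
through the adherence stage alone), and a missing memory item excludes
from any rule that needs adherence. The combined rule's exclusion set is
therefore exactly the union of the two single-rule exclusion sets.

## SIDE level assignment

`determine_side_level` is total on structurally valid sub-test outcomes:
each stance is attempted iff the previous one was passed, testing stops at
the first failure (tandem counts as failed only when both leading legs
fail), and a patient with no attempted stance is not testable. Two
readings of the top level were possible where one single-leg stance
succeeds and the other fails; the package assigns level 3 (both legs must
succeed for level 4), mirroring the explicit one-leg/two-leg distinction
between 2b and 3 and preferring the conservative lower grade. Exhaustive
enumeration of the 3^6 outcome lattice (10 valid outcomes) backs the unit
tests; any violation of the stop rule raises an error naming the
inconsistent pair of sub-tests.

## Diagnostic statistics

Sensitivity, specificity and Youden J = Se + Sp − 1 are computed on exact
ratios; rounding (half-up, 2 decimals for proportions, 1 for percentages)
is applied only at the reporting layer, because the printed values this
package reproduces are themselves half-up roundings (e.g. 31/36 → 0.86,
152/362 → 0.42). Two-sided Fisher exact tests use the point-probability
(minimum-likelihood) convention — the sum of hypergeometric probabilities
of all margin-fixed tables no more probable than the observed one — via
`scipy.stats.fisher_exact`; the test suite verifies agreement with an
exact integer-arithmetic enumeration on every 2×2 table with total ≤ 60
(absolute tolerance 1e−12). No confidence intervals are reported and the
ROC is restricted to the five ordinal cutoffs, matching the package's
reporting scope.

## The canonical synthetic cohort

No patient-level data are available, so `build_fixture` constructs a
416-patient cohort that reproduces, exactly, every published marginal
count: the SIDE-by-fall distribution (38 fallers / 378 non-fallers), the
three adherence items by fall group, the management-method breakdown of
the 38 falls with its per-category memory-item positives, the missing-data
cascade (18 not-testable SIDE, 14 missing memory item, 6 both → 390
analyzable), and the background demographics (sex 154/262, six diagnosis
groups, age 77.9 ± 9.6 in 38–102, FIM motor 49.7 ± 19.5, FIM cognitive
25.5 ± 7.5).

The joint distribution of SIDE band × memory item is not printed and the
constraint system is under-determined (the combined rule's true negatives
could be 226 or 227 and still round to 0.64). The fixture fixes the
**tn-maximal canonical solution**: among the 36 analyzable fallers, 27 of
the 35 at SIDE 0–2b are memory-positive and the single level-3 faller is
negative (both not-testable fallers positive); among the 354 analyzable
non-fallers, 127 of 252 at 0–2b are positive and the 102 at 3–4 split
30/72; the 10 not-testable non-fallers with an observed item split 3/7 and
the 8 remaining missing items sit at levels 0–2b. Within a band, per-level
splits are unconstrained by any printed number and are fixed
near-proportionally (e.g. level-0 fallers 9 positive / 3 negative). The
personality and impulsiveness items and the management categories carry no
printed joint information with SIDE, so they are assigned within fall
group in a shuffled order drawn from the fixture's fixed internal stream
(seed 416); the same stream drives demographics. Ages and FIM scores are
truncated normals on the instrument ranges whose *truncated* moments are
calibrated to the printed mean/SD (two ages are pinned to 38 and 102 to
honour the printed range). `verify_fixture` re-derives all of the above
from any cohort and reports pass/fail per constraint; printed moments are
checked to a generator tolerance of 2.5 units, roughly three standard
errors of a 416-sample moment for the widest covariate (FIM motor).

## The stochastic sampler

`sample_cohort` generalises the fixture for simulation: fall status is
Bernoulli at the spec's faller fraction, then SIDE, the three adherence
items and (for fallers) the management category are drawn from the
per-group proportions. A `dependence` parameter d ∈ [−1, 1] tilts the
joint of (poor-balance band 0–2b vs 3–4) × (memory positive) within each
fall group by the odds ratio (1 + d)/(1 − d), solving the Plackett
quadratic so both margins are preserved; d = 0 gives conditional
independence and ±1 the Fréchet bounds. The sampler emulates the margins
and this single association only — it does not model time-to-fall, ward
occupancy, repeated falls, or correlation between adherence items and
demographics, so sampler-based tests demonstrate estimator behaviour under
the stated margins, not realism of full patient trajectories. Every draw
is reproducible from the spec's single integer seed.

Parameter recovery is checked on 500 seeded cohorts of 416 patients (the
study's size): the replicate-mean sensitivity and specificity of both
single-predictor rules must fall within three Monte-Carlo standard errors
of the margin-implied truth. Marginal fidelity is checked at n = 100 000
(conditional cell rates within one percentage point).

## Numerical and design choices

* Sample SD (n − 1) throughout; a single observation reports SD as NaN
  rather than 0.
* Half-up rounding is implemented with `decimal.Decimal` to avoid binary
  float ties; it is never applied before arithmetic.
* CSV serialisation uses lower-case string tokens for every enumeration
  and 0/1 for the fall flag; missing values are explicit `missing` tokens,
  never sentinel numbers. Round-trip identity (write → read) is exact.
* Zero margins (no analyzable fallers or non-fallers) raise errors naming
  the empty margin instead of returning NaN metrics.
* `positivity_by_category` counts a faller with a missing memory item in
  the denominator but not the numerator, with a warning; the canonical
  cohort contains no such faller.

## Known limitations

* The fixture is *a* solution of the published constraint system, not the
  original data; analyses of joint structure beyond the documented closure
  (e.g. SIDE × personality) reflect the generator's arbitrary choices.
* The intermediate 287-patient split (poor-balance analyzable set) is
  reported but its faller composition is fixed only by the fixture's
  construction, as no printed value constrains it.
* Per-cutoff problem sizes, runtimes and all analyses target cohorts of a
  few hundred to ~10^5 records; nothing is optimised for millions of rows.
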
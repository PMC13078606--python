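# Methods

## Triage model

A questionnaire is a directed acyclic graph of multiple-choice questions.
Each answer option names the next question or a terminal marker, optionally
carries *feature tags* (symptom features asserted by choosing it), and may
be a *fast-track* red flag. Sessions are forward-only — no backtracking or
answer revision — and bounded by a hard budget of 25 questions (the
`max_questions` field; configurable). Three red flags are modelled as
fast-track options: recent sight-threatening (chemical or penetrating)
injury, recent sudden loss of vision, and stroke symptoms accompanying a
visual disturbance; choosing one ends the session immediately. Free text is
captured verbatim and passed through to the symptom report unparsed — it is
for the reviewing clinician, never for the algorithm. Eligibility (age ≥ 13
years, symptom onset within 7 days) is a pre-session gate returning a
refusal result, not a questionnaire node.

The compiled `SymptomReport` is the pure function of the answer trace:
presenting concern from the entry answer, features as the union of chosen
options' tags, fast-track flag if any chosen option was a red flag. Replay
of a recorded trace reproduces the live session's report exactly; the test
suite verifies this over all 1,014 root-to-terminal paths of the shipped
questionnaire.

**Disposition.** The acuity chart is a list of rows (feature pattern →
urgency grade, service route). A row fires when its pattern is a subset of
the report's features; among firing rows the most urgent grade wins, and on
an urgency tie the more specialist service (ED > EEC > hospital urgent eye
service > community urgent eye service > optometry > pharmacy). A report
firing no row takes the configured default, grade C routed to the community
urgent eye service — a deliberately conservative middle band for
unclassifiable presentations. Fast-tracked reports bypass the chart:
(A, ED) always. The max-rule makes urgency monotone in the feature set
*among reports that fire at least one row*; an unmatched report's default-C
disposition carries no such guarantee (adding a single low-acuity feature
can legitimately yield D), and the property test is scoped accordingly.

The shipped questionnaire and chart are demonstrative stand-ins, flagged as
synthetic in their configs: the deployed commercial tool's question set and
scoring rules are proprietary and unpublished, so this package is fully
config-driven and ships an instrument whose entry question reproduces the
public four-way presenting-concern filter (red or painful eye; painless
visual disturbance; eye injury; eyelid problem) and whose branches cover
every row of the chart. No clinical validity is claimed for either config.

## Evaluation statistics

*Reference standard.* Two masked ophthalmologist reviewers grade urgency
A–D; on disagreement the more urgent grade is the combined reference. The
urgent dichotomy ("reference-urgent") is grade A or B from **at least one**
reviewer — equivalent to the combined grade's band. The down-rating
analysis instead uses the reviewer **consensus** (urgent only when both
reviewers grade A/B, i.e. the less urgent of the pair): an urgent nurse
disposition counts as down-rated when it is not confirmed urgent by both
reviewers. These are different operationalisations and both are exposed;
the consensus version is what makes a 21-case both-urgent subset the
complement of the down-rated cases.

*Accuracy.* Sensitivity tp/(tp+fn) and specificity tn/(fp+tn) with exact
Clopper–Pearson intervals from Beta quantiles (scipy). Exact intervals were
chosen because they reproduce the benchmark results this package is
validated against and are conservative at the small positive margin
(n = 76) typical of triage validation; Wald and Wilson intervals do not
reproduce those bounds. Degenerate margins (no positives or no negatives)
raise rather than returning NaN.

*Paired comparison.* McNemar with continuity correction,
χ² = (|b−c|−1)²/(b+c) on discordant-pair counts, p from the upper χ²₁ tail.
The statistic is computed exactly as stated — no flooring at |b−c| ≤ 1 —
matching the standard statsmodels implementation, against which it is
cross-checked. The operation takes explicit (b, c) because published
evaluations rarely print discordant counts; the cohort evaluator derives
them from per-patient pairs when those exist.

*Ordinal agreement.* Quadratically weighted Cohen κ on the 4×4
cross-tabulation with grades coded A=1 … D=4, equally spaced; quadratic
weights (i−j)²/(k−1)² encode that a two-band triage miss is
disproportionately worse than a one-band miss. The default 95% CI uses the
large-sample Fleiss–Cohen–Everitt variance (cross-checked to machine
precision against `statsmodels.stats.inter_rater.cohens_kappa`); a seeded
multinomial bootstrap is available because the variance estimator is known
to be optimistic in small, sparse tables. Interpretation bands follow the
conventional closed two-decimal cut-offs (≤ 0 none, 0.01–0.20 none to
slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
0.81–1.00 almost perfect); κ is rounded to 2 dp before banding so the
cut-offs partition the line. A table in which each rater effectively uses a
single category makes expected disagreement zero and raises a
degenerate-marginal error. Percent agreement is computed on the urgent
dichotomy (this is the version consistent with the companion accuracy
analysis; full A–D raw agreement is available via the cross-tab).

*Missing data.* Rows missing a grade are excluded listwise from each
statistic involving that rater; exclusion counts appear in the evaluation
report. Likert and duration summaries use non-missing values only; the
sample SD of a single observation is reported as missing, not 0.

## Cohort simulator

Each patient draws a latent true urgency grade from a 4-vector prevalence;
each rater's assigned grade is drawn independently from the row of that
rater's 4×4 row-stochastic confusion matrix indexed by the latent grade.
Conditional independence of rater errors given the latent grade is an
explicit modelling assumption — real raters saw overlapping information
(the nurse a phone call, the reviewers the same symptom report), so real
error correlations are unknowable from published margins and are not
modelled. Presenting concern, Likert score, duration and outcome flags are
drawn from separate marginal models, independent of the grades.

The study-like configuration encodes a published 282-patient evaluation's
margins as defaults:

| parameter | default | basis |
|---|---|---|
| latent prevalence A–D | (21, 55, 159, 47)/282 | urgent band 76/282 as printed; the A/B and C/D splits are unpublished, chosen once with the A share echoing the 21-case both-urgent subset |
| nurse operating point | sens 0.855, spec 0.228 | printed band-level accuracy |
| tool operating point | sens 0.763, spec 0.641 | printed band-level accuracy |
| concern mix | (0.500, 0.411, 0.064, 0.025) | printed cohort table |
| Likert distribution over 1–5 | (0.004, 0.022, 0.170, 0.368, 0.436) | moment-matched to mean 4.21, SD ≈ 0.82, top-2 mass 0.804; response rate 209/282 |
| duration (minutes) | lognormal, moment-matched to mean 5.6, SD 2.4, redrawn into [0.15, 20.7] | printed summary and range |
| outcome flag probabilities | urgent (0.50, 0.40, 0.50, 0.15), non-urgent (0.12, 0.10, 0.25, 0.01) | chosen to give ≈ 46.5% all-clear visits overall |

The nurse and tool matrices embed the dichotomous operating points as
urgent-band row sums; within-band splits are fixed plausible values. The
two reviewer matrices are **band-faithful** — they never cross the
urgent/non-urgent boundary relative to the latent grade — so the
at-least-one-urgent reference standard recovers the latent band exactly and
the estimated sensitivity/specificity of the other raters converge to their
configured operating points (verified at n = 50,000 to within ±1
percentage point, and via total-variation distance < 0.02 per matrix row at
n = 100,000). This is the feature the simulator is designed to have; it is
also what real reviewers do not guarantee, which is precisely why a
reference standard needs validating. The simulator emulates marginal
structure only: no diagnoses, no symptom-to-grade coupling (concern and
grade are independent), no rater drift, no informative missingness.

## Study-marginal fixture

`fixture_study_cohort()` is a deterministic 282-row table solving the
printed margins jointly: both 2×2 accuracy tables (nurse tp 65, fp 159,
fn 11, tn 47; tool 58, 74, 18, 132), the 76-case reference-urgent margin,
the 21-case both-reviewer-urgent subset (hence 203/224 reviewer
down-rating), the 93/224 tool down-rating, the concern mix, a 131/282
community-care-suitable outcome margin, a 256/282 ESS-route margin, and a
209-response Likert column with mean 4.21 and 168 top-2 ratings. The
three-way dichotomy cell counts follow uniquely (up to one free cell, fixed
at 57 both-urgent-and-reference-urgent cases) from those margins. Grade
letters are schematic — B for urgent and C for non-urgent assignments, plus
the constructed reviewer pairs — because the full A–D frequency
distributions were never published. Two printed quantities are **not**
realised, because they are arithmetically incompatible with the 2×2 tables
under any single grade-combination rule: the over/under-estimation
percentages (a tool false-negative count of 18 forces at least 18
letter-level underestimates against the combined grade, yet 4/282 was
printed; similarly 11 > 9 for the nurse), and the 145/256
"advice-only among ESS-suitable" count (145 > the 131 total advice-only
visits). The over/under operation is therefore validated by its partition
identity and brute-force oracles on random cohorts instead.

## Numerical and interface choices

Percentages are rendered to 1 dp and κ to 2 dp in reports, matching the
precision conventions of the clinical literature. All randomness flows
through a single `numpy.random.Generator` seeded per run; CLI invocations
write a manifest (command, input checksums, seed, version, timestamp) so a
run can be reproduced bit-for-bit. Cohort CSVs are comma-separated UTF-8
with a fixed header; unknown grade letters, out-of-range Likert scores and
non-binary outcome flags are row-level errors carrying line numbers, and a
missing column is fatal. Problem sizes in the shipped analyses — 50,000
simulated patients for operating-point recovery, 2,000 replicates for
interval coverage, 1,000 random tables for the κ oracle — were chosen as
the smallest sizes at which Monte-Carlo error is comfortably below the
tolerances being checked.

## Limitations

The shipped questionnaire/chart pair is a demonstrative instrument, not the
proprietary deployed tool, and no claim of clinical equivalence is made.
The simulator's independence assumptions mean passing recovery tests shows
the *estimators* are correct, not that real rater behaviour is captured.
Published κ point estimates for specific rater pairs are not reproducible
from marginal counts (the per-patient 4×4 tables are unpublished) and are
deliberately not asserted anywhere; the agreement machinery is validated by
oracle identities and cross-implementation checks instead.
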
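# eyetriage

Tools for building and evaluating patient-facing ophthalmic symptom triage.

Emergency eye clinics (EECs) triage referrals by telephone, and nursing
triage tends to be risk-averse: most patients are booked urgently although
only a minority need same-day or next-day assessment, while many could be
managed in commissioned community optometry enhanced service schemes
(ESSs). A digital triage questionnaire that patients complete themselves —
a branching multiple-choice instrument that compiles a symptom report and
suggests an urgency grade and a care setting — can redistribute that load,
provided its diagnostic accuracy against expert judgement is known.

`eyetriage` packages both halves of that problem:

* **Triage engine** (`eyetriage.engine`, `eyetriage.chart`) — a
  config-driven branching questionnaire DAG with red-flag fast-tracking
  (chemical/penetrating injury, sudden vision loss, stroke symptoms end the
  session and route to the emergency department the same day), plus a
  chart-based disposition algorithm mapping compiled symptom reports to an
  urgency grade A–D (same day / 24 h / 48–72 h / within a week) and a
  service route (ED, EEC, hospital or community urgent eye service,
  optometry, pharmacy). A demonstrative questionnaire and acuity chart are
  shipped as JSON configs.
* **Evaluation framework** (`eyetriage.stats`) — the diagnostic-accuracy
  machinery for validating any triage rater against a two-reviewer
  ophthalmologist reference standard.
* **Cohort simulator** (`eyetriage.simulate`) — a latent-urgency generative
  model with per-rater ordinal confusion matrices, so every statistic can
  be exercised against known ground truth without patient data, plus a
  deterministic 282-row fixture cohort reconstructed from a published
  evaluation's printed marginal counts.

## The statistics

With two masked reviewers grading urgency, the reference standard takes the
more urgent grade on disagreement; a case is *reference-urgent* when at
least one reviewer assigns A or B. For a rater's urgent/non-urgent calls
against that dichotomy, sensitivity and specificity are reported with exact
Clopper–Pearson 95% intervals,

&nbsp;&nbsp;CI(x, n) = [ B(α/2; x, n−x+1), B(1−α/2; x+1, n−x) ],

where B(q; a, b) is the Beta quantile, and paired raters are compared with
the continuity-corrected McNemar statistic (|b−c|−1)²/(b+c) on the
discordant-pair counts. Full A–D agreement between rater pairs uses the
quadratically weighted Cohen κ,

&nbsp;&nbsp;κ_w = 1 − Σ w_ij O_ij / Σ w_ij E_ij,&nbsp;&nbsp; w_ij = (i−j)²/(k−1)²,

with a large-sample (Fleiss–Cohen–Everitt) or seeded-bootstrap confidence
interval and the conventional interpretation bands (0.21–0.40 fair,
0.41–0.60 moderate, …). Down-rating (urgent dispositions re-graded C/D by
another rater), over/under-estimation against the combined reviewer grade,
ESS suitability of routed services, and community-care suitability by
clinic outcome (no imaging, tests, prescription or surgery) complete the
service-redistribution analysis.

## Worked example

Emit the fixture cohort (282 rows reconstructed from printed study
margins) and evaluate it:

```
$ triage fixtures --out-dir .
$ triage evaluate --cohort fixture_cohort.csv --out-prefix eval
Triage evaluation report
============================================================
Cohort rows: 282
Reference standard: 76/282 urgent (27.0%)

Accuracy for identifying urgent cases (vs reference standard)
rater   sens % (95% CI)           spec % (95% CI)
nurse   85.5 (75.6-92.5)          22.8 (17.3-29.2)
tool    76.3 (65.2-85.3)          64.1 (57.1-70.6)
Percent agreement (urgent dichotomy): nurse 39.7%, tool 67.4%
...
Down-rating of urgent nurse dispositions
  ophthalmologist_consensus: 203 downrated (90.6%)
  tool: 93 downrated (41.5%)
...
Suggested suitable for community ESS: 256 (90.8%)
Suitable for community care by outcome: 131 (46.5%)
Likert acceptability: mean 4.21 (SD 0.82; n=209), top-2 80.4%
```

Read: nurse triage catches 65 of the 76 reference-urgent cases (85.5%
sensitivity) but marks 159 of 206 non-urgent cases urgent too (22.8%
specificity); the digital tool trades a little sensitivity (76.3%) for far
higher specificity (64.1%), would have safely down-rated 41.5% of the
urgent nursing dispositions, and routes 90.8% of patients to services a
community scheme could deliver.

Run a questionnaire session against the shipped reference config:

```
$ echo '{"q_entry": "injury", "q_inj_type": "chemical"}' > answers.json
$ triage run --answers answers.json
{
  "report": { "presenting_concern": "eye_injury", "features": ["chemical_injury"],
              "fast_tracked": true, "free_text": null },
  "disposition": { "urgency": "A", "service": "ED", "fast_track": true }
}
```

Simulate a cohort with known ground truth and evaluate it:

```
$ triage simulate --n 5000 --seed 17 --out cohort.csv --truth-out truth.csv
$ triage evaluate --cohort cohort.csv --out-prefix sim_eval
```

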
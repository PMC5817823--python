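# naranjo

Scoring, evaluation, and simulation tools for the **Naranjo Algorithm**, the
standard ten-question instrument for judging whether a suspected adverse drug
reaction (ADR) was actually caused by the suspected drug. The package is
aimed at pharmacovigilance analysts and clinical epidemiologists who want to
(a) score suspected-ADR records under the original instrument or its reduced
bedside variants, (b) measure how well a scheme's total score discriminates
adjudicated ADRs from non-ADRs, and (c) run those evaluations on synthetic
cohorts calibrated to published inpatient-cohort summaries when patient-level
data are unavailable.

## The instrument and the statistics

Each of the ten questions (previous conclusive reports, temporal relation,
dechallenge, rechallenge, alternative causes, placebo response, toxic blood
level, dose response, prior similar reaction, objective evidence) is answered
*yes* / *no* / *do-not-know* and scores between −1 and +2; do-not-know always
scores 0. The total score S = Σ s_i summarises the causal evidence, and a
record is classified as an ADR when S ≥ c (inclusive cut-off). Four schemes
are built in:

| scheme       | questions | score range | default cut-off |
|--------------|-----------|-------------|-----------------|
| `original10` | 1–10      | −4 … 13     | 5               |
| `modified5`  | 1–5       | −3 … 8      | 5               |
| `binary5`    | 1–5, each collapsed to 0/1 | 0 … 5 | 4     |
| `binary4`    | 2–5, each collapsed to 0/1 | 0 … 4 | 3     |

In the binarized variants a question contributes 1 exactly when its answer
falls in the positively-scored branch, with do-not-know grouped with "no"
(so for question 5 — *are there alternative causes?* — both "no" and
"do-not-know" score 1).

Against a gold-standard adjudication the package computes confusion matrices,
sensitivity TP/(TP+FN) and specificity TN/(TN+FP), the ROC staircase over
score thresholds with trapezoidal AUC (identical to the tie-corrected
Mann–Whitney statistic P(S⁺ > S⁻) + ½P(S⁺ = S⁻)), and DeLong
(placement-value) confidence intervals for the AUC.

The synthetic-cohort generator is a latent-class model: a hidden ADR /
non-ADR label is drawn with prevalence 997/1579, then the ten answers are
drawn independently from class-conditional categorical distributions
reconstructed from published summary tables of a large Japanese inpatient
cohort (1579 suspected ADRs, 997 confirmed). See `docs/methods.md` for the
reconstruction arithmetic and its limits.

## Worked example

```python
import naranjo as na

record = na.AssessmentRecord(
    "case-001",
    answers={1: na.Answer.YES, 2: na.Answer.YES, 3: na.Answer.YES,
             4: na.Answer.DO_NOT_KNOW, 5: na.Answer.NO,
             6: na.Answer.DO_NOT_KNOW, 7: na.Answer.DO_NOT_KNOW,
             8: na.Answer.DO_NOT_KNOW, 9: na.Answer.YES, 10: na.Answer.DO_NOT_KNOW},
)
scheme = na.build_scheme("original10")
scored = na.score_record(record, scheme)
print("total:", scored.total, "predicted ADR:", na.classify(scored, scheme.default_cutoff))

params = na.calibrate()
cohort = na.simulate(params, 5000, seed=42)
report = na.evaluation_report(cohort, na.build_scheme("binary4"))
print("sensitivity:", report["sensitivity"], "specificity:", report["specificity"])
print("AUC: %.3f (95%% CI %.3f-%.3f)" % (report["auc"],
      report["auc_ci"]["lower"], report["auc_ci"]["upper"]))
```

prints

```
total: 7 predicted ADR: True
sensitivity: 0.49 specificity: 0.99
AUC: 0.956 (95% CI 0.951-0.961)
```

The case scores 1+2+1+0+2 on questions 1–5 and +1 for the prior similar
reaction, total 7 ≥ 5, so the instrument calls it an ADR. On the simulated
cohort the four-question binary scheme at its cut-off of 3 is highly specific
(0.99) but insensitive (0.49), the intended trade-off for a quick screening
tool; the AUC of 0.956 says the total score ranks a random confirmed ADR
above a random non-ADR about 96% of the time.

The same pipeline is available from the shell:

```sh
naranjo simulate --n 1579 --seed 42 --out cohort.csv
naranjo score    --scheme binary4 --in cohort.csv --out scored.csv
naranjo evaluate --scheme binary4 --in cohort.csv --report report.json
naranjo roc      --scheme original10 --in cohort.csv --out roc.csv
```

Input CSV needs columns `record_id,q1..q10` with answers `yes`/`no`/`dk`
and an optional `label` column (`adr`/`no_adr`).

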
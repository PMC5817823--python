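# Methods

## Scoring model

An assessment record holds answers (yes / no / do-not-know) to up to ten
questions about a suspected adverse drug reaction. A scoring scheme maps
each (question, answer) pair to an integer and sums over its question set;
classification is inclusive, predicting an ADR when the total reaches the
cut-off. The 1981 score table is hard-coded: questions 1, 3, 7, 8, 9, 10
score +1 for yes; question 2 scores +2 / −1 for yes / no; question 4 scores
+2 / −1; question 5 (alternative causes) scores −1 / +2 because *no* is the
answer that supports causality; question 6 (placebo rechallenge) scores
−1 / +1. Do-not-know scores 0 everywhere, so it can never outrank an
informative answer, and the theoretical totals are −4…13 for the full
instrument.

The binarized variants collapse each question to 0/1 with the rule
"positively-scored branch → 1, everything else → 0", applied after grouping
do-not-know with "no" — the grouping the binary questionnaire itself prints
as a single "No/Do not know" column. The two rules differ only at question
5 with answer do-not-know (grouped with "no", the positive branch, it scores
1; binarizing the raw 0 would score 0). We follow the questionnaire's
published column grouping. Binarizing a raw score outside {−1, 0, +1, +2}
is an error rather than a silent clamp.

Custom questionnaires can be defined through the same `ScoringScheme` type
and serialised to JSON (`to_dict` / `scheme_from_dict`); the four built-ins
are frozen.

## Diagnostic accuracy

Sensitivity and specificity come from the confusion matrix at a cut-off;
both raise on an empty denominator instead of returning NaN. The ROC curve
is the staircase with one threshold per distinct observed total (ties share
a threshold), anchored at (0,0) and (1,1); its trapezoidal area equals the
tie-corrected Mann–Whitney statistic P(S⁺ > S⁻) + ½P(S⁺ = S⁻), a property
the tests verify against a brute-force pairwise oracle. Because totals are
small integers, no interpolation or score smoothing is applied.

The AUC confidence interval uses DeLong's placement-value variance
(midranks, so ties are handled consistently with the Mann–Whitney identity)
with a normal quantile at the requested level, clipped to [0, 1]. The
method is implemented here directly — no installed Python library exposes
it — and is cross-checked in the tests against a frozen interval from the
R `pROC` reference implementation and against a stratified percentile
bootstrap. When separation is perfect the variance degenerates to zero;
the clipped interval is still returned with a logged warning rather than an
exception, since a boundary AUC is a legitimate observation on small
fixtures.

Reported metrics are rounded half-up to two decimals for presentation
(`round_half_up`); raw values are kept alongside them in evaluation
reports.

## Calibrated synthetic cohort

The generator is a latent-class model: draw the hidden label with
prevalence 997/1579 (the confirmed-ADR fraction of the reference inpatient
cohort of 1579 suspected ADRs), then draw the ten answers independently
from class-conditional categorical distributions. Calibration reconstructs
those conditionals from published summaries only:

* **Question 1** is printed as a full cross-tabulation — 866 of 1002
  yes-answers and 131 of 577 no/do-not-know answers confirmed — and is used
  exactly.
* **Questions 2–5**: the true-positive count is TP = round(sens × 997) from
  the printed single-question sensitivity; the rest of the positive-score
  column is false positives; negative-score answers (no rechallenge
  reaction, alternative cause present) are assigned wholly to the non-ADR
  class, since they are evidence against causality; the zero-score column
  absorbs the remainder of each class. The reconstruction is rejected if
  any count goes negative or the implied specificity drifts more than 0.01
  from the printed value — a guard against rounding error accumulating
  silently.
* **Questions 6–10** are nearly constant (≥ 95% of records in one column);
  their handful of positive-score answers (3, 2, 24, 35, 53 records) are
  assigned to the ADR class and everything else to the zero column.
* Where "no" and "do-not-know" share a zero-score column the published
  split is unknown; a single representative answer is used (no for
  questions 1–5, do-not-know for 6–10, matching the column labels). The
  choice is score-invariant under every scheme, so it has no numeric
  effect.

Implied per-score marginals are re-derived and must match the published
column counts within ±1 per cell, enforced at calibration time.

### What the generator does and does not emulate

It reproduces the prevalence, the per-question marginal score
distributions, and the per-question sensitivities/specificities (the
acceptance tests confirm recovery within ±0.03, averaged over five
simulated cohorts of the published size). It does **not** reproduce the
joint dependence between questions, which the summaries do not determine:
answers are conditionally independent given the class. Real answers are
positively correlated (a record with a clear temporal relation tends to
have a clean dechallenge too), and independence makes the summed score a
stronger classifier than it is in real data. Concretely, the analytic
model AUCs are 0.986 / 0.985 / 0.979 / 0.958 for original10 / modified5 /
binary5 / binary4, versus roughly 0.92–0.93 reported on the real cohort,
and cut-off sensitivities and the ADR rate at score 5 shift accordingly.
Tests on simulated cohorts therefore assert exact agreement only for
quantities the calibration pins down (per-question accuracy, marginals,
the monotone rise of the ADR fraction with the total score, agreement
between empirical and analytic model AUC) and treat cohort-level operating
characteristics as reported, not asserted, values. Passing tests show the
pipeline is self-consistent and correctly calibrated to the published
margins — not that real joint behaviour is reproduced.

`model_score_distribution` / `model_auc` compute the exact class-conditional
total-score laws by convolution, giving an analytic reference for any
simulated cohort.

## Problem sizes and numerical choices

The large-cohort checks simulate 50 000 records, big enough that Monte-Carlo
error on an AUC is ~0.001 and the monotone-trend check is limited by model
shape rather than noise; monotonicity is asserted with a 3-standard-error
slack on adjacent score bins holding at least 50 records. Parameter-recovery
checks average five cohorts of 1579 (the published size): specificity
denominators are only 582, so a single cohort has standard errors up to
0.02 and the five-cohort mean brings ±0.03 to about 3.5 SE. The
DeLong-versus-bootstrap agreement check (2000 stratified replicates,
n = 500, ±0.01 endpoints) uses a cohort with class separation shrunk
halfway toward the marginal mixture (model AUC ≈ 0.83): at the calibrated
AUC ≈ 0.99 the normal-theory interval is boundary-clipped and percentile
endpoints are not comparable at that tolerance. A single integer seeds one
`numpy.random.Generator` per simulation; there is no global random state.

## Limitations

* Conditional independence given the class, as above; scheme-level
  operating characteristics on synthetic cohorts are optimistic.
* One suspected drug per record; multi-drug attribution and interactions
  are out of scope.
* The verbal probability categories of the original instrument
  (definite / probable / possible / doubtful) are not modelled; cut-offs
  are numeric.
* CSV input is deliberately strict: unknown answer tokens always fail with
  their row and column, and empty cells are read as do-not-know only under
  the explicit `coerce_missing_to_dk` option, so silent data degradation
  cannot occur.
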
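# Methods

## Problem

Administrative claims databases record discharge diagnoses for
reimbursement, not research, so any study that identifies acute myocardial
infarction (AMI) from ICD-9-CM 410.xx codes inherits the coding's error
rate. The standard way to quantify that error is a validation study: link a
sample of coded hospitalizations to the hospital's own charts, confirm each
case against clinical criteria, and report the positive predictive value
(PPV) and sensitivity of the code — overall and under stricter case
definitions that add code position, drug and procedure requirements.

`amivalid` implements that full workflow as a reusable pipeline, plus a
synthetic generator of paired claims/chart cohorts so every stage can be
exercised against known latent truth. The package targets claims extracts
shaped like Taiwan's National Health Insurance Research Database (up to five
ordered discharge diagnoses and five procedures per admission) and chart
extracts with structured adjudication evidence, but nothing ties it to one
provider.

## Record linkage

Claims rows cannot be joined to charts by a shared identifier, so linkage is
deterministic on the composite key *(birth date, sex, admission date,
discharge date)*. Two exclusion rules apply before pairing:

1. **Ambiguity** — a complete key shared by ≥ 2 records on the *same side*
   excludes all of its bearers; such admissions cannot be attributed to a
   single patient, and the method excludes rather than arbitrates.
2. **Missingness** — any blank key field excludes the record.

Pairs form only between keys unique on both sides; a unique key without a
counterpart is an unmatched residual, so every input record lands in exactly
one of {linked, ambiguous, missing, residual}. The linkage rate is linked
cases over claims input. When a patient links more than once, only the
earliest admission is kept; an admission-date tie is an error by default
(the data give no principled winner) unless `tie_keep_one` asks for the
lexicographically first case id. Patient identity for first-episode
selection uses the extract's pseudonymous `patient_id` when present,
otherwise the (birth date, sex) pair — a documented limitation, since two
patients can share both.

## Chart adjudication

AMI is confirmed by the WHO rule: at least two of {ischemic chest
discomfort, ischemic ECG changes, elevated CK-MB/troponin-T} documented in
the chart. A missing ECG contributes no criterion. Infarct type follows the
ECG — ST elevation (Q-wave patterns folded in) ⇒ STEMI, ST depression or
other ischemia ⇒ NSTEMI, confirmed without an ischemic tracing ⇒
unspecified. On the claims side 410.0–410.6 imply STEMI and 410.7/410.9
imply NSTEMI; 410.8 ("other specified site") belongs to neither bucket and
is reported separately rather than silently merged. Codes are normalized
with the dot optional and 4th/5th digits optional. Type-coding accuracy is
the fraction of ECG-typed confirmed cases whose highest-positioned 410 code
falls in the matching bucket; unspecified cases are excluded from both
denominators.

Dual review is modeled as two reviewer flags per chart plus rule-based
consensus: the raw agreement rate is the fraction of cases where the
reviewers concur, and disagreements resolve to the consensus call.

## Accuracy statistics

For procedures and antiplatelet prescriptions the chart is the gold
standard: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV =
TP/(TP+FP), NPV = TN/(TN+FN) from the aligned 2×2. Confidence intervals are
Clopper–Pearson exact intervals computed from beta quantiles,

  lower = B(α/2; k, n−k+1),  upper = B(1−α/2; k+1, n−k),

with the conventional bounds 0 and 1 at k = 0 and k = n. The exact method
is a deliberate choice: for small numerators such as 22/24 it yields
(0.73, 0.99) where a Wald interval would exceed 1. The test suite
cross-checks the bounds against direct tail-probability inversion by
bisection and against an independent library implementation, and verifies
≥ 93% empirical coverage at the nominal 95% level.

Case definitions combine the 410 code's position (any slot vs principal =
slot 1) with required claims exposures (antiplatelet = aspirin OR
clopidogrel at admission; heparin; catheterization; PTCA). Sensitivity uses
all chart-confirmed cases as denominator; PPV uses all claims-positive
cases. Tightening a definition can only shrink the claims-positive set, so
sensitivity is non-increasing along each requirement chain — a property the
tests assert.

Displayed proportions are rounded half-up to 2 decimals; internal values
are never rounded.

## Discharge-diagnosis concordance

A claims/chart pair of diagnosis lists is consistent only when identical
position-by-position and equal in length; order matters because position 1
is the principal diagnosis. Discordant pairs are classified: `order_only`
(same multiset), `code_absent_one_side` (one multiset strictly contains the
other — covering both a dropped trailing code and an insertion), 
`code_substituted` (equal length, different codes), `length_differs`
(unequal length with discrepancies on both sides). Codes are compared
literally after whitespace stripping; semantically equivalent codes (e.g.
two different malignancy-history codes) remain discordant by design.

## Synthetic generator

`generate_cohort` emulates a cohort of 410-coded hospitalizations: a latent
fraction `p_true_ami` are true AMI; the three evidence flags are drawn
independently given truth (the source report gives only marginal
frequencies, so conditional independence is the declared model); ECG-typed
true cases are STEMI with probability `stemi_fraction`; claims codes land in
the correct type bucket with probability `p_stemi_code_correct` /
`p_nstemi_code_correct`; the 410 code sits in the principal slot with
probability `p_principal_given_coded`, with remaining slots filled without
replacement from a comorbidity pool; procedures/drugs have per-item
prevalences and per-database false-negative/false-positive recording
errors; the chart's list is a random non-identity permutation with
probability `p_order_permuted`; linkage hazards blank one key field on one
side (`p_missing_key`) or clone an existing key for a distinct patient
(`n_collision_pairs`); `n_repeat_admissions` adds later second episodes and
`n_misplaced_charts` flags charts review-incomplete. Reviewer calls flip
independently from the rule-based truth with `reviewer_flip_rate`. One
seeded NumPy generator drives everything; identical config+seed gives
byte-identical CSVs. Marker elevation is a boolean flag, not a continuous
assay value with thresholds, because no numeric cutoffs are part of the
adjudication contract.

Defaults are the validated study conditions where reported: evidence
conditionals given AMI 0.68/0.97/0.94, `p_true_ami` 0.88, principal
fraction 0.83, STEMI fraction 0.50, coding accuracies 0.904/0.979, male
fraction 0.71, order-permutation rate 0.04 (≈ 14/338). Evidence
conditionals given NOT-AMI are **not** source-derived; the shipped scenario
0.30/0.20/0.15 gives a plausible low false-confirmation probability
(P(≥2 | not AMI) ≈ 0.117) for patients admitted with a suspected but
unconfirmed infarction. The reviewer flip rate 0.088 is the solution of
(1−ε)² + ε² = 0.84, the raw agreement the model should reproduce.

Two analytic oracles support recovery testing: `expected_confirmation_rate`
gives P(≥ 2 of 3 flags | truth) in closed form under independence, and
`expected_cohort_ppv` the attenuated cohort-level confirmation rate
p·P(≥2|AMI) + (1−p)·P(≥2|¬AMI) that the pipeline's any-position PPV
estimates.

What the generator does **not** emulate: realistic ICD-9 co-occurrence
structure, continuous lab values, costs or length of stay, correlated
evidence flags, and informative missingness. Passing recovery tests
therefore shows the pipeline correctly inverts this generative model, not
that real charts behave this simply.

## Deterministic reconstruction scenarios

`study_flow_cohort` builds a fixed 351-claims / 349-charts cohort whose
every margin equals a published validation study's counts: 341 link, 338
complete review, 297 confirm (evidence margins 202/288/279), 281 principal
with 261 confirmed, reviewer agreement 285/338, 14 discordant diagnosis
lists (the published pairs verbatim), per-item 2×2 counts as printed, and
type-coding accuracy 132/146 and 139/142. The builder's seed only shuffles
row order and attribute pairing; margins are invariant. Two source
inconsistencies are resolved explicitly: the aspirin-first-visit 2×2 sums
to 337 in print and is padded with one concordant negative, and the
"4 unspecified of 297" cannot coexist with "288 of 297 with ischemic ECG"
under ECG-based typing, so the reconstruction carries 9 unspecified cases
and reproduces the per-type accuracies instead. `case_definition_scenario`
realizes one case-definition row's printed counts as adjudicated cases
(padding with confirmed non-positives so the confirmed total is exact).

## Pipeline and numerical choices

Stages exchange plain CSV (schemas in `schemas.md`); manifests and
summaries are JSON. Counts are non-increasing along extracted → linked →
reviewed → confirmed, and the manifest stores SHA-256 digests so identical
config+seed runs are verifiably identical. A stage failure removes the
run's partial outputs and exits with code 3; validation errors exit 2.
Degenerate inputs are defined, not fatal: an empty cohort yields a report
with every metric absent, a zero denominator suppresses only that metric,
and an empty 2×2 is an error. Problem sizes used by the test suite and the
acceptance script: the 338-case reconstruction for printed-count checks,
n = 20 000 generated patients for stochastic recovery (3-standard-error
bands), and ≤ 20-record instances for brute-force linkage equivalence.

## Known limitations

Only deterministic linkage is implemented — no probabilistic (Fellegi–
Sunter) weighting, by design. The (birth date, sex) fallback identity can
merge distinct patients. The generator's independence assumptions are
stated, not estimated. Chart-side truth is taken as error-free except for
the explicit recording-error and misplacement hooks.
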
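# CSV interchange schemas

All pipeline tables are plain CSV, UTF-8, comma-separated, header row first.
Blank cells mean "missing". Set-valued cells are `|`-joined sorted tokens;
booleans are `1`/`0`; dates are ISO-8601 (`YYYY-MM-DD`).

## claims.csv

One row per claims-side hospitalization.

| column | meaning |
| --- | --- |
| `record_id` | unique claims record id |
| `patient_id` | pseudonymous patient key (may be blank) |
| `birth_date`, `sex`, `admission_date`, `discharge_date` | the four deterministic-linkage key fields; `sex` is `M`/`F` (inputs `1`/`2`/`male`/`female` are normalized) |
| `dx1` … `dx5` | ordered ICD-9-CM discharge diagnoses; `dx1` is the principal diagnosis |
| `procedures` | set drawn from `catheterization`, `PTCA`, `CABG`, `stenting` |
| `drugs_admission` | set drawn from `aspirin`, `clopidogrel`, `heparin` |
| `drugs_first_visit` | set drawn from `aspirin`, `clopidogrel` (first post-discharge visit) |

## charts.csv

All claims columns plus the chart-review fields:

| column | meaning |
| --- | --- |
| `chest_discomfort` | ischemic chest discomfort documented |
| `ecg_finding` | `ST_elevation`, `ST_depression_or_other_ischemia`, `none`, `missing` |
| `marker_elevated` | CK-MB or troponin-T elevation documented |
| `review_a`, `review_b` | the two reviewers' confirmed calls (blank when unreviewed) |
| `review_complete` | `0` for charts that could not be fully reviewed (e.g. misplaced) |

## truth.csv

Latent generator truth, one row per simulated patient: `patient_id`,
`is_true_ami`, `true_type` (`STEMI`/`NSTEMI`/`unspecified`, blank when not
AMI), `true_procedures`, `true_drugs_admission`, `true_drugs_first_visit`.

## linked.csv

One row per linked case surviving first-episode selection: `case_id` (the
claims record id) followed by every claims column prefixed `claims_` and
every chart column prefixed `chart_`.

## exclusions.csv

`record_id`, `side` (`claims`/`chart`), `reason` ∈ {`ambiguous_key`,
`missing_key`, `unmatched`, `repeat_episode_of_<case_id>`,
`review_incomplete`}.

## adjudicated.csv

linked.csv columns plus `confirmed`, `n_criteria_met` (0–3), `mi_type`
(`STEMI`/`NSTEMI`/`unspecified`/`not_ami`), `code_implied_type`
(`STEMI_coded`/`NSTEMI_coded`/`AMI_other_code`/`not_ami_code`),
`concordant_type`.

## table1.csv

Per case definition: `criteria`, `n_claims_positive`, `n_true_positive`,
`n_confirmed`, `sensitivity`, `ppv` (6-decimal fixed point; blank when the
denominator is empty).

## table2.csv

Per validated item: `item`, `tp`, `fp`, `fn`, `tn`, then
`{sensitivity,specificity,ppv,npv}` each with `_ci_low`/`_ci_high`
(Clopper–Pearson 95% bounds).

## concordance.csv

Per discordant case: `case_id`, `first_mismatch_position` (1-based),
`mismatch_kind` (`order_only`, `code_absent_one_side`, `code_substituted`,
`length_differs`), `claims_codes`, `chart_codes`.

## JSON artifacts

`linkage_summary.json` (flow counts and linkage rate),
`concordance_summary.json` (`n`, `n_consistent`, `rate`), `summary.json`
(headline metrics plus table 1/2 contents), `manifest.json` (config
snapshot, seed, per-stage counts, SHA-256 digests of every artifact,
timestamps).
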
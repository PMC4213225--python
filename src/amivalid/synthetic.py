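"""Synthetic paired claims/chart cohorts with known latent truth.

The generator emulates the population a claims-validation study starts
from: hospitalizations carrying an ICD-9-CM 410.xx (AMI) code on the claims
side, of which a latent fraction are true infarctions.  For each admission
it draws latent truth, conditional chart evidence (chest discomfort,
ischemic ECG, marker elevation — independently given truth), code placement
(principal versus secondary slot), STEMI/NSTEMI coding errors, per-database
recording errors for procedures and drugs, diagnosis-order permutation on
the chart side, and the two linkage hazards (blanked key fields and
deliberate key collisions between distinct patients).

Everything is driven by one seeded :class:`numpy.random.Generator`; the same
config and seed reproduce byte-identical CSV tables.

The module also ships deterministic reconstruction scenarios
(:func:`study_flow_cohort`, :func:`case_definition_scenario`) assembled from
the published summary counts of a Taiwanese AMI validation study.  These are
synthetic stand-ins for the never-deposited source data: they reproduce the
printed margins exactly but invent every patient-level detail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from datetime import date, timedelta
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, NonNegativeInt

from .adjudication import (
    NOT_AMI_CODE,
    NSTEMI,
    STEMI,
    STEMI_CODED,
    UNSPECIFIED,
    ChartEvidence,
    adjudicate,
    code_implied_type,
    first_ami_code,
)
from .records import (
    ADMISSION_DRUGS,
    ASPIRIN,
    CABG,
    CATHETERIZATION,
    CLOPIDOGREL,
    ECG_NONE,
    FIRST_VISIT_DRUGS,
    HEPARIN,
    PROCEDURES,
    PTCA,
    ST_DEPRESSION,
    ST_ELEVATION,
    STENTING,
    ChartEncounter,
    ClaimsEncounter,
    LinkedCase,
)

STEMI_STEMS = ("410.0", "410.1", "410.2", "410.3", "410.4", "410.5", "410.6")
NSTEMI_STEMS = ("410.7", "410.9")
ALL_410_STEMS = STEMI_STEMS + ("410.8",) + NSTEMI_STEMS

_KEY_FIELDS = ("birth_date", "sex", "admission_date", "discharge_date")

DEFAULT_COMORBIDITY_POOL = [
    "414.01", "250.00", "401.9", "428.0", "584.9", "272.4", "427.31",
    "496", "585", "424.0", "411.1", "511.9", "790.7", "578.9", "280.0",
    "434.91", "427.1",
]

_PROB = dict(ge=0.0, le=1.0)


class RecordingErrorRates(BaseModel):
    """Per-database recording error for procedure/drug items.

    False negative: a truly present item is not recorded; false positive: an
    absent item is recorded anyway.  The chart is treated as the gold
    standard, so its default error rates are zero.
    """

    model_config = {"extra": "forbid"}

    claims_false_negative: float = Field(0.03, **_PROB)
    claims_false_positive: float = Field(0.03, **_PROB)
    chart_false_negative: float = Field(0.0, **_PROB)
    chart_false_positive: float = Field(0.0, **_PROB)


class GeneratorConfig(BaseModel):
    """Study conditions for one synthetic cohort.

    Defaults follow the validation study this package reproduces wherever
    that study reports a value; the evidence conditionals given NOT-AMI are
    a documented default scenario, not study-derived.
    """

    model_config = {"extra": "forbid"}

    n_patients: NonNegativeInt = 350
    seed: int = 0

    # latent truth and coding
    p_true_ami: float = Field(0.88, **_PROB)
    p_principal_given_coded: float = Field(0.83, **_PROB)
    stemi_fraction: float = Field(0.50, **_PROB)
    p_stemi_code_correct: float = Field(0.904, **_PROB)
    p_nstemi_code_correct: float = Field(0.979, **_PROB)

    # chart evidence conditionals (independent given latent truth)
    p_chest_pain_given_ami: float = Field(0.68, **_PROB)
    p_ecg_given_ami: float = Field(0.97, **_PROB)
    p_marker_given_ami: float = Field(0.94, **_PROB)
    p_chest_pain_given_not: float = Field(0.30, **_PROB)
    p_ecg_given_not: float = Field(0.20, **_PROB)
    p_marker_given_not: float = Field(0.15, **_PROB)

    # exposures and their recording
    procedure_rates: dict[str, float] = Field(
        default_factory=lambda: {CATHETERIZATION: 0.73, PTCA: 0.62, CABG: 0.07, STENTING: 0.60}
    )
    drug_admission_rates: dict[str, float] = Field(
        default_factory=lambda: {ASPIRIN: 0.89, CLOPIDOGREL: 0.90, HEPARIN: 0.80}
    )
    drug_first_visit_rates: dict[str, float] = Field(
        default_factory=lambda: {ASPIRIN: 0.60, CLOPIDOGREL: 0.72}
    )
    recording_error: RecordingErrorRates = Field(default_factory=RecordingErrorRates)
    per_item_recording_error: dict[str, RecordingErrorRates] = Field(default_factory=dict)

    # discordance and linkage hazards
    p_order_permuted: float = Field(0.04, **_PROB)
    p_missing_key: float = Field(0.01, **_PROB)
    n_collision_pairs: NonNegativeInt = 0
    n_repeat_admissions: NonNegativeInt = 0
    n_misplaced_charts: NonNegativeInt = 0

    # reviewer simulation and demographics
    reviewer_flip_rate: float = Field(0.088, **_PROB)
    p_male: float = Field(0.71, **_PROB)
    comorbidity_pool: list[str] = Field(default_factory=lambda: list(DEFAULT_COMORBIDITY_POOL))

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        """Load a config from a JSON or YAML file."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def _rate_check(self) -> None:
        for name in ("procedure_rates", "drug_admission_rates", "drug_first_visit_rates"):
            for item, rate in getattr(self, name).items():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"{name}[{item!r}] must lie in [0, 1], got {rate}")

    def model_post_init(self, __context) -> None:
        self._rate_check()
        if self.n_collision_pairs > self.n_patients:
            raise ValueError("n_collision_pairs cannot exceed n_patients")
        if self.n_repeat_admissions > self.n_patients:
            raise ValueError("n_repeat_admissions cannot exceed n_patients")
        if len(self.comorbidity_pool) < 4 and self.n_patients:
            raise ValueError("comorbidity_pool needs at least 4 codes")


@dataclass(frozen=True)
class LatentTruth:
    patient_id: str
    is_true_ami: bool
    true_type: Optional[str]  # STEMI / NSTEMI / unspecified; None when not AMI
    true_procedures: frozenset[str]
    true_drugs_admission: frozenset[str]
    true_drugs_first_visit: frozenset[str]


class Cohort(NamedTuple):
    claims: list[ClaimsEncounter]
    charts: list[ChartEncounter]
    truth: list[LatentTruth]


class ConfirmationRates(NamedTuple):
    given_ami: float
    given_not: float


def who_positive_probability(p_chest: float, p_ecg: float, p_marker: float) -> float:
    """P(at least 2 of 3 independent evidence flags are present)."""
    p1, p2, p3 = p_chest, p_ecg, p_marker
    return (
        p1 * p2 * (1 - p3)
        + p1 * (1 - p2) * p3
        + (1 - p1) * p2 * p3
        + p1 * p2 * p3
    )


def expected_confirmation_rate(config: GeneratorConfig) -> ConfirmationRates:
    """Closed-form WHO 2-of-3 confirmation probabilities given latent truth.

    Assumes the three evidence flags are independent given truth — the
    generator's declared model.  Used as the analytic oracle for parameter
    recovery on generated cohorts.
    """
    return ConfirmationRates(
        given_ami=who_positive_probability(
            config.p_chest_pain_given_ami, config.p_ecg_given_ami, config.p_marker_given_ami
        ),
        given_not=who_positive_probability(
            config.p_chest_pain_given_not, config.p_ecg_given_not, config.p_marker_given_not
        ),
    )


def expected_cohort_ppv(config: GeneratorConfig) -> float:
    """Closed-form chart-confirmation rate of a 410-coded cohort.

    The any-position PPV the pipeline estimates converges to
    ``p_true_ami * P(>=2 | AMI) + (1 - p_true_ami) * P(>=2 | not AMI)``.
    """
    rates = expected_confirmation_rate(config)
    return config.p_true_ami * rates.given_ami + (1 - config.p_true_ami) * rates.given_not


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_unique_key(
    rng: np.random.Generator, used: set, p_male: float
) -> tuple[str, str, str, str]:
    for _ in range(1000):
        birth = date(1920, 1, 1) + timedelta(days=int(rng.integers(0, 60 * 365)))
        sex = "M" if rng.random() < p_male else "F"
        admission = date(2008, 1, 1) + timedelta(days=int(rng.integers(0, 366)))
        los = int(rng.integers(1, 31))
        discharge = admission + timedelta(days=los)
        key = (birth.isoformat(), sex, admission.isoformat(), discharge.isoformat())
        if key not in used:
            used.add(key)
            return key
    raise RuntimeError("could not draw a unique linkage key after 1000 attempts")


def _item_rates(config: GeneratorConfig, item: str) -> RecordingErrorRates:
    return config.per_item_recording_error.get(item, config.recording_error)


def _record_items(
    rng: np.random.Generator,
    config: GeneratorConfig,
    truth: frozenset[str],
    vocabulary: Sequence[str],
    side: str,
) -> frozenset[str]:
    recorded = set()
    for item in vocabulary:
        err = _item_rates(config, item)
        fn = err.claims_false_negative if side == "claims" else err.chart_false_negative
        fp = err.claims_false_positive if side == "claims" else err.chart_false_positive
        if item in truth:
            if rng.random() >= fn:
                recorded.add(item)
        else:
            if rng.random() < fp:
                recorded.add(item)
    return frozenset(recorded)


def _permuted(rng: np.random.Generator, codes: tuple[str, ...]) -> tuple[str, ...]:
    """A non-identity permutation of a list with >= 2 distinct orderings."""
    if len(codes) < 2:
        return codes
    while True:
        perm = tuple(codes[i] for i in rng.permutation(len(codes)))
        if perm != codes:
            return perm


def _make_admission(
    rng: np.random.Generator,
    config: GeneratorConfig,
    patient_id: str,
    index: int,
    key: tuple[str, str, str, str],
    truth: LatentTruth,
    evidence: ChartEvidence,
    claims_code: str,
) -> tuple[ClaimsEncounter, ChartEncounter]:
    birth, sex, admission, discharge = key

    n_dx = int(rng.integers(3, 6))
    pool_idx = rng.choice(len(config.comorbidity_pool), size=n_dx - 1, replace=False)
    comorbidities = [config.comorbidity_pool[i] for i in pool_idx]
    if rng.random() < config.p_principal_given_coded:
        position = 0
    else:
        position = int(rng.integers(1, n_dx))
    dx = list(comorbidities)
    dx.insert(position, claims_code)
    claims_dx = tuple(dx)
    chart_dx = (
        _permuted(rng, claims_dx) if rng.random() < config.p_order_permuted else claims_dx
    )

    claims = ClaimsEncounter(
        record_id=f"C{index:06d}",
        patient_id=patient_id,
        birth_date=birth,
        sex=sex,
        admission_date=admission,
        discharge_date=discharge,
        diagnoses=claims_dx,
        procedures=_record_items(rng, config, truth.true_procedures, PROCEDURES, "claims"),
        drugs_admission=_record_items(rng, config, truth.true_drugs_admission, ADMISSION_DRUGS, "claims"),
        drugs_first_visit=_record_items(rng, config, truth.true_drugs_first_visit, FIRST_VISIT_DRUGS, "claims"),
    )
    truth_confirmed = adjudicate(evidence).confirmed
    flip_a = rng.random() < config.reviewer_flip_rate
    flip_b = rng.random() < config.reviewer_flip_rate
    chart = ChartEncounter(
        record_id=f"H{index:06d}",
        patient_id=patient_id,
        birth_date=birth,
        sex=sex,
        admission_date=admission,
        discharge_date=discharge,
        diagnoses=chart_dx,
        procedures=_record_items(rng, config, truth.true_procedures, PROCEDURES, "chart"),
        drugs_admission=_record_items(rng, config, truth.true_drugs_admission, ADMISSION_DRUGS, "chart"),
        drugs_first_visit=_record_items(rng, config, truth.true_drugs_first_visit, FIRST_VISIT_DRUGS, "chart"),
        chest_discomfort=evidence.chest_discomfort,
        ecg_finding=evidence.ecg_finding,
        marker_elevated=evidence.marker_elevated,
        review_a=truth_confirmed != flip_a,
        review_b=truth_confirmed != flip_b,
    )
    return claims, chart


def _draw_latent(rng: np.random.Generator, config: GeneratorConfig, patient_id: str):
    """Latent truth, chart evidence and the claims-side 410 code for one patient."""
    is_ami = rng.random() < config.p_true_ami
    if is_ami:
        chest = rng.random() < config.p_chest_pain_given_ami
        ecg = rng.random() < config.p_ecg_given_ami
        marker = rng.random() < config.p_marker_given_ami
        if not ecg:
            true_type = UNSPECIFIED
            ecg_finding = ECG_NONE
        elif rng.random() < config.stemi_fraction:
            true_type = STEMI
            ecg_finding = ST_ELEVATION
        else:
            true_type = NSTEMI
            ecg_finding = ST_DEPRESSION
    else:
        chest = rng.random() < config.p_chest_pain_given_not
        ecg = rng.random() < config.p_ecg_given_not
        marker = rng.random() < config.p_marker_given_not
        true_type = None
        ecg_finding = ST_DEPRESSION if ecg else ECG_NONE

    if true_type == STEMI:
        correct = rng.random() < config.p_stemi_code_correct
        stem = str(rng.choice(STEMI_STEMS if correct else NSTEMI_STEMS))
    elif true_type == NSTEMI:
        correct = rng.random() < config.p_nstemi_code_correct
        stem = str(rng.choice(NSTEMI_STEMS if correct else STEMI_STEMS))
    else:
        stem = str(rng.choice(ALL_410_STEMS))
    claims_code = stem + "1" if "." in stem else stem + ".01"

    procedures = frozenset(
        item for item, rate in config.procedure_rates.items() if rng.random() < rate
    )
    drugs_adm = frozenset(
        item for item, rate in config.drug_admission_rates.items() if rng.random() < rate
    )
    drugs_fv = frozenset(
        item for item, rate in config.drug_first_visit_rates.items() if rng.random() < rate
    )
    truth = LatentTruth(
        patient_id=patient_id,
        is_true_ami=is_ami,
        true_type=true_type,
        true_procedures=procedures,
        true_drugs_admission=drugs_adm,
        true_drugs_first_visit=drugs_fv,
    )
    evidence = ChartEvidence(
        chest_discomfort=chest, ecg_finding=ecg_finding, marker_elevated=marker
    )
    return truth, evidence, claims_code


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate one paired cohort with aligned latent truth.

    One claims row and one chart row per admission; collision patients share
    all four key fields with an existing patient; repeat admissions add a
    later episode for a sampled patient; missing-key hazards blank one field
    on one side; misplaced charts are flagged review-incomplete.
    Deterministic under (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    used_keys: set = set()

    claims: list[ClaimsEncounter] = []
    charts: list[ChartEncounter] = []
    truths: list[LatentTruth] = []
    patient_keys: list[tuple[str, str, str, str]] = []

    index = 0
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        key = _draw_unique_key(rng, used_keys, config.p_male)
        truth, evidence, code = _draw_latent(rng, config, pid)
        cl, ch = _make_admission(rng, config, pid, index, key, truth, evidence, code)
        claims.append(cl)
        charts.append(ch)
        truths.append(truth)
        patient_keys.append(key)
        index += 1

    # deliberate key collisions: a fresh patient duplicating an existing key
    if config.n_collision_pairs:
        targets = rng.choice(config.n_patients, size=config.n_collision_pairs, replace=False)
        for j, t in enumerate(targets):
            pid = f"X{j:05d}"
            truth, evidence, code = _draw_latent(rng, config, pid)
            cl, ch = _make_admission(
                rng, config, pid, index, patient_keys[int(t)], truth, evidence, code
            )
            claims.append(cl)
            charts.append(ch)
            truths.append(truth)
            index += 1

    # repeat admissions: a later second episode for sampled patients
    if config.n_repeat_admissions:
        repeaters = rng.choice(config.n_patients, size=config.n_repeat_admissions, replace=False)
        for t in repeaters:
            t = int(t)
            birth, sex, _, discharge = patient_keys[t]
            for _ in range(100):
                adm2 = date.fromisoformat(discharge) + timedelta(days=int(rng.integers(10, 120)))
                dis2 = adm2 + timedelta(days=int(rng.integers(1, 31)))
                key2 = (birth, sex, adm2.isoformat(), dis2.isoformat())
                if key2 not in used_keys:
                    used_keys.add(key2)
                    break
            truth = truths[t]
            _, evidence, code = _draw_latent(rng, config, truth.patient_id)
            cl, ch = _make_admission(rng, config, truth.patient_id, index, key2, truth, evidence, code)
            claims.append(cl)
            charts.append(ch)
            index += 1

    # missing-key hazard: blank one field on one side
    if config.p_missing_key > 0:
        for i in range(len(claims)):
            if rng.random() < config.p_missing_key:
                field = _KEY_FIELDS[int(rng.integers(0, 4))]
                if rng.random() < 0.5:
                    claims[i] = replace(claims[i], **{field: None})
                else:
                    charts[i] = replace(charts[i], **{field: None})

    # misplaced charts: linked but unreviewable
    if config.n_misplaced_charts:
        lost = rng.choice(len(charts), size=min(config.n_misplaced_charts, len(charts)), replace=False)
        for i in lost:
            charts[int(i)] = replace(charts[int(i)], review_complete=False)

    order = rng.permutation(len(charts))
    charts = [charts[int(i)] for i in order]
    return Cohort(claims=claims, charts=charts, truth=truths)


def truth_to_frame(truths: Sequence[LatentTruth]):
    import pandas as pd

    rows = [
        {
            "patient_id": t.patient_id,
            "is_true_ami": "1" if t.is_true_ami else "0",
            "true_type": t.true_type or "",
            "true_procedures": "|".join(sorted(t.true_procedures)),
            "true_drugs_admission": "|".join(sorted(t.true_drugs_admission)),
            "true_drugs_first_visit": "|".join(sorted(t.true_drugs_first_visit)),
        }
        for t in truths
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "is_true_ami", "true_type",
            "true_procedures", "true_drugs_admission", "true_drugs_first_visit",
        ],
    )


# ---------------------------------------------------------------------------
# deterministic reconstruction scenarios (synthetic stand-ins for the
# never-deposited study data; patient-level detail is invented, margins are
# the published ones)
# ---------------------------------------------------------------------------

# per-item (tp, fp, fn, tn) agreement counts between claims and chart.
# The aspirin first-visit row is padded with one extra concordant negative so
# every item covers the full reviewed cohort.
ITEM_AGREEMENT_COUNTS: dict[str, tuple[int, int, int, int]] = {
    f"{CATHETERIZATION}": (240, 3, 8, 87),
    f"{PTCA}": (205, 5, 6, 122),
    f"{CABG}": (22, 2, 2, 312),
    f"{STENTING}": (184, 1, 19, 134),
    f"{ASPIRIN}_admission": (293, 7, 9, 29),
    f"{CLOPIDOGREL}_admission": (299, 4, 4, 31),
    f"{ASPIRIN}_first_visit": (199, 34, 4, 101),
    f"{CLOPIDOGREL}_first_visit": (205, 38, 4, 91),
}

# the 14 published discordant discharge-diagnosis list pairs (claims, chart)
DISCORDANT_LIST_PAIRS: list[tuple[tuple[str, ...], tuple[str, ...]]] = [
    (("410.11", "414.01", "250.00"), ("410.11", "414.01", "250.00", "272.4")),
    (("410.11", "414.01", "V02.61", "401.9"), ("410.11", "414.01", "496", "401.9", "V02.61")),
    (("414.01", "410.92", "401.9"), ("414.01", "410.92", "401.9", "780.2")),
    (("414.01", "410.72", "585", "250.00"), ("414.01", "410.72", "584.9", "250.00", "585")),
    (("410.61", "414.01", "424.0"), ("410.61", "414.01", "424.0", "413.9")),
    (("410.11", "428.0", "584.9", "790.7", "427.31"), ("428.0", "410.12", "584.9", "790.7", "427.31")),
    (("410.41", "424.0", "401.9", "272.4", "250.00"), ("410.41", "424.0", "414.01", "272.4", "250.00")),
    (("410.41", "414.01", "511.9", "785.51", "427.31"), ("410.41", "414.01", "511.9", "532.90", "427.31")),
    (("410.71", "414.01", "411.1", "518.81", "532.40"), ("410.71", "414.01", "411.1", "250.00", "532.40")),
    (("410.71", "414.01", "578.9", "280.0", "426.13"), ("410.71", "414.01", "578.9", "280.0", "290.0")),
    (("414.01", "410.41", "428.0", "584.9", "250.00"), ("410.41", "414.01", "428.0", "584.9", "403.91")),
    (("414.01", "410.72", "250.00", "496", "600.0"), ("414.01", "584.9", "410.72", "250.00", "496")),
    (("410.41", "414.01", "427.1", "434.91", "145.9"), ("410.41", "414.01", "427.1", "434.91", "V10.22")),
    (("410.71", "414.01", "151.9", "250.00", "272.4"), ("410.71", "414.01", "V10.04", "250.00", "272.4")),
]

# reviewed-cohort margins used by study_flow_cohort
_N_CLAIMS, _N_CHARTS, _N_LINKED, _N_REVIEWED = 351, 349, 341, 338
_N_CONFIRMED = 297
_N_PRINCIPAL, _N_PRINCIPAL_CONFIRMED = 281, 261
# evidence-pattern counts among confirmed (chest pain / ECG / markers):
# all three 175, pain+ECG 18, pain+markers 9, ECG+markers 95 -> margins
# 202 / 288 / 279 of 297
_PATTERN_COUNTS = {(1, 1, 1): 175, (1, 1, 0): 18, (1, 0, 1): 9, (0, 1, 1): 95}
_NONCONF_PATTERNS = {(1, 0, 0): 15, (0, 1, 0): 13, (0, 0, 0): 13}
_N_AGREE_CONFIRMED, _N_AGREE_REJECTED = 258, 27


def _seq_key(i: int) -> tuple[str, str, str, str]:
    birth = date(1930, 1, 1) + timedelta(days=13 * i)
    adm = date(2008, 1, 2) + timedelta(days=i % 330)
    return (
        birth.isoformat(),
        "M" if i % 3 else "F",
        adm.isoformat(),
        (adm + timedelta(days=2 + i % 9)).isoformat(),
    )


def study_flow_cohort(seed: int = 0) -> Cohort:
    """Deterministic cohort reproducing a published validation study's margins.

    Synthetic reconstruction: 351 claims rows versus 349 chart rows, of which
    341 link (2 ambiguous, 2 missing-key and 6 unmatched claims; 2/2/4 on the
    chart side), 3 linked charts are review-incomplete, and the 338 reviewed
    cases carry evidence, code-position, type-coding, reviewer, exposure and
    diagnosis-list attributes whose margins equal the published counts.  The
    seed only shuffles row order and attribute pairing; every margin is
    invariant to it.
    """
    rng = np.random.default_rng(seed)

    specials = DISCORDANT_LIST_PAIRS
    n_special = len(specials)

    # --- attribute pools for the 338 reviewed cases -----------------------
    # special (discordant-list) cases first: all confirmed, full evidence,
    # type matching their printed claims code, correct coding.
    cases: list[dict] = []
    n_special_principal = 0
    for claims_dx, chart_dx in specials:
        code = first_ami_code(claims_dx)
        stemi = code_implied_type(code) == STEMI_CODED
        cases.append(
            dict(
                confirmed=True,
                pattern=(1, 1, 1),
                ecg_finding=ST_ELEVATION if stemi else ST_DEPRESSION,
                claims_dx=claims_dx,
                chart_dx=chart_dx,
                principal=bool(claims_dx and code_implied_type(claims_dx[0]) != NOT_AMI_CODE),
            )
        )
        n_special_principal += cases[-1]["principal"]

    # generic confirmed cases: patterns, ECG types with coding correctness,
    # and principal flags drawn from exact-count pools
    pattern_pool: list[tuple[int, int, int]] = []
    for pat, count in _PATTERN_COUNTS.items():
        n = count - sum(1 for c in cases if c["pattern"] == pat and c["confirmed"])
        pattern_pool += [pat] * n
    rng.shuffle(pattern_pool)

    n_special_stemi = sum(1 for c in cases if c["ecg_finding"] == ST_ELEVATION)
    n_special_nstemi = n_special - n_special_stemi
    # 146 STEMI with 132 correctly coded; 142 ECG-typed NSTEMI with 139 correct
    type_pool = (
        [("STEMI", True)] * (132 - n_special_stemi)
        + [("STEMI", False)] * 14
        + [("NSTEMI", True)] * (139 - n_special_nstemi)
        + [("NSTEMI", False)] * 3
    )
    rng.shuffle(type_pool)

    principal_pool_conf = [True] * (_N_PRINCIPAL_CONFIRMED - n_special_principal)
    principal_pool_conf += [False] * (_N_CONFIRMED - n_special - len(principal_pool_conf))
    rng.shuffle(principal_pool_conf)

    type_iter = iter(type_pool)
    for pat, principal in zip(pattern_pool, principal_pool_conf):
        chest, ecg, marker = pat
        if ecg:
            mi_type, correct = next(type_iter)
            ecg_finding = ST_ELEVATION if mi_type == "STEMI" else ST_DEPRESSION
        else:
            mi_type, correct = UNSPECIFIED, True
            ecg_finding = ECG_NONE
        if mi_type == "STEMI":
            stem = str(rng.choice(STEMI_STEMS)) if correct else str(rng.choice(NSTEMI_STEMS))
        elif mi_type == "NSTEMI":
            stem = str(rng.choice(NSTEMI_STEMS)) if correct else str(rng.choice(STEMI_STEMS))
        else:
            stem = "410.9"
        cases.append(
            dict(
                confirmed=True,
                pattern=pat,
                ecg_finding=ecg_finding,
                code=stem + "1",
                principal=principal,
            )
        )

    # non-confirmed cases
    principal_pool_non = [True] * (_N_PRINCIPAL - _N_PRINCIPAL_CONFIRMED)
    principal_pool_non += [False] * (
        (_N_REVIEWED - _N_CONFIRMED) - len(principal_pool_non)
    )
    rng.shuffle(principal_pool_non)
    noncont = []
    for pat, count in _NONCONF_PATTERNS.items():
        noncont += [pat] * count
    rng.shuffle(noncont)
    for pat, principal in zip(noncont, principal_pool_non):
        cases.append(
            dict(
                confirmed=False,
                pattern=pat,
                ecg_finding=ST_DEPRESSION if pat[1] else ECG_NONE,
                code="410.91",
                principal=principal,
            )
        )

    assert len(cases) == _N_REVIEWED

    # fill diagnosis lists for generic cases
    pool = DEFAULT_COMORBIDITY_POOL
    for i, c in enumerate(cases):
        if "claims_dx" in c:
            continue
        picks = rng.choice(len(pool), size=3, replace=False)
        dx = [pool[int(j)] for j in picks]
        dx.insert(0 if c["principal"] else 1, c["code"])
        c["claims_dx"] = tuple(dx)
        c["chart_dx"] = tuple(dx)

    # reviewer flags: agreement on 258 confirmed + 27 rejected cases
    conf_pool = [True] * _N_AGREE_CONFIRMED + [False] * (
        _N_CONFIRMED - _N_AGREE_CONFIRMED
    )
    rej_pool = [True] * _N_AGREE_REJECTED + [False] * (
        (_N_REVIEWED - _N_CONFIRMED) - _N_AGREE_REJECTED
    )
    rng.shuffle(conf_pool)
    rng.shuffle(rej_pool)
    it_conf, it_rej = iter(conf_pool), iter(rej_pool)
    for c in cases:
        agree = next(it_conf) if c["confirmed"] else next(it_rej)
        c["review_a"] = c["confirmed"]
        c["review_b"] = c["confirmed"] if agree else not c["confirmed"]

    # per-item exposure flags with the published 2x2 counts
    for item, (tp, fp, fn, tn) in ITEM_AGREEMENT_COUNTS.items():
        labels = ["tp"] * tp + ["fp"] * fp + ["fn"] * fn + ["tn"] * tn
        assert len(labels) == _N_REVIEWED
        rng.shuffle(labels)
        for c, lab in zip(cases, labels):
            c.setdefault("claims_items", set())
            c.setdefault("chart_items", set())
            if lab in ("tp", "fp"):
                c["claims_items"].add(item)
            if lab in ("tp", "fn"):
                c["chart_items"].add(item)

    # --- materialize encounters ------------------------------------------
    claims: list[ClaimsEncounter] = []
    charts: list[ChartEncounter] = []
    truths: list[LatentTruth] = []

    def split_items(items: set) -> tuple[frozenset, frozenset, frozenset]:
        procs = frozenset(i for i in items if i in PROCEDURES)
        adm = frozenset(i.removesuffix("_admission") for i in items if i.endswith("_admission"))
        fv = frozenset(i.removesuffix("_first_visit") for i in items if i.endswith("_first_visit"))
        # heparin is not item-validated; tie it to catheterization claims
        return procs, adm, fv

    for i, c in enumerate(cases):
        key = _seq_key(i)
        pid = f"S{i:05d}"
        procs_cl, adm_cl, fv_cl = split_items(c["claims_items"])
        procs_ch, adm_ch, fv_ch = split_items(c["chart_items"])
        if CATHETERIZATION in procs_cl:
            adm_cl |= {HEPARIN}
        if CATHETERIZATION in procs_ch:
            adm_ch |= {HEPARIN}
        claims.append(
            ClaimsEncounter(
                record_id=f"C{i:06d}",
                patient_id=pid,
                birth_date=key[0], sex=key[1], admission_date=key[2], discharge_date=key[3],
                diagnoses=c["claims_dx"],
                procedures=procs_cl,
                drugs_admission=adm_cl,
                drugs_first_visit=fv_cl,
            )
        )
        chest, _, marker = c["pattern"]
        charts.append(
            ChartEncounter(
                record_id=f"H{i:06d}",
                patient_id=pid,
                birth_date=key[0], sex=key[1], admission_date=key[2], discharge_date=key[3],
                diagnoses=c["chart_dx"],
                procedures=procs_ch,
                drugs_admission=adm_ch,
                drugs_first_visit=fv_ch,
                chest_discomfort=bool(chest),
                ecg_finding=c["ecg_finding"],
                marker_elevated=bool(marker),
                review_a=c["review_a"],
                review_b=c["review_b"],
            )
        )
        truths.append(
            LatentTruth(
                patient_id=pid,
                is_true_ami=c["confirmed"],
                true_type=None,
                true_procedures=procs_ch,
                true_drugs_admission=adm_ch,
                true_drugs_first_visit=fv_ch,
            )
        )

    # 3 linked but review-incomplete (misplaced) charts
    for j in range(_N_LINKED - _N_REVIEWED):
        i = _N_REVIEWED + j
        key = _seq_key(i)
        pid = f"S{i:05d}"
        dx = ("410.91", "414.01", "401.9")
        claims.append(
            ClaimsEncounter(
                record_id=f"C{i:06d}", patient_id=pid,
                birth_date=key[0], sex=key[1], admission_date=key[2], discharge_date=key[3],
                diagnoses=dx,
            )
        )
        charts.append(
            ChartEncounter(
                record_id=f"H{i:06d}", patient_id=pid,
                birth_date=key[0], sex=key[1], admission_date=key[2], discharge_date=key[3],
                diagnoses=dx, review_complete=False,
            )
        )

    # unlinkable extras on each side
    def extra_key(i: int) -> tuple[str, str, str, str]:
        return _seq_key(1000 + i)

    n = _N_LINKED
    shared_c = extra_key(0)
    for j in range(2):  # ambiguous claims pair
        claims.append(
            ClaimsEncounter(
                record_id=f"C{n + j:06d}", patient_id=f"A{j}",
                birth_date=shared_c[0], sex=shared_c[1],
                admission_date=shared_c[2], discharge_date=shared_c[3],
                diagnoses=("410.91",),
            )
        )
    for j in range(2):  # missing-key claims
        k = extra_key(1 + j)
        claims.append(
            ClaimsEncounter(
                record_id=f"C{n + 2 + j:06d}", patient_id=f"M{j}",
                birth_date=k[0], sex=None, admission_date=k[2], discharge_date=k[3],
                diagnoses=("410.91",),
            )
        )
    for j in range(6):  # unmatched unique claims
        k = extra_key(3 + j)
        claims.append(
            ClaimsEncounter(
                record_id=f"C{n + 4 + j:06d}", patient_id=f"U{j}",
                birth_date=k[0], sex=k[1], admission_date=k[2], discharge_date=k[3],
                diagnoses=("410.91",),
            )
        )
    shared_h = extra_key(20)
    for j in range(2):  # ambiguous chart pair
        charts.append(
            ChartEncounter(
                record_id=f"H{n + j:06d}", patient_id=f"a{j}",
                birth_date=shared_h[0], sex=shared_h[1],
                admission_date=shared_h[2], discharge_date=shared_h[3],
                diagnoses=("410.91",),
            )
        )
    for j in range(2):  # missing-key charts
        k = extra_key(22 + j)
        charts.append(
            ChartEncounter(
                record_id=f"H{n + 2 + j:06d}", patient_id=f"m{j}",
                birth_date=k[0], sex=k[1], admission_date=None, discharge_date=k[3],
                diagnoses=("410.91",),
            )
        )
    for j in range(4):  # unmatched unique charts
        k = extra_key(25 + j)
        charts.append(
            ChartEncounter(
                record_id=f"H{n + 4 + j:06d}", patient_id=f"u{j}",
                birth_date=k[0], sex=k[1], admission_date=k[2], discharge_date=k[3],
                diagnoses=("410.91",),
            )
        )

    assert len(claims) == _N_CLAIMS and len(charts) == _N_CHARTS
    claims = [claims[int(i)] for i in rng.permutation(len(claims))]
    charts = [charts[int(i)] for i in rng.permutation(len(charts))]
    return Cohort(claims=claims, charts=charts, truth=truths)


def case_definition_scenario(
    defn,
    n_claims_positive: int,
    n_true_positive: int,
    n_confirmed_total: int = 297,
    n_filler_negative: int = 10,
) -> list[LinkedCase]:
    """Adjudicated cases realizing one case-definition row's printed counts.

    Synthetic reconstruction: builds ``n_claims_positive`` cases whose claims
    record satisfies ``defn`` (``n_true_positive`` of them chart-confirmed),
    plus confirmed cases outside the definition so that the confirmed total
    is ``n_confirmed_total``, plus unconfirmed filler negatives.  Requires a
    definition that a record can fail (a position or exposure requirement).
    """
    if n_true_positive > n_claims_positive or n_true_positive > n_confirmed_total:
        raise ValueError("inconsistent scenario counts")

    full_exposures = dict(
        procedures=frozenset({CATHETERIZATION, PTCA}),
        drugs_admission=frozenset({ASPIRIN, HEPARIN}),
    )

    def positive_claims(i: int) -> ClaimsEncounter:
        return ClaimsEncounter(
            record_id=f"P{i:06d}", patient_id=f"P{i:06d}",
            diagnoses=("410.91", "414.01"), **full_exposures,
        )

    def negative_claims(i: int) -> ClaimsEncounter:
        if defn.position == "principal":
            return ClaimsEncounter(
                record_id=f"N{i:06d}", patient_id=f"N{i:06d}",
                diagnoses=("414.01", "410.91"), **full_exposures,
            )
        if not (defn.require_antiplatelet or defn.require_heparin
                or defn.require_catheterization or defn.require_ptca):
            raise ValueError("definition matches every 410-coded record; no negatives exist")
        return ClaimsEncounter(
            record_id=f"N{i:06d}", patient_id=f"N{i:06d}",
            diagnoses=("410.91", "414.01"),
        )

    confirmed_ev = ChartEvidence(True, ST_ELEVATION, True)
    rejected_ev = ChartEvidence(False, ECG_NONE, False)

    def chart(i: int, confirmed: bool) -> ChartEncounter:
        ev = confirmed_ev if confirmed else rejected_ev
        return ChartEncounter(
            record_id=f"H{i:06d}", patient_id=f"H{i:06d}",
            chest_discomfort=ev.chest_discomfort,
            ecg_finding=ev.ecg_finding,
            marker_elevated=ev.marker_elevated,
        )

    cases = []
    i = 0
    plan = (
        [(True, True)] * n_true_positive
        + [(True, False)] * (n_claims_positive - n_true_positive)
        + [(False, True)] * (n_confirmed_total - n_true_positive)
        + [(False, False)] * n_filler_negative
    )
    for pos, conf in plan:
        cl = positive_claims(i) if pos else negative_claims(i)
        ch = chart(i, conf)
        case = LinkedCase(case_id=cl.record_id, claims=cl, chart=ch)
        case.adjudication = adjudicate(
            ChartEvidence(ch.chest_discomfort, ch.ecg_finding, ch.marker_elevated)
        )
        cases.append(case)
        i += 1
    return cases
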
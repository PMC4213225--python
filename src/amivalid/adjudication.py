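"""Chart adjudication: WHO 2-of-3 confirmation, infarct typing, coding accuracy.

An admission is confirmed as acute myocardial infarction (AMI) when at least
two of three criteria are documented in the chart: chest discomfort
characteristic of ischemia, ECG changes indicative of ischemia (ST
elevation/Q waves or ST depression), and elevated serum markers of
myocardial injury (CK-MB or troponin-T).  ST-elevation (STEMI) versus
non-ST-elevation (NSTEMI) infarction is distinguished from the ECG finding;
Q-wave patterns are folded into the ST-elevation category.  On the claims
side the corresponding ICD-9-CM convention is 410.0–410.6 for STEMI and
410.7/410.9 for NSTEMI; 410.8 belongs to neither bucket and is reported
separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .records import (
    ECG_MISSING,
    ECG_NONE,
    ST_DEPRESSION,
    ST_ELEVATION,
    ChartEncounter,
    LinkedCase,
)

# mi_type vocabulary
STEMI = "STEMI"
NSTEMI = "NSTEMI"
UNSPECIFIED = "unspecified"
NOT_AMI = "not_ami"

# code_implied_type vocabulary
STEMI_CODED = "STEMI_coded"
NSTEMI_CODED = "NSTEMI_coded"
AMI_OTHER_CODE = "AMI_other_code"  # 410.8 or a bare "410" stem: AMI family, neither type bucket
NOT_AMI_CODE = "not_ami_code"


@dataclass(frozen=True)
class ChartEvidence:
    """Structured evidence abstracted from one discharge note."""

    chest_discomfort: bool = False
    ecg_finding: str = ECG_MISSING
    marker_elevated: bool = False


@dataclass(frozen=True)
class AdjudicationResult:
    confirmed: bool
    n_criteria_met: int
    mi_type: str


def evidence_from_chart(chart: ChartEncounter) -> ChartEvidence:
    return ChartEvidence(
        chest_discomfort=chart.chest_discomfort,
        ecg_finding=chart.ecg_finding,
        marker_elevated=chart.marker_elevated,
    )


def adjudicate(evidence: ChartEvidence) -> AdjudicationResult:
    """Apply the WHO 2-of-3 rule and type the infarct from the ECG.

    A missing ECG contributes no criterion.  A confirmed case without an
    ischemic ECG finding is typed ``unspecified``.
    """
    ecg_ischemic = evidence.ecg_finding in (ST_ELEVATION, ST_DEPRESSION)
    n = int(evidence.chest_discomfort) + int(ecg_ischemic) + int(evidence.marker_elevated)
    confirmed = n >= 2
    if not confirmed:
        mi_type = NOT_AMI
    elif evidence.ecg_finding == ST_ELEVATION:
        mi_type = STEMI
    elif evidence.ecg_finding == ST_DEPRESSION:
        mi_type = NSTEMI
    else:  # confirmed on chest pain + markers; ECG none or missing
        mi_type = UNSPECIFIED
    return AdjudicationResult(confirmed=confirmed, n_criteria_met=n, mi_type=mi_type)


_CODE_RE = re.compile(r"^([VvEe]?\d{1,3})(?:\.?(\d{1,2}))?$")


def code_implied_type(icd_code: str) -> str:
    """Bucket an ICD-9-CM code into the claims-implied infarct type.

    Normalization: surrounding whitespace stripped, the dot optional, 4th and
    5th digits optional.  Stems 410.0–410.6 imply STEMI, 410.7 and 410.9 imply
    NSTEMI; 410.8 (and a bare ``410``) are AMI codes outside both type
    buckets; anything else is not an AMI code.
    """
    if not isinstance(icd_code, str) or not icd_code.strip():
        raise ValueError(f"unparseable ICD-9-CM code: {icd_code!r}")
    m = _CODE_RE.match(icd_code.strip())
    if m is None:
        raise ValueError(f"unparseable ICD-9-CM code: {icd_code!r}")
    head, tail = m.group(1), m.group(2)
    if head != "410":
        return NOT_AMI_CODE
    if not tail:
        return AMI_OTHER_CODE
    fourth = tail[0]
    if fourth in "0123456":
        return STEMI_CODED
    if fourth in "79":
        return NSTEMI_CODED
    return AMI_OTHER_CODE  # 410.8x


def is_ami_code(icd_code: str) -> bool:
    """True for any code in the 410.xx family (including 410.8)."""
    return code_implied_type(icd_code) != NOT_AMI_CODE


def first_ami_code(diagnoses: Sequence[str]) -> Optional[str]:
    """Highest-positioned 410-family code of a diagnosis list, if any."""
    for code in diagnoses:
        if is_ami_code(code):
            return code
    return None


@dataclass(frozen=True)
class TypeCodingAccuracy:
    """Fraction of ECG-typed confirmed cases whose claims code agrees."""

    n_stemi: int
    n_stemi_correct: int
    n_nstemi: int
    n_nstemi_correct: int

    @property
    def stemi_accuracy(self) -> Optional[float]:
        return self.n_stemi_correct / self.n_stemi if self.n_stemi else None

    @property
    def nstemi_accuracy(self) -> Optional[float]:
        return self.n_nstemi_correct / self.n_nstemi if self.n_nstemi else None


def type_coding_accuracy(cases: Sequence[LinkedCase]) -> TypeCodingAccuracy:
    """Per-type claims-coding accuracy among adjudicated confirmed cases.

    Confirmed cases typed ``unspecified`` are excluded from both
    denominators.  The claims code considered is the highest-positioned
    410-family code.
    """
    ns = nsc = nn = nnc = 0
    for case in cases:
        adj = case.adjudication
        if adj is None:
            raise ValueError(f"case {case.case_id} has no adjudication result")
        if not adj.confirmed or adj.mi_type not in (STEMI, NSTEMI):
            continue
        code = first_ami_code(case.claims.diagnoses)
        implied = code_implied_type(code) if code is not None else NOT_AMI_CODE
        if adj.mi_type == STEMI:
            ns += 1
            nsc += implied == STEMI_CODED
        else:
            nn += 1
            nnc += implied == NSTEMI_CODED
    return TypeCodingAccuracy(ns, nsc, nn, nnc)


@dataclass(frozen=True)
class AgreementResult:
    agreement_rate: float
    final: tuple[bool, ...]


def reviewer_agreement(
    review_a: Sequence[bool],
    review_b: Sequence[bool],
    consensus: Sequence[bool],
) -> AgreementResult:
    """Raw two-reviewer agreement with third-party consensus resolution.

    ``final[i]`` is the agreed call where the reviewers concur, otherwise the
    consensus call reached with the third expert.
    """
    if not (len(review_a) == len(review_b) == len(consensus)):
        raise ValueError(
            f"reviewer lists must align: {len(review_a)}, {len(review_b)}, {len(consensus)}"
        )
    if not review_a:
        raise ValueError("reviewer lists are empty")
    final = tuple(
        a if a == b else c for a, b, c in zip(review_a, review_b, consensus)
    )
    n_agree = sum(a == b for a, b in zip(review_a, review_b))
    return AgreementResult(agreement_rate=n_agree / len(review_a), final=final)
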
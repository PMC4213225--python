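"""Core record types and CSV interchange.

Two tabular extracts drive everything downstream: a claims-side encounter
table (NHIRD-like) and a chart-side table (DNMC-like).  Both carry the four
deterministic-linkage key fields (birth date, sex, admission date, discharge
date), an ordered list of up to five ICD-9-CM discharge diagnoses, recorded
procedures and drug exposures.  The chart side additionally carries the
structured adjudication evidence abstracted from the discharge note.

All tables are exchanged as plain CSV with the headers documented in
``docs/schemas.md``.  Blank cells mean "missing"; sets are serialised as
``|``-joined sorted tokens; booleans as ``1``/``0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace  # noqa: F401  (replace is part of the public surface)
from typing import Iterable, Optional, Sequence

import pandas as pd

MAX_DIAGNOSES = 5

# controlled vocabularies used throughout the pipeline
ASPIRIN = "aspirin"
CLOPIDOGREL = "clopidogrel"
HEPARIN = "heparin"
ANTIPLATELET_AGENTS = frozenset({ASPIRIN, CLOPIDOGREL})
ADMISSION_DRUGS = (ASPIRIN, CLOPIDOGREL, HEPARIN)
FIRST_VISIT_DRUGS = (ASPIRIN, CLOPIDOGREL)

CATHETERIZATION = "catheterization"
PTCA = "PTCA"
CABG = "CABG"
STENTING = "stenting"
PROCEDURES = (CATHETERIZATION, PTCA, CABG, STENTING)

# ECG finding vocabulary for chart evidence
ST_ELEVATION = "ST_elevation"
ST_DEPRESSION = "ST_depression_or_other_ischemia"
ECG_NONE = "none"
ECG_MISSING = "missing"
ECG_FINDINGS = (ST_ELEVATION, ST_DEPRESSION, ECG_NONE, ECG_MISSING)


def normalize_diagnoses(codes: Iterable[Optional[str]]) -> tuple[str, ...]:
    """Strip whitespace and drop blank slots; enforce the 5-slot limit.

    The dot form of ICD-9-CM codes is preserved and 4th/5th digits are never
    truncated (410.11 and 410.12 are distinct codes).
    """
    cleaned = tuple(c.strip() for c in codes if c is not None and c.strip())
    if len(cleaned) > MAX_DIAGNOSES:
        raise ValueError(
            f"diagnosis list has {len(cleaned)} codes; at most {MAX_DIAGNOSES} allowed"
        )
    return cleaned


@dataclass(frozen=True)
class ClaimsEncounter:
    """One claims-side hospitalization."""

    record_id: str
    birth_date: Optional[str] = None  # ISO-8601 date or None when missing
    sex: Optional[str] = None
    admission_date: Optional[str] = None
    discharge_date: Optional[str] = None
    diagnoses: tuple[str, ...] = ()
    procedures: frozenset[str] = frozenset()
    drugs_admission: frozenset[str] = frozenset()
    drugs_first_visit: frozenset[str] = frozenset()
    patient_id: Optional[str] = None


@dataclass(frozen=True)
class ChartEncounter:
    """One chart-side hospitalization with abstracted adjudication evidence.

    ``review_a``/``review_b`` are the two cardiologist reviewers' independent
    confirmed/not-confirmed calls when available; ``review_complete`` is False
    for charts that could not be fully reviewed (e.g. misplaced charts).
    """

    record_id: str
    birth_date: Optional[str] = None
    sex: Optional[str] = None
    admission_date: Optional[str] = None
    discharge_date: Optional[str] = None
    diagnoses: tuple[str, ...] = ()
    procedures: frozenset[str] = frozenset()
    drugs_admission: frozenset[str] = frozenset()
    drugs_first_visit: frozenset[str] = frozenset()
    patient_id: Optional[str] = None
    chest_discomfort: bool = False
    ecg_finding: str = ECG_MISSING
    marker_elevated: bool = False
    review_a: Optional[bool] = None
    review_b: Optional[bool] = None
    review_complete: bool = True

    def __post_init__(self) -> None:
        if self.ecg_finding not in ECG_FINDINGS:
            raise ValueError(
                f"record {self.record_id}: unknown ecg_finding {self.ecg_finding!r}; "
                f"expected one of {ECG_FINDINGS}"
            )


@dataclass
class LinkedCase:
    """A claims/chart pair surviving deterministic linkage."""

    case_id: str
    claims: ClaimsEncounter
    chart: ChartEncounter
    adjudication: Optional["object"] = None  # AdjudicationResult, set downstream

    @property
    def patient_id(self) -> str:
        """Patient identity for first-episode selection.

        Uses the generator/provider patient id when present; otherwise falls
        back to the (birth date, sex) pair — a documented limitation of
        pseudonymous extracts.
        """
        if self.claims.patient_id:
            return self.claims.patient_id
        return f"{self.claims.birth_date}|{self.claims.sex}"


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_KEY_COLS = ["record_id", "patient_id", "birth_date", "sex", "admission_date", "discharge_date"]
_DX_COLS = [f"dx{i}" for i in range(1, MAX_DIAGNOSES + 1)]
_SET_COLS = ["procedures", "drugs_admission", "drugs_first_visit"]
_CHART_EXTRA = ["chest_discomfort", "ecg_finding", "marker_elevated", "review_a", "review_b", "review_complete"]

CLAIMS_COLUMNS = _KEY_COLS + _DX_COLS + _SET_COLS
CHART_COLUMNS = CLAIMS_COLUMNS + _CHART_EXTRA


def _fmt_set(s: frozenset[str]) -> str:
    return "|".join(sorted(s))


def _parse_set(s: str) -> frozenset[str]:
    return frozenset(t for t in s.split("|") if t) if s else frozenset()


def _fmt_bool(b: Optional[bool]) -> str:
    return "" if b is None else ("1" if b else "0")


def _parse_bool(s: str, *, default: Optional[bool] = None) -> Optional[bool]:
    if s == "":
        return default
    if s in ("1", "true", "True"):
        return True
    if s in ("0", "false", "False"):
        return False
    raise ValueError(f"cannot parse boolean cell {s!r}")


def _common_row(enc: ClaimsEncounter | ChartEncounter) -> dict:
    row = {
        "record_id": enc.record_id,
        "patient_id": enc.patient_id or "",
        "birth_date": enc.birth_date or "",
        "sex": enc.sex or "",
        "admission_date": enc.admission_date or "",
        "discharge_date": enc.discharge_date or "",
    }
    for i, col in enumerate(_DX_COLS):
        row[col] = enc.diagnoses[i] if i < len(enc.diagnoses) else ""
    row["procedures"] = _fmt_set(enc.procedures)
    row["drugs_admission"] = _fmt_set(enc.drugs_admission)
    row["drugs_first_visit"] = _fmt_set(enc.drugs_first_visit)
    return row


def claims_to_frame(claims: Sequence[ClaimsEncounter]) -> pd.DataFrame:
    return pd.DataFrame([_common_row(c) for c in claims], columns=CLAIMS_COLUMNS)


def charts_to_frame(charts: Sequence[ChartEncounter]) -> pd.DataFrame:
    rows = []
    for c in charts:
        row = _common_row(c)
        row["chest_discomfort"] = _fmt_bool(c.chest_discomfort)
        row["ecg_finding"] = c.ecg_finding
        row["marker_elevated"] = _fmt_bool(c.marker_elevated)
        row["review_a"] = _fmt_bool(c.review_a)
        row["review_b"] = _fmt_bool(c.review_b)
        row["review_complete"] = _fmt_bool(c.review_complete)
        rows.append(row)
    return pd.DataFrame(rows, columns=CHART_COLUMNS)


def _common_kwargs(row: pd.Series) -> dict:
    return dict(
        record_id=row["record_id"],
        patient_id=row["patient_id"] or None,
        birth_date=row["birth_date"] or None,
        sex=row["sex"] or None,
        admission_date=row["admission_date"] or None,
        discharge_date=row["discharge_date"] or None,
        diagnoses=normalize_diagnoses(row[c] for c in _DX_COLS),
        procedures=_parse_set(row["procedures"]),
        drugs_admission=_parse_set(row["drugs_admission"]),
        drugs_first_visit=_parse_set(row["drugs_first_visit"]),
    )


def frame_to_claims(df: pd.DataFrame) -> list[ClaimsEncounter]:
    return [ClaimsEncounter(**_common_kwargs(row)) for _, row in df.iterrows()]


def frame_to_charts(df: pd.DataFrame) -> list[ChartEncounter]:
    out = []
    for _, row in df.iterrows():
        out.append(
            ChartEncounter(
                **_common_kwargs(row),
                chest_discomfort=bool(_parse_bool(row["chest_discomfort"], default=False)),
                ecg_finding=row["ecg_finding"] or ECG_MISSING,
                marker_elevated=bool(_parse_bool(row["marker_elevated"], default=False)),
                review_a=_parse_bool(row["review_a"]),
                review_b=_parse_bool(row["review_b"]),
                review_complete=bool(_parse_bool(row["review_complete"], default=True)),
            )
        )
    return out


def read_table(path) -> pd.DataFrame:
    """Read an interchange CSV with every cell as a string, blank = missing."""
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
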
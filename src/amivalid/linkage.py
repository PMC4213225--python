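"""Deterministic record linkage on {birth date, sex, admission, discharge}.

Claims and chart encounters are matched exactly on the four-field composite
key.  Two exclusion rules apply before any pairing: records whose complete
key is shared by two or more records on their own side are ambiguous and
excluded (such cases cannot be attributed to a single patient), and records
missing any of the four fields are excluded.  Pairs form only between keys
that are unique on both sides; a unique key with no counterpart is an
unmatched residual.  When a patient has several linked hospitalizations,
only the first episode (earliest admission) is retained.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

from .records import ChartEncounter, ClaimsEncounter, LinkedCase

CLAIMS_SIDE = "claims"
CHART_SIDE = "chart"

_SEX_MAP = {
    "m": "M", "male": "M", "1": "M",
    "f": "F", "female": "F", "2": "F",
}


class KeyParseError(ValueError):
    """A linkage key field could not be parsed."""


def normalize_sex(value: str, record_id: str = "?") -> str:
    try:
        return _SEX_MAP[value.strip().lower()]
    except KeyError:
        raise KeyParseError(f"record {record_id}, column sex: cannot normalize {value!r}") from None


def _parse_date(value: str, record_id: str, column: str) -> date:
    try:
        return date.fromisoformat(value.strip())
    except ValueError:
        raise KeyParseError(
            f"record {record_id}, column {column}: malformed date {value!r}"
        ) from None


@dataclass(frozen=True)
class LinkKey:
    birth_date: date
    sex: str
    admission_date: date
    discharge_date: date


def build_key(record: ClaimsEncounter | ChartEncounter) -> Optional[LinkKey]:
    """Composite key of a record, or None when any field is blank.

    Raises :class:`KeyParseError` for malformed dates or sex values, or when
    admission postdates discharge.
    """
    raw = (record.birth_date, record.sex, record.admission_date, record.discharge_date)
    if any(v is None or not str(v).strip() for v in raw):
        return None
    key = LinkKey(
        birth_date=_parse_date(record.birth_date, record.record_id, "birth_date"),
        sex=normalize_sex(record.sex, record.record_id),
        admission_date=_parse_date(record.admission_date, record.record_id, "admission_date"),
        discharge_date=_parse_date(record.discharge_date, record.record_id, "discharge_date"),
    )
    if key.admission_date > key.discharge_date:
        raise KeyParseError(
            f"record {record.record_id}: admission_date {record.admission_date} "
            f"after discharge_date {record.discharge_date}"
        )
    return key


@dataclass
class LinkResult:
    """Accounting of one linkage run; every input record lands in exactly one
    of linked / excluded_ambiguous / excluded_missing / unmatched."""

    linked: list[LinkedCase] = field(default_factory=list)
    excluded_ambiguous: list[tuple[str, str]] = field(default_factory=list)  # (side, record_id)
    excluded_missing: list[tuple[str, str]] = field(default_factory=list)
    unmatched: list[tuple[str, str]] = field(default_factory=list)
    n_claims_input: int = 0
    n_charts_input: int = 0

    @property
    def linkage_rate(self) -> Optional[float]:
        """Linked cases over claims input (the denominator of the matching rate)."""
        return len(self.linked) / self.n_claims_input if self.n_claims_input else None


def link_records(
    claims: Sequence[ClaimsEncounter], charts: Sequence[ChartEncounter]
) -> LinkResult:
    result = LinkResult(n_claims_input=len(claims), n_charts_input=len(charts))

    def index(side: str, records) -> dict[LinkKey, list]:
        by_key: dict[LinkKey, list] = defaultdict(list)
        for rec in records:
            key = build_key(rec)
            if key is None:
                result.excluded_missing.append((side, rec.record_id))
            else:
                by_key[key].append(rec)
        return by_key

    claims_by_key = index(CLAIMS_SIDE, claims)
    charts_by_key = index(CHART_SIDE, charts)

    for side, by_key in ((CLAIMS_SIDE, claims_by_key), (CHART_SIDE, charts_by_key)):
        for key, recs in by_key.items():
            if len(recs) > 1:
                for rec in recs:
                    result.excluded_ambiguous.append((side, rec.record_id))

    for key, recs in claims_by_key.items():
        if len(recs) != 1:
            continue
        counterpart = charts_by_key.get(key, [])
        if len(counterpart) == 1:
            claim, chart = recs[0], counterpart[0]
            result.linked.append(LinkedCase(case_id=claim.record_id, claims=claim, chart=chart))
        else:
            # no counterpart, or the chart-side key is ambiguous
            result.unmatched.append((CLAIMS_SIDE, recs[0].record_id))
    for key, recs in charts_by_key.items():
        if len(recs) == 1 and len(claims_by_key.get(key, [])) != 1:
            result.unmatched.append((CHART_SIDE, recs[0].record_id))
    return result


class FirstEpisodeTieError(ValueError):
    """Two episodes of one patient share the same admission date."""


def select_first_episode(
    linked: Sequence[LinkedCase], tie_keep_one: bool = False
) -> tuple[list[LinkedCase], list[tuple[str, str]]]:
    """Keep each patient's earliest admission; report later episodes.

    Returns the retained cases (input order preserved) and the list of
    (kept case id, dropped case id) pairs.  A tie on admission date raises
    :class:`FirstEpisodeTieError` unless ``tie_keep_one`` is set, in which
    case the lexicographically first case id is kept.
    """
    by_patient: dict[str, list[LinkedCase]] = defaultdict(list)
    for case in linked:
        by_patient[case.patient_id].append(case)

    keep: dict[str, LinkedCase] = {}
    repeats: list[tuple[str, str]] = []
    for patient, cases in by_patient.items():
        def adm(c: LinkedCase) -> date:
            key = build_key(c.claims)
            if key is None:
                raise ValueError(f"case {c.case_id}: cannot order episodes without admission date")
            return key.admission_date

        ordered = sorted(cases, key=lambda c: (adm(c), c.case_id))
        if len(ordered) > 1 and adm(ordered[0]) == adm(ordered[1]) and not tie_keep_one:
            raise FirstEpisodeTieError(
                f"patient {patient}: episodes {ordered[0].case_id} and {ordered[1].case_id} "
                "share the same admission date (pass tie_keep_one to keep the first id)"
            )
        keep[ordered[0].case_id] = ordered[0]
        repeats.extend((ordered[0].case_id, later.case_id) for later in ordered[1:])

    kept = [c for c in linked if c.case_id in keep]
    return kept, repeats
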
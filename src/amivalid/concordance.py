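"""Order-sensitive concordance of discharge-diagnosis lists.

Claims reimbursement allows up to five discharge diagnoses per admission;
slot 1 is the principal diagnosis.  A claims/chart pair is consistent only
when the two code lists are identical position by position and equal in
length — two lists holding the same codes in a different order are
discordant.  Discordant pairs are classified by what broke:

* ``order_only`` — same multiset of codes, different order;
* ``code_absent_one_side`` — one list's codes are a strict sub-multiset of
  the other's (a diagnosis recorded on only one side, whether or not the
  shorter list is a prefix);
* ``code_substituted`` — equal length but different codes somewhere;
* ``length_differs`` — different lengths with discrepancies on both sides.

Codes are compared literally after whitespace stripping: the dot form is
preserved and 4th/5th digits matter (410.11 vs 410.12 is a substitution,
never a match).  Semantically equivalent codes are never reconciled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .records import normalize_diagnoses

ORDER_ONLY = "order_only"
CODE_ABSENT_ONE_SIDE = "code_absent_one_side"
CODE_SUBSTITUTED = "code_substituted"
LENGTH_DIFFERS = "length_differs"


@dataclass(frozen=True)
class DiscordanceRecord:
    case_id: str
    claims_codes: tuple[str, ...]
    chart_codes: tuple[str, ...]
    first_mismatch_position: int  # 1-based, matching the principal-diagnosis convention
    mismatch_kind: str


def compare_lists(
    claims_codes: Sequence[str],
    chart_codes: Sequence[str],
    case_id: str = "",
) -> tuple[bool, Optional[DiscordanceRecord]]:
    """Position-by-position comparison of two diagnosis lists.

    Returns (True, None) for consistent pairs, otherwise (False, record)
    with the first mismatching 1-based position and the mismatch kind.
    """
    a = normalize_diagnoses(claims_codes)
    b = normalize_diagnoses(chart_codes)
    if a == b:
        return True, None

    position = next(
        (i + 1 for i in range(min(len(a), len(b))) if a[i] != b[i]),
        min(len(a), len(b)) + 1,  # one list is a proper prefix of the other
    )
    ca, cb = Counter(a), Counter(b)
    if ca == cb:
        kind = ORDER_ONLY
    elif not (ca - cb) or not (cb - ca):
        kind = CODE_ABSENT_ONE_SIDE
    elif len(a) == len(b):
        kind = CODE_SUBSTITUTED
    else:
        kind = LENGTH_DIFFERS
    return False, DiscordanceRecord(
        case_id=case_id,
        claims_codes=a,
        chart_codes=b,
        first_mismatch_position=position,
        mismatch_kind=kind,
    )


def consistency_rate(
    pairs: Sequence[tuple[Sequence[str], Sequence[str]]],
    case_ids: Optional[Sequence[str]] = None,
) -> tuple[float, list[DiscordanceRecord]]:
    """Fraction of consistent pairs plus the sorted discordance report.

    ``case_ids`` defaults to 1-based positional ids; the report is sorted by
    case id.
    """
    if not pairs:
        raise ValueError("consistency_rate requires at least one pair")
    if case_ids is None:
        case_ids = [str(i + 1) for i in range(len(pairs))]
    if len(case_ids) != len(pairs):
        raise ValueError(f"case_ids must align with pairs: {len(case_ids)} vs {len(pairs)}")

    records = []
    n_ok = 0
    for cid, (claims_codes, chart_codes) in zip(case_ids, pairs):
        ok, rec = compare_lists(claims_codes, chart_codes, case_id=cid)
        if ok:
            n_ok += 1
        else:
            records.append(rec)
    records.sort(key=lambda r: r.case_id)
    return n_ok / len(pairs), records
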
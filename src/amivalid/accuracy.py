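"""Diagnostic accuracy: 2x2 tables, exact binomial intervals, case definitions.

Sensitivity is the probability that an item recorded in the chart (the gold
standard) is also recorded in the claims; PPV the probability that a claims
record is truly present in the chart.  Confidence intervals for binomial
proportions are Clopper-Pearson exact intervals: the method reproduces the
printed interval for small numerators (22/24 -> 0.73-0.99) where a Wald
interval would overshoot 1.

Case definitions combine the position of the AMI code (any slot versus the
principal, first-listed slot) with required drug and procedure claims, and
are scored against chart adjudication: sensitivity over all confirmed cases,
PPV over all claims-positive cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional, Sequence

from pydantic import BaseModel
from scipy.stats import beta as beta_dist

from .records import ANTIPLATELET_AGENTS, CATHETERIZATION, HEPARIN, PTCA, LinkedCase
from .adjudication import first_ami_code, is_ami_code


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for report display (3 dp internal
    values like 0.955 display as 0.96, not banker's 0.96/0.95 ambiguity)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwo:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def two_by_two(claims_flags: Sequence[bool], chart_flags: Sequence[bool]) -> TwoByTwo:
    """Cross-tabulate aligned claims/chart indicator lists."""
    if len(claims_flags) != len(chart_flags):
        raise ValueError(
            f"flag lists must align: {len(claims_flags)} vs {len(chart_flags)}"
        )
    tp = fp = fn = tn = 0
    for c, g in zip(claims_flags, chart_flags):
        if c and g:
            tp += 1
        elif c and not g:
            fp += 1
        elif not c and g:
            fn += 1
        else:
            tn += 1
    return TwoByTwo(tp, fp, fn, tn)


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval via beta quantiles.

    The lower bound is 0 when ``successes`` is 0 and the upper bound 1 when
    ``successes`` equals ``n`` (the tail inversions are degenerate there).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {successes}")
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(beta_dist.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(beta_dist.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


@dataclass(frozen=True)
class MetricEstimate:
    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int


@dataclass(frozen=True)
class AccuracyStats:
    sensitivity: Optional[MetricEstimate]
    specificity: Optional[MetricEstimate]
    ppv: Optional[MetricEstimate]
    npv: Optional[MetricEstimate]
    level: float = 0.95


def _estimate(k: int, n: int, level: float) -> Optional[MetricEstimate]:
    if n == 0:
        return None
    low, high = exact_binomial_ci(k, n, level)
    return MetricEstimate(value=k / n, ci_low=low, ci_high=high, numerator=k, denominator=n)


def accuracy(table: TwoByTwo, level: float = 0.95) -> AccuracyStats:
    """Sensitivity, specificity, PPV and NPV with exact intervals.

    A metric whose denominator is zero is returned as None; the others are
    still computed.
    """
    if table.n == 0:
        raise ValueError("cannot compute statistics on an empty 2x2 table")
    return AccuracyStats(
        sensitivity=_estimate(table.tp, table.tp + table.fn, level),
        specificity=_estimate(table.tn, table.tn + table.fp, level),
        ppv=_estimate(table.tp, table.tp + table.fp, level),
        npv=_estimate(table.tn, table.tn + table.fn, level),
        level=level,
    )


class CaseDefinition(BaseModel):
    """A claims-side rule for identifying AMI hospitalizations.

    The 410-family code requirement is always present; ``position`` says
    whether any diagnosis slot qualifies or only the principal (first)
    slot.  Exposure requirements are evaluated against the claims record:
    antiplatelet means aspirin or clopidogrel at admission.
    """

    label: str = ""
    position: Literal["any", "principal"] = "any"
    require_antiplatelet: bool = False
    require_heparin: bool = False
    require_catheterization: bool = False
    require_ptca: bool = False

    def matches(self, claims) -> bool:
        dx = claims.diagnoses
        if self.position == "principal":
            if not dx or not is_ami_code(dx[0]):
                return False
        else:
            if first_ami_code(dx) is None:
                return False
        if self.require_antiplatelet and not (claims.drugs_admission & ANTIPLATELET_AGENTS):
            return False
        if self.require_heparin and HEPARIN not in claims.drugs_admission:
            return False
        if self.require_catheterization and CATHETERIZATION not in claims.procedures:
            return False
        if self.require_ptca and PTCA not in claims.procedures:
            return False
        return True


@dataclass(frozen=True)
class CaseDefinitionResult:
    label: str
    n_claims_positive: int
    n_true_positive: int  # claims-positive AND chart-confirmed
    n_confirmed: int
    sensitivity: Optional[float]
    ppv: Optional[float]


def evaluate_case_definition(
    defn: CaseDefinition, cases: Sequence[LinkedCase]
) -> CaseDefinitionResult:
    """Score one case definition against adjudicated truth.

    Sensitivity = true positives / all chart-confirmed cases; PPV = true
    positives / claims-positive cases.  Either is None when its denominator
    is empty.
    """
    n_pos = n_true = n_conf = 0
    for case in cases:
        if case.adjudication is None:
            raise ValueError(f"case {case.case_id} has no adjudication result")
        pos = defn.matches(case.claims)
        conf = case.adjudication.confirmed
        n_pos += pos
        n_conf += conf
        n_true += pos and conf
    return CaseDefinitionResult(
        label=defn.label,
        n_claims_positive=n_pos,
        n_true_positive=n_true,
        n_confirmed=n_conf,
        sensitivity=(n_true / n_conf) if n_conf else None,
        ppv=(n_true / n_pos) if n_pos else None,
    )
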
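"""End-to-end orchestration: simulate -> link -> adjudicate -> validate -> report.

The pipeline mirrors the accounting of a claims-validation study flow chart:
claims and chart encounters extracted, deterministically linked, first
episodes selected, charts reviewed (WHO adjudication), case definitions and
per-item agreement validated, and discharge-diagnosis concordance reported.
Every stage writes a plain CSV/JSON artifact into the run directory and the
manifest records per-stage row counts and output digests so a rerun with the
same config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import records
from .accuracy import (
    AccuracyStats,
    CaseDefinition,
    CaseDefinitionResult,
    accuracy,
    evaluate_case_definition,
    round_half_up,
    two_by_two,
)
from .adjudication import (
    AdjudicationResult,
    NOT_AMI_CODE,
    NSTEMI_CODED,
    STEMI_CODED,
    adjudicate,
    code_implied_type,
    evidence_from_chart,
    first_ami_code,
    reviewer_agreement,
    type_coding_accuracy,
)
from .concordance import consistency_rate
from .linkage import LinkResult, link_records, select_first_episode
from .records import (
    ADMISSION_DRUGS,
    FIRST_VISIT_DRUGS,
    PROCEDURES,
    ChartEncounter,
    ClaimsEncounter,
    LinkedCase,
    charts_to_frame,
    claims_to_frame,
    frame_to_charts,
    frame_to_claims,
    read_table,
    write_table,
)
from .synthetic import Cohort, GeneratorConfig, generate_cohort, truth_to_frame

SCHEMA_VERSION = "1"

DEFAULT_DEFINITIONS: list[CaseDefinition] = [
    CaseDefinition(label="any 410 + antiplatelet", position="any", require_antiplatelet=True),
    CaseDefinition(
        label="any 410 + heparin + antiplatelet",
        position="any", require_antiplatelet=True, require_heparin=True,
    ),
    CaseDefinition(label="principal 410", position="principal"),
    CaseDefinition(
        label="principal 410 + antiplatelet", position="principal", require_antiplatelet=True
    ),
    CaseDefinition(
        label="principal 410 + heparin + antiplatelet",
        position="principal", require_antiplatelet=True, require_heparin=True,
    ),
    CaseDefinition(
        label="principal 410 + catheterization",
        position="principal", require_catheterization=True,
    ),
    CaseDefinition(label="principal 410 + PTCA", position="principal", require_ptca=True),
]


def validated_items() -> list[str]:
    """Item names validated claims-vs-chart in the agreement table."""
    return (
        list(PROCEDURES)
        + [f"{d}_admission" for d in ADMISSION_DRUGS if d != "heparin"]
        + [f"{d}_first_visit" for d in FIRST_VISIT_DRUGS]
    )


def _item_flag(enc: ClaimsEncounter | ChartEncounter, item: str) -> bool:
    if item.endswith("_admission"):
        return item.removesuffix("_admission") in enc.drugs_admission
    if item.endswith("_first_visit"):
        return item.removesuffix("_first_visit") in enc.drugs_first_visit
    return item in enc.procedures


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs of the run were removed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# linked / adjudicated interchange frames
# ---------------------------------------------------------------------------


def linked_to_frame(cases: Sequence[LinkedCase]) -> pd.DataFrame:
    base = pd.DataFrame({"case_id": [c.case_id for c in cases]}, dtype=str)
    cf = claims_to_frame([c.claims for c in cases]).add_prefix("claims_")
    hf = charts_to_frame([c.chart for c in cases]).add_prefix("chart_")
    if not cases:
        cf = pd.DataFrame(columns=["claims_" + c for c in records.CLAIMS_COLUMNS])
        hf = pd.DataFrame(columns=["chart_" + c for c in records.CHART_COLUMNS])
    return pd.concat([base, cf, hf], axis=1)


def frame_to_linked(df: pd.DataFrame) -> list[LinkedCase]:
    claims_cols = {c: c.removeprefix("claims_") for c in df.columns if c.startswith("claims_")}
    chart_cols = {c: c.removeprefix("chart_") for c in df.columns if c.startswith("chart_")}
    claims = frame_to_claims(df[list(claims_cols)].rename(columns=claims_cols))
    charts = frame_to_charts(df[list(chart_cols)].rename(columns=chart_cols))
    out = []
    for cid, cl, ch in zip(df["case_id"], claims, charts):
        out.append(LinkedCase(case_id=cid, claims=cl, chart=ch))
    return out


_ADJ_COLS = ["confirmed", "n_criteria_met", "mi_type", "code_implied_type", "concordant_type"]


def adjudicated_to_frame(cases: Sequence[LinkedCase]) -> pd.DataFrame:
    df = linked_to_frame(cases)
    rows = {c: [] for c in _ADJ_COLS}
    for case in cases:
        adj = case.adjudication
        code = first_ami_code(case.claims.diagnoses)
        implied = code_implied_type(code) if code else NOT_AMI_CODE
        concordant = (adj.mi_type == "STEMI" and implied == STEMI_CODED) or (
            adj.mi_type == "NSTEMI" and implied == NSTEMI_CODED
        )
        rows["confirmed"].append("1" if adj.confirmed else "0")
        rows["n_criteria_met"].append(str(adj.n_criteria_met))
        rows["mi_type"].append(adj.mi_type)
        rows["code_implied_type"].append(implied)
        rows["concordant_type"].append("1" if concordant else "0")
    for col in _ADJ_COLS:
        df[col] = rows[col]
    return df


def frame_to_adjudicated(df: pd.DataFrame) -> list[LinkedCase]:
    cases = frame_to_linked(df)
    for case, (_, row) in zip(cases, df.iterrows()):
        case.adjudication = AdjudicationResult(
            confirmed=row["confirmed"] == "1",
            n_criteria_met=int(row["n_criteria_met"]),
            mi_type=row["mi_type"],
        )
    return cases


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _fmt(v: Optional[float]) -> str:
    return "" if v is None else f"{v:.6f}"


def table1_frame(results: Sequence[CaseDefinitionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "criteria": r.label,
                "n_claims_positive": r.n_claims_positive,
                "n_true_positive": r.n_true_positive,
                "n_confirmed": r.n_confirmed,
                "sensitivity": _fmt(r.sensitivity),
                "ppv": _fmt(r.ppv),
            }
            for r in results
        ],
        columns=["criteria", "n_claims_positive", "n_true_positive", "n_confirmed", "sensitivity", "ppv"],
    )


def table2_frame(stats: dict[str, tuple["object", AccuracyStats]]) -> pd.DataFrame:
    rows = []
    for item, (tab, st) in stats.items():
        row = {"item": item, "tp": tab.tp, "fp": tab.fp, "fn": tab.fn, "tn": tab.tn}
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            est = getattr(st, metric)
            row[metric] = _fmt(est.value if est else None)
            row[f"{metric}_ci_low"] = _fmt(est.ci_low if est else None)
            row[f"{metric}_ci_high"] = _fmt(est.ci_high if est else None)
        rows.append(row)
    cols = ["item", "tp", "fp", "fn", "tn"] + [
        f"{m}{s}" for m in ("sensitivity", "specificity", "ppv", "npv")
        for s in ("", "_ci_low", "_ci_high")
    ]
    return pd.DataFrame(rows, columns=cols)


def run_stages(
    claims: Sequence[ClaimsEncounter],
    charts: Sequence[ChartEncounter],
    outdir,
    definitions: Optional[Sequence[CaseDefinition]] = None,
    level: float = 0.95,
    tie_keep_one: bool = False,
) -> dict:
    """Link, adjudicate, validate and report; returns the summary dict.

    Writes linked.csv, exclusions.csv, linkage_summary.json,
    adjudicated.csv, table1.csv, table2.csv, concordance.csv,
    concordance_summary.json and summary.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    definitions = list(DEFAULT_DEFINITIONS if definitions is None else definitions)

    # --- link -------------------------------------------------------------
    result: LinkResult = link_records(claims, charts)
    kept, repeats = select_first_episode(result.linked, tie_keep_one=tie_keep_one)
    reviewed = [c for c in kept if c.chart.review_complete]
    for case in reviewed:
        case.adjudication = adjudicate(evidence_from_chart(case.chart))

    excl_rows = (
        [{"record_id": rid, "side": side, "reason": "ambiguous_key"} for side, rid in result.excluded_ambiguous]
        + [{"record_id": rid, "side": side, "reason": "missing_key"} for side, rid in result.excluded_missing]
        + [{"record_id": rid, "side": side, "reason": "unmatched"} for side, rid in result.unmatched]
        + [{"record_id": dropped, "side": "claims", "reason": f"repeat_episode_of_{first}"}
           for first, dropped in repeats]
        + [{"record_id": c.chart.record_id, "side": "chart", "reason": "review_incomplete"}
           for c in kept if not c.chart.review_complete]
    )
    write_table(pd.DataFrame(excl_rows, columns=["record_id", "side", "reason"]), outdir / "exclusions.csv")
    write_table(linked_to_frame(kept), outdir / "linked.csv")

    linkage_summary = {
        "n_claims_extracted": result.n_claims_input,
        "n_charts_extracted": result.n_charts_input,
        "n_excluded_ambiguous": len(result.excluded_ambiguous),
        "n_excluded_missing": len(result.excluded_missing),
        "n_unmatched": len(result.unmatched),
        "n_repeat_episodes_excluded": len(repeats),
        "n_linked": len(kept),
        "n_review_complete": len(reviewed),
        "linkage_rate": result.linkage_rate,
    }
    (outdir / "linkage_summary.json").write_text(json.dumps(linkage_summary, indent=2))

    # --- adjudicate -------------------------------------------------------
    write_table(adjudicated_to_frame(reviewed), outdir / "adjudicated.csv")
    n_confirmed = sum(c.adjudication.confirmed for c in reviewed)

    confirmed_cases = [c for c in reviewed if c.adjudication.confirmed]
    evidence_marginals = None
    if confirmed_cases:
        evidence_marginals = {
            "chest_discomfort": sum(c.chart.chest_discomfort for c in confirmed_cases) / len(confirmed_cases),
            "ecg_ischemia": sum(
                c.chart.ecg_finding in ("ST_elevation", "ST_depression_or_other_ischemia")
                for c in confirmed_cases
            ) / len(confirmed_cases),
            "marker_elevated": sum(c.chart.marker_elevated for c in confirmed_cases) / len(confirmed_cases),
        }

    type_acc = type_coding_accuracy(reviewed) if reviewed else None

    with_reviews = [c for c in reviewed if c.chart.review_a is not None and c.chart.review_b is not None]
    agreement = None
    if with_reviews:
        agreement = reviewer_agreement(
            [c.chart.review_a for c in with_reviews],
            [c.chart.review_b for c in with_reviews],
            [c.adjudication.confirmed for c in with_reviews],
        ).agreement_rate

    # --- validate ---------------------------------------------------------
    any_pos = evaluate_case_definition(CaseDefinition(label="any 410", position="any"), reviewed) if reviewed else None
    principal = (
        evaluate_case_definition(CaseDefinition(label="principal 410", position="principal"), reviewed)
        if reviewed else None
    )
    table1 = [evaluate_case_definition(d, reviewed) for d in definitions] if reviewed else []
    write_table(table1_frame(table1), outdir / "table1.csv")

    table2: dict = {}
    if reviewed:
        for item in validated_items():
            tab = two_by_two(
                [_item_flag(c.claims, item) for c in reviewed],
                [_item_flag(c.chart, item) for c in reviewed],
            )
            table2[item] = (tab, accuracy(tab, level))
    write_table(table2_frame(table2), outdir / "table2.csv")

    # --- concordance ------------------------------------------------------
    if reviewed:
        rate, discords = consistency_rate(
            [(c.claims.diagnoses, c.chart.diagnoses) for c in reviewed],
            case_ids=[c.case_id for c in reviewed],
        )
    else:
        rate, discords = None, []
    write_table(
        pd.DataFrame(
            [
                {
                    "case_id": r.case_id,
                    "first_mismatch_position": r.first_mismatch_position,
                    "mismatch_kind": r.mismatch_kind,
                    "claims_codes": "|".join(r.claims_codes),
                    "chart_codes": "|".join(r.chart_codes),
                }
                for r in discords
            ],
            columns=["case_id", "first_mismatch_position", "mismatch_kind", "claims_codes", "chart_codes"],
        ),
        outdir / "concordance.csv",
    )
    concordance_summary = {
        "n": len(reviewed),
        "n_consistent": (len(reviewed) - len(discords)) if reviewed else 0,
        "rate": rate,
    }
    (outdir / "concordance_summary.json").write_text(json.dumps(concordance_summary, indent=2))

    summary = {
        "flow": linkage_summary,
        "n_confirmed": n_confirmed,
        "ppv_any_position": any_pos.ppv if any_pos else None,
        "sensitivity_any_position": any_pos.sensitivity if any_pos else None,
        "n_principal": principal.n_claims_positive if principal else None,
        "n_principal_confirmed": principal.n_true_positive if principal else None,
        "ppv_principal": principal.ppv if principal else None,
        "reviewer_agreement": agreement,
        "evidence_marginals_confirmed": evidence_marginals,
        "stemi_code_accuracy": type_acc.stemi_accuracy if type_acc else None,
        "nstemi_code_accuracy": type_acc.nstemi_accuracy if type_acc else None,
        "n_stemi": type_acc.n_stemi if type_acc else None,
        "n_nstemi": type_acc.n_nstemi if type_acc else None,
        "consistency_rate": rate,
        "n_discordant_lists": len(discords),
        "table1": [
            {
                "criteria": r.label,
                "n_claims_positive": r.n_claims_positive,
                "n_true_positive": r.n_true_positive,
                "sensitivity": r.sensitivity,
                "ppv": r.ppv,
            }
            for r in table1
        ],
        "table2": {
            item: {
                "counts": [tab.tp, tab.fp, tab.fn, tab.tn],
                **{
                    metric: (
                        None if getattr(st, metric) is None
                        else {
                            "value": getattr(st, metric).value,
                            "ci_low": getattr(st, metric).ci_low,
                            "ci_high": getattr(st, metric).ci_high,
                        }
                    )
                    for metric in ("sensitivity", "specificity", "ppv", "npv")
                },
            }
            for item, (tab, st) in table2.items()
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config, outdir, seed: Optional[int] = None) -> dict:
    """Simulate a cohort from ``config`` and run every downstream stage.

    ``config`` may be a :class:`GeneratorConfig` or a path to a JSON/YAML
    file; ``seed`` overrides the config seed.  Returns the run manifest
    (also written as manifest.json).  On stage failure all files written by
    this run are removed and :class:`StageError` is raised.
    """
    if not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.from_file(config)
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    artifacts = [
        "claims.csv", "charts.csv", "truth.csv", "linked.csv", "exclusions.csv",
        "linkage_summary.json", "adjudicated.csv", "table1.csv", "table2.csv",
        "concordance.csv", "concordance_summary.json", "summary.json",
    ]

    stage = "simulate"
    try:
        cohort: Cohort = generate_cohort(config)
        write_table(claims_to_frame(cohort.claims), outdir / "claims.csv")
        write_table(charts_to_frame(cohort.charts), outdir / "charts.csv")
        write_table(truth_to_frame(cohort.truth), outdir / "truth.csv")
        stage = "link/adjudicate/validate/report"
        summary = run_stages(cohort.claims, cohort.charts, outdir)
    except Exception as exc:
        for name in artifacts + ["manifest.json"]:
            (outdir / name).unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    from . import __version__

    manifest = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "counts": {
            "claims_extracted": summary["flow"]["n_claims_extracted"],
            "charts_extracted": summary["flow"]["n_charts_extracted"],
            "linked": summary["flow"]["n_linked"],
            "reviewed": summary["flow"]["n_review_complete"],
            "confirmed": summary["n_confirmed"],
        },
        "digests": {name: _sha256(outdir / name) for name in artifacts if (outdir / name).exists()},
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def summarize(outdir) -> tuple[str, dict]:
    """Headline metrics of a completed run as (text report, summary dict)."""
    outdir = Path(outdir)
    path = outdir / "summary.json"
    if not path.exists():
        raise FileNotFoundError(f"missing stage output: {path}")
    summary = json.loads(path.read_text())

    def pct(v: Optional[float]) -> str:
        return "absent" if v is None else f"{round_half_up(100 * v, 1)}%"

    def prop(v: Optional[float]) -> str:
        return "absent" if v is None else f"{round_half_up(v, 2):.2f}"

    flow = summary["flow"]
    lines = [
        "AMI claims-validation run summary",
        "=================================",
        f"claims extracted   : {flow['n_claims_extracted']}",
        f"charts extracted   : {flow['n_charts_extracted']}",
        f"linked             : {flow['n_linked']}  (linkage rate {pct(flow['linkage_rate'])})",
        f"chart review done  : {flow['n_review_complete']}",
        f"confirmed AMI      : {summary['n_confirmed']}",
        f"PPV (any position) : {prop(summary['ppv_any_position'])}",
        f"PPV (principal)    : {prop(summary['ppv_principal'])}"
        + (
            f"  ({summary['n_principal_confirmed']}/{summary['n_principal']})"
            if summary["n_principal"] else ""
        ),
        f"reviewer agreement : {pct(summary['reviewer_agreement'])}",
        f"diagnosis-list consistency : {pct(summary['consistency_rate'])}",
    ]
    if summary["table1"]:
        lines.append("")
        lines.append("case definitions (criteria | claims+ | confirmed+ | sens | PPV)")
        for row in summary["table1"]:
            lines.append(
                f"  {row['criteria']:<40} {row['n_claims_positive']:>5} {row['n_true_positive']:>5} "
                f"{prop(row['sensitivity']):>6} {prop(row['ppv']):>6}"
            )
    return "\n".join(lines), summary
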
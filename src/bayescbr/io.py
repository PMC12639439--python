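"""Readers, writers and the serialisable analysis report.

Patient records travel as two UTF-8 CSV files: a long-format evaluations
table (``patient_id, eval_day, recist_status``) and a per-patient events
table (``patient_id, inclusion_day, progression_day, discontinuation_day,
discontinuation_reason, death_day, last_contact_day``).  The design
configuration is YAML (or JSON, a YAML subset) with keys mirroring
:class:`~bayescbr.design.TrialDesign`, priors as ``{alpha, beta, label}``
mappings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .classify import CbrOutcome, ProportionEstimate
from .design import TrialDesign
from .priors import BetaParams, BinomialData, PosteriorSummary, as_percent
from .records import PatientRecord, RecordValidationError
from .survival import KmCurve, days_to_months

__all__ = [
    "read_patient_records",
    "write_patient_records",
    "read_design",
    "write_design",
    "AnalysisReport",
    "render_report",
]

EVAL_COLUMNS = ["patient_id", "eval_day", "recist_status"]
EVENT_COLUMNS = [
    "patient_id",
    "inclusion_day",
    "progression_day",
    "discontinuation_day",
    "discontinuation_reason",
    "death_day",
    "last_contact_day",
]


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_patient_records(
    evaluations_path, events_path
) -> list[PatientRecord]:
    """Load and validate records from the two-file CSV dialect.

    Validation failures are reported with the offending patient id and
    CSV row number.
    """
    evals = pd.read_csv(evaluations_path)
    events = pd.read_csv(events_path)
    missing = [c for c in EVAL_COLUMNS if c not in evals.columns]
    if missing:
        raise RecordValidationError(
            f"{evaluations_path}: missing columns {missing}"
        )
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise RecordValidationError(f"{events_path}: missing columns {missing}")
    if events["patient_id"].duplicated().any():
        dup = events.loc[events["patient_id"].duplicated(), "patient_id"]
        raise RecordValidationError(
            f"{events_path}: duplicated patient ids {sorted(set(dup))}"
        )

    by_patient: dict[str, list[tuple[float, str]]] = {}
    for i, row in evals.iterrows():
        pid = str(row["patient_id"])
        try:
            day = float(row["eval_day"])
        except (TypeError, ValueError) as exc:
            raise RecordValidationError(
                f"{evaluations_path} row {i + 2}: bad eval_day "
                f"{row['eval_day']!r}"
            ) from exc
        by_patient.setdefault(pid, []).append((day, str(row["recist_status"])))

    records = []
    for i, row in events.iterrows():
        pid = str(row["patient_id"])
        reason = row["discontinuation_reason"]
        try:
            records.append(
                PatientRecord(
                    patient_id=pid,
                    evaluations=tuple(by_patient.get(pid, [])),
                    progression_time=_opt(row["progression_day"]),
                    discontinuation_time=_opt(row["discontinuation_day"]),
                    discontinuation_reason=(
                        None if pd.isna(reason) else str(reason)
                    ),
                    death_time=_opt(row["death_day"]),
                    last_contact_time=float(row["last_contact_day"]),
                    inclusion_time=_opt(row["inclusion_day"]) or 0.0,
                )
            )
        except (RecordValidationError, TypeError, ValueError) as exc:
            raise RecordValidationError(
                f"{events_path} row {i + 2}: {exc}"
            ) from exc
    orphans = set(by_patient) - {r.patient_id for r in records}
    if orphans:
        raise RecordValidationError(
            f"{evaluations_path}: evaluations for unknown patients "
            f"{sorted(orphans)}"
        )
    return records


def write_patient_records(
    records: Sequence[PatientRecord], evaluations_path, events_path
) -> None:
    """Write records in the CSV dialect read by :func:`read_patient_records`."""
    eval_rows = [
        {"patient_id": r.patient_id, "eval_day": t, "recist_status": s}
        for r in records
        for t, s in r.evaluations
    ]
    pd.DataFrame(eval_rows, columns=EVAL_COLUMNS).to_csv(
        evaluations_path, index=False
    )
    event_rows = [
        {
            "patient_id": r.patient_id,
            "inclusion_day": r.inclusion_time,
            "progression_day": r.progression_time,
            "discontinuation_day": r.discontinuation_time,
            "discontinuation_reason": r.discontinuation_reason,
            "death_day": r.death_time,
            "last_contact_day": r.last_contact_time,
        }
        for r in records
    ]
    pd.DataFrame(event_rows, columns=EVENT_COLUMNS).to_csv(
        events_path, index=False
    )


def read_design(path) -> TrialDesign:
    """Load a trial design from YAML/JSON config."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "priors" in raw:
        raw["priors"] = tuple(
            BetaParams(p["alpha"], p["beta"], p.get("label", ""))
            for p in raw["priors"]
        )
    return TrialDesign(**raw)


def write_design(design: TrialDesign, path) -> None:
    payload = {
        "max_n": design.max_n,
        "p0": design.p0,
        "futility_threshold": design.futility_threshold,
        "priors": [
            {"alpha": p.alpha, "beta": p.beta, "label": p.label}
            for p in design.priors
        ],
        "decision_prior_label": design.decision_prior_label,
        "first_interim_n": design.first_interim_n,
        "interim_step": design.interim_step,
        "followup_weeks": design.followup_weeks,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_hash(payload: dict) -> str:
    """Stable hash of a configuration mapping (key order irrelevant)."""
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


@dataclass(frozen=True)
class AnalysisReport:
    """Everything one analysis produced, ready for serialisation."""

    cohort_summary: dict
    cbr: BinomialData
    outcomes: tuple[CbrOutcome, ...]
    posterior_summaries: tuple[PosteriorSummary, ...]
    orr: ProportionEstimate
    survival: dict  # endpoint -> KmCurve
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        surv = {}
        for name, curve in self.survival.items():
            lo, hi = curve.median_ci
            surv[name] = {
                "endpoint": name,
                "n": curve.n,
                "events": curve.n_events,
                "median_days": curve.median,
                "median_months": (
                    None if curve.median is None
                    else days_to_months(curve.median)
                ),
                "ci_low_months": None if lo is None else days_to_months(lo),
                "ci_high_months": None if hi is None else days_to_months(hi),
            }
        return {
            "cohort_summary": dict(self.cohort_summary),
            "cbr": {
                "successes": self.cbr.successes,
                "n": self.cbr.n,
                "outcomes": [
                    {
                        "patient_id": o.patient_id,
                        "label": o.label,
                        "rule_fired": o.rule_fired,
                        "best_response": o.best_response,
                    }
                    for o in self.outcomes
                ],
                "posteriors": [
                    s.as_record() for s in self.posterior_summaries
                ],
            },
            "orr": {
                "responders": self.orr.count,
                "denominator": self.orr.denominator,
                "proportion": self.orr.proportion,
                "ci_low": self.orr.ci_low,
                "ci_high": self.orr.ci_high,
            },
            "survival": surv,
            "provenance": dict(self.provenance),
        }


def render_report(report: AnalysisReport, format: str = "text") -> str:
    """Render an analysis report as display text or full-precision JSON.

    The text layout mirrors a trial efficacy table: success count,
    per-prior posterior mean with credible interval (display-rounded to
    one decimal), the best-response tally, the ORR, and survival medians.
    """
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")

    lines = ["Efficacy summary", "================", ""]
    lines.append(
        f"Clinical benefit (success): {report.cbr.successes}/{report.cbr.n}"
    )
    lines.append("Posterior CBR by prior distribution:")
    for s in report.posterior_summaries:
        lines.append(
            f"  {s.posterior.label:<30s} "
            f"{as_percent(s.mean):.1f} "
            f"({as_percent(s.ci_low):.1f}-{as_percent(s.ci_high):.1f})"
            f"   P(CBR<={s.p0:g}) = {s.futility_prob:.3f}"
        )
    lines.append("")
    lines.append("Best overall response:")
    for cat in ("CR", "PR", "SD", "PD", "NE"):
        n = report.cohort_summary.get(cat, 0)
        if n:
            lines.append(f"  {cat:<3s} {n}")
    lines.append(
        f"Objective response rate: {report.orr.count}/{report.orr.denominator}"
        f" = {as_percent(report.orr.proportion):.1f}% "
        f"(95% CI {as_percent(report.orr.ci_low):.1f}-"
        f"{as_percent(report.orr.ci_high):.1f})"
    )
    if report.survival:
        lines.append("")
        lines.append("Time-to-event endpoints (months):")
        for name, curve in report.survival.items():
            med = curve.median_months()
            lo, hi = curve.median_ci
            fmt = lambda v: (
                "NR" if v is None else f"{days_to_months(v):.1f}"
            )
            med_s = "NR" if med is None else f"{med:.1f}"
            lines.append(
                f"  {name:<4s} median {med_s} "
                f"(95% CI {fmt(lo)}-{fmt(hi)})  "
                f"events {curve.n_events}/{curve.n}"
            )
    return "\n".join(lines)
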
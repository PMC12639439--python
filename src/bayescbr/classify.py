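"""Patient-level clinical-benefit classification and response rates.

The primary endpoint counts a patient as a success when the best response
within 24 weeks is CR or PR, or when stable disease is durable (last
evaluation at >= 22 weeks with no progression, or progression only after
26 weeks).  The protocol expresses this as an ordered list of rules, here
labelled R1-R7; exactly one rule fires per classifiable patient.

R1 success  CR or PR as best response within 24 weeks.
-- for best response SD within 24 weeks --
R2 success  no progression, no definitive discontinuation for
            progression/death, and last evaluation >= 22 weeks.
R3 success  progression documented strictly after 26 weeks.
R4 failure  progression documented within 26 weeks.
R5 failure  discontinued for progression or death within 26 weeks with no
            evaluation after discontinuation.
R6 failure  PD as best response within 24 weeks.
R7 failure  definitive discontinuation for progression or death before any
            tumor evaluation.

A stable-disease patient still on treatment whose last evaluation is below
22 weeks matches no rule; the protocol leaves this configuration undefined
and :func:`classify_cbr` raises rather than guesses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from statsmodels.stats.proportion import proportion_confint

from .priors import BinomialData
from .records import CR, NE, PD, PR, SD, RESPONSE_ORDER, PatientRecord

__all__ = [
    "CbrOutcome",
    "UnclassifiableRecordError",
    "best_response",
    "classify_cbr",
    "cohort_cbr",
    "best_response_tally",
    "orr",
    "ProportionEstimate",
    "RESPONSE_WINDOW_DAYS",
    "SD_DURABILITY_DAYS",
    "PROGRESSION_CUTOFF_DAYS",
]

#: 24 weeks: window for the best-response status entering the CBR rules.
RESPONSE_WINDOW_DAYS = 24 * 7
#: 22 weeks: minimum inclusion-to-last-evaluation span for durable SD (R2).
SD_DURABILITY_DAYS = 22 * 7
#: 26 weeks: progression/discontinuation cutoff separating R3 from R4/R5.
PROGRESSION_CUTOFF_DAYS = 26 * 7


class UnclassifiableRecordError(ValueError):
    """A record matching none of the protocol's classification rules."""

    def __init__(self, patient_id: str, message: str):
        self.patient_id = patient_id
        super().__init__(f"{patient_id}: {message}")


@dataclass(frozen=True)
class CbrOutcome:
    """Binary success/failure label with the rule that produced it."""

    patient_id: str
    label: str  # "success" | "failure"
    rule_fired: str  # "R1" .. "R7"
    best_response: str  # CR/PR/SD/PD/NE within the 24-week window

    @property
    def is_success(self) -> bool:
        return self.label == "success"


def best_response(
    record: PatientRecord, window_days: Optional[float] = RESPONSE_WINDOW_DAYS
) -> str:
    """Best RECIST category among evaluations at time <= window_days.

    Ordering CR > PR > SD > PD.  ``window_days=None`` uses the whole
    record (the convention for best *overall* response and the ORR).
    Returns NE when no evaluation falls in the window.
    """
    if window_days is not None and window_days <= 0:
        raise ValueError("window_days must be positive")
    statuses = [
        s
        for t, s in record.evaluations
        if window_days is None or t <= window_days
    ]
    if not statuses:
        return NE
    return max(statuses, key=RESPONSE_ORDER.__getitem__)


def _definitive_discontinuation(
    record: PatientRecord,
) -> tuple[Optional[float], Optional[str]]:
    """Discontinuation for progression or death, with death as fallback.

    A recorded death without an explicit discontinuation row is treated as
    definitive discontinuation for death at the death date.
    """
    if record.discontinuation_reason in ("progression", "death"):
        return record.discontinuation_time, record.discontinuation_reason
    if record.death_time is not None:
        return record.death_time, "death"
    return None, None


def classify_cbr(record: PatientRecord, analysis_time: float) -> CbrOutcome:
    """Apply the protocol success/failure rules at ``analysis_time`` days.

    Events after ``analysis_time`` (within-record clock) are ignored, so
    the classification reflects what was known at that analysis.
    """
    rec = record.truncated(analysis_time)
    br = best_response(rec, RESPONSE_WINDOW_DAYS)

    def outcome(label: str, rule: str) -> CbrOutcome:
        return CbrOutcome(rec.patient_id, label, rule, br)

    if br in (CR, PR):
        return outcome("success", "R1")

    if br == SD:
        disc_time, disc_reason = _definitive_discontinuation(rec)
        prog = rec.progression_time
        last_eval = rec.last_evaluation_time()
        if prog is None and disc_time is None and last_eval >= SD_DURABILITY_DAYS:
            return outcome("success", "R2")
        if prog is not None and prog > PROGRESSION_CUTOFF_DAYS:
            return outcome("success", "R3")
        if prog is not None:  # prog <= 26 weeks
            return outcome("failure", "R4")
        if disc_time is not None and disc_time <= PROGRESSION_CUTOFF_DAYS:
            evals_after = any(t > disc_time for t, _ in rec.evaluations)
            if not evals_after:
                return outcome("failure", "R5")
        raise UnclassifiableRecordError(
            rec.patient_id,
            "stable disease matching no protocol rule (no progression, "
            f"last evaluation at day {last_eval}, "
            f"discontinuation at day {disc_time})",
        )

    if br == PD:
        return outcome("failure", "R6")

    # br == NE: no evaluation within 24 weeks
    disc_time, _ = _definitive_discontinuation(rec)
    if not rec.evaluations and disc_time is not None:
        return outcome("failure", "R7")
    raise UnclassifiableRecordError(
        rec.patient_id,
        "not evaluable within 24 weeks and not discontinued for "
        "progression or death before any evaluation",
    )


def cohort_cbr(
    records: Sequence[PatientRecord], analysis_time: Optional[float] = None
) -> tuple[BinomialData, list[CbrOutcome]]:
    """Classify every record; successes over the full-analysis-set size.

    Not-evaluable patients stay in the denominator (they classify as
    failures via R6/R7).  ``analysis_time`` defaults to the latest event
    time across the cohort.
    """
    if not records:
        raise ValueError("cohort_cbr requires a non-empty record list")
    if analysis_time is None:
        analysis_time = max(r.max_event_time() for r in records)
    outcomes = [classify_cbr(r, analysis_time) for r in records]
    s = sum(o.is_success for o in outcomes)
    return BinomialData(successes=s, n=len(records)), outcomes


def best_response_tally(records: Sequence[PatientRecord]) -> Counter:
    """Counts of best overall response (whole record, no time window)."""
    return Counter(best_response(r, None) for r in records)


@dataclass(frozen=True)
class ProportionEstimate:
    """A rate with its exact (Clopper-Pearson) binomial confidence interval."""

    count: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95


def orr(
    records: Sequence[PatientRecord], denominator_policy: str = "assessable"
) -> ProportionEstimate:
    """Objective response rate: best overall response CR or PR.

    ``denominator_policy='assessable'`` drops not-evaluable patients from
    the denominator; ``'full'`` keeps every record.
    """
    if denominator_policy not in ("assessable", "full"):
        raise ValueError(f"unknown denominator policy {denominator_policy!r}")
    if not records:
        raise ValueError("orr requires a non-empty record list")
    best = [best_response(r, None) for r in records]
    responders = sum(b in (CR, PR) for b in best)
    denom = (
        len(records)
        if denominator_policy == "full"
        else sum(b != NE for b in best)
    )
    if denom == 0:
        raise ZeroDivisionError("no assessable patients: ORR undefined")
    lo, hi = proportion_confint(responders, denom, alpha=0.05, method="beta")
    return ProportionEstimate(responders, denom, responders / denom,
                              float(lo), float(hi))
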
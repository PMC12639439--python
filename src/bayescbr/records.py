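"""Patient-level timeline records for a RECIST-evaluated single-arm trial.

All within-patient times are days from inclusion (day 0 = first treatment
administration); ``inclusion_time`` carries the calendar offset of day 0
so that cohort-level interim analyses can be placed on a common clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "CR",
    "PR",
    "SD",
    "PD",
    "NE",
    "RECIST_STATUSES",
    "RESPONSE_ORDER",
    "DISCONTINUATION_REASONS",
    "PatientRecord",
    "RecordValidationError",
]

CR = "CR"
PR = "PR"
SD = "SD"
PD = "PD"
NE = "NE"  # not evaluable: no post-baseline tumor evaluation

RECIST_STATUSES = (CR, PR, SD, PD)

#: best-overall-response ordering, best first
RESPONSE_ORDER = {CR: 4, PR: 3, SD: 2, PD: 1, NE: 0}

DISCONTINUATION_REASONS = (
    "progression",
    "death",
    "toxicity",
    "physician_decision",
    "patient_refusal",
    "other",
)


class RecordValidationError(ValueError):
    """A patient record violating the timeline invariants."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's response / progression / death / discontinuation timeline.

    Parameters
    ----------
    patient_id
        Stable identifier.
    evaluations
        Ordered ``(day, status)`` tumor evaluations with status one of
        CR/PR/SD/PD; strictly increasing in time.
    progression_time
        Day of first documented RECIST progression, if any.
    discontinuation_time, discontinuation_reason
        Definitive treatment discontinuation, if recorded.
    death_time
        Day of death, if the patient died.
    last_contact_time
        Last day the patient is known to be under observation; bounds every
        other recorded time.
    inclusion_time
        Calendar day of inclusion (cohort clock); within-record times stay
        relative to inclusion.
    """

    patient_id: str
    evaluations: tuple[tuple[float, str], ...] = ()
    progression_time: Optional[float] = None
    discontinuation_time: Optional[float] = None
    discontinuation_reason: Optional[str] = None
    death_time: Optional[float] = None
    last_contact_time: float = 0.0
    treatment_start_time: float = 0.0
    inclusion_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "evaluations", tuple(
            (float(t), str(s)) for t, s in self.evaluations
        ))
        last = -float("inf")
        for t, status in self.evaluations:
            if status not in RECIST_STATUSES:
                raise RecordValidationError(
                    f"{self.patient_id}: unknown RECIST status {status!r}"
                )
            if t < 0:
                raise RecordValidationError(
                    f"{self.patient_id}: negative evaluation day {t}"
                )
            if t <= last:
                raise RecordValidationError(
                    f"{self.patient_id}: evaluation days not strictly "
                    f"increasing at day {t}"
                )
            last = t
        for name in ("progression_time", "discontinuation_time", "death_time"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RecordValidationError(
                    f"{self.patient_id}: negative {name} {v}"
                )
        if (
            self.discontinuation_reason is not None
            and self.discontinuation_reason not in DISCONTINUATION_REASONS
        ):
            raise RecordValidationError(
                f"{self.patient_id}: unknown discontinuation reason "
                f"{self.discontinuation_reason!r}"
            )
        if self.death_time is not None and self.evaluations:
            if self.death_time < max(t for t, _ in self.evaluations):
                raise RecordValidationError(
                    f"{self.patient_id}: death at day {self.death_time} "
                    f"precedes a tumor evaluation"
                )
        if self.last_contact_time < self.max_event_time():
            raise RecordValidationError(
                f"{self.patient_id}: last_contact_time "
                f"{self.last_contact_time} precedes a recorded event"
            )

    def max_event_time(self) -> float:
        """Latest within-record event time (0 if nothing is recorded)."""
        times = [t for t, _ in self.evaluations]
        for v in (self.progression_time, self.discontinuation_time,
                  self.death_time):
            if v is not None:
                times.append(v)
        return max(times, default=0.0)

    def last_evaluation_time(self) -> Optional[float]:
        return self.evaluations[-1][0] if self.evaluations else None

    def truncated(self, analysis_time: float) -> "PatientRecord":
        """The record as it was known at ``analysis_time`` days on study.

        Events strictly after the cut are removed; last contact is capped.
        """
        t = float(analysis_time)

        def keep(v: Optional[float]) -> Optional[float]:
            return v if (v is not None and v <= t) else None

        disc = keep(self.discontinuation_time)
        return replace(
            self,
            evaluations=tuple(e for e in self.evaluations if e[0] <= t),
            progression_time=keep(self.progression_time),
            discontinuation_time=disc,
            discontinuation_reason=(
                self.discontinuation_reason if disc is not None else None
            ),
            death_time=keep(self.death_time),
            last_contact_time=min(self.last_contact_time, t),
        )
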
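"""Synthetic patient cohorts with the structure the analysis assumes.

The generator emulates a small recurrent/metastatic head-and-neck cancer
cohort treated with metronomic chemotherapy plus dual immune checkpoint
blockade: a best-response mixture over {CR, PR, durable SD, PD, not
evaluable}, exponential latent progression and death times (medians in
months), tumor evaluations on a fixed scan grid (every 8 weeks by
default), and uniform accrual.

Latent progression and death are coupled comonotonically: one uniform
draw drives both exponential quantile transforms, so each marginal is
exactly exponential at its specified median while death never precedes
progression whenever the OS median exceeds the PFS median.  Progression
is *documented* at the first scheduled scan at or after the latent
progression time, as in real RECIST data; drawn categories are
conditioned on the scan grid so that they always map onto the intended
success/failure rule (e.g. a "PD" patient's progression is documented at
or before 26 weeks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .classify import PROGRESSION_CUTOFF_DAYS, RESPONSE_WINDOW_DAYS
from .records import CR, PD, PR, SD, PatientRecord
from .survival import DAYS_PER_MONTH

__all__ = ["CohortSpec", "generate_cohort", "reference_cohort"]

CATEGORIES = ("CR", "PR", "SD24", "PD", "NE")

#: best-response mixture of the 15-patient head-and-neck cohort:
#: 1 CR, 1 PR, 1 durable SD, 11 PD, 1 not evaluable.
REFERENCE_RESPONSE_PROBS = {
    "CR": 1 / 15,
    "PR": 1 / 15,
    "SD24": 1 / 15,
    "PD": 11 / 15,
    "NE": 1 / 15,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a generated cohort.

    Defaults reproduce the study conditions of the head-and-neck cohort:
    n = 15, the observed best-response mixture, median PFS 1.8 months,
    median OS 8.0 months, scans every 8 weeks starting at week 8, accrual
    spread over 17 months, and an exponential time-to-response with
    median 2 months for responders.
    """

    n_patients: int = 15
    response_probs: dict = field(
        default_factory=lambda: dict(REFERENCE_RESPONSE_PROBS)
    )
    pfs_median_months: float = 1.8
    os_median_months: float = 8.0
    eval_interval_weeks: float = 8.0
    response_onset_median_months: float = 2.0
    accrual_months: float = 17.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        unknown = set(self.response_probs) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown response categories {sorted(unknown)}")
        total = sum(self.response_probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"response probabilities must sum to 1, got {total}"
            )
        for name in ("pfs_median_months", "os_median_months",
                     "eval_interval_weeks", "response_onset_median_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _rate_per_day(median_months: float) -> float:
    return math.log(2.0) / (median_months * DAYS_PER_MONTH)


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort of patient records; identical seeds give identical cohorts."""
    rng = np.random.default_rng(spec.seed)
    lam_p = _rate_per_day(spec.pfs_median_months)
    lam_d = _rate_per_day(spec.os_median_months)
    interval = spec.eval_interval_weeks * 7.0
    # last scan at or before the 26-week progression cutoff: a latent
    # progression before this scan is always documented within 26 weeks
    pd_bound = math.floor(PROGRESSION_CUTOFF_DAYS / interval) * interval
    if pd_bound <= 0:
        raise ValueError("evaluation interval exceeds the 26-week cutoff")
    response_bound = math.floor(RESPONSE_WINDOW_DAYS / interval) * interval

    cats = list(spec.response_probs)
    probs = np.array([spec.response_probs[c] for c in cats])
    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        pid = f"SYN{i + 1:04d}"
        cat = cats[rng.choice(len(cats), p=probs)]
        inclusion = rng.uniform(0.0, spec.accrual_months * DAYS_PER_MONTH)
        u = rng.random()

        if cat == "NE":
            death = rng.uniform(0.0, interval)
            records.append(
                PatientRecord(
                    patient_id=pid,
                    evaluations=(),
                    death_time=death,
                    discontinuation_time=death,
                    discontinuation_reason="death",
                    last_contact_time=death,
                    inclusion_time=inclusion,
                )
            )
            continue

        onset: Optional[float] = None
        if cat in ("CR", "PR"):
            # documented response at a scan within the 24-week window
            lam_r = _rate_per_day(spec.response_onset_median_months)
            u_r = rng.random() * (1.0 - math.exp(-lam_r * response_bound))
            latent_onset = -math.log1p(-u_r) / lam_r
            onset = math.ceil(latent_onset / interval) * interval
            onset = max(interval, min(onset, response_bound))
            # progression conditioned to follow the response
            floor_u = 1.0 - math.exp(-lam_p * onset)
            u = floor_u + u * (1.0 - floor_u)
        elif cat == "PD":
            u = u * (1.0 - math.exp(-lam_p * pd_bound))
        else:  # SD24: progression documented only after 26 weeks
            floor_u = 1.0 - math.exp(-lam_p * pd_bound)
            u = floor_u + u * (1.0 - floor_u)

        latent_prog = -math.log1p(-u) / lam_p
        death = -math.log1p(-u) / lam_d  # comonotone with progression
        doc_prog = math.ceil(latent_prog / interval) * interval
        doc_prog = max(doc_prog, interval)

        evals: list[tuple[float, str]] = []
        t = interval
        while t < doc_prog and t <= death:
            status = SD
            if onset is not None and t >= onset:
                status = cat  # CR or PR sustained until progression
            evals.append((t, status))
            t += interval

        if doc_prog <= death:
            evals.append((doc_prog, PD))
            progression: Optional[float] = doc_prog
            disc_time, disc_reason = doc_prog, "progression"
        else:
            # died before the scan that would have documented progression
            progression = None
            disc_time, disc_reason = death, "death"

        last_contact = max(death, disc_time, *(t for t, _ in evals))
        records.append(
            PatientRecord(
                patient_id=pid,
                evaluations=tuple(evals),
                progression_time=progression,
                discontinuation_time=disc_time,
                discontinuation_reason=disc_reason,
                death_time=death,
                last_contact_time=last_contact,
                inclusion_time=inclusion,
            )
        )
    return records


def reference_cohort() -> list[PatientRecord]:
    """The deterministic 15-patient head-and-neck cohort (synthetic).

    A hand-built stand-in reproducing the published cohort structure:
    1 CR (first response at 10.9 months, lasting 13.6 months), 1 PR
    (first response at 1.8 months, lasting 3.7 months), 1 durable SD
    progressing at 27 weeks, 11 PD within 26 weeks, and 1 patient dead of
    septic shock before any tumor evaluation.  Individual event times
    other than those listed are invented but consistent with the
    published medians (PFS 1.8 months, OS 8.0 months, 13 deaths).
    """
    records: list[PatientRecord] = []
    # CR: SD scans, CR documented at day 332 (10.9 mo), progression 414 d
    # later (13.6 mo duration), death much later.
    records.append(
        PatientRecord(
            patient_id="HN01",
            evaluations=(
                (56, SD), (112, SD), (168, SD), (224, SD), (280, SD),
                (332, CR), (392, CR), (448, CR), (560, CR), (672, CR),
                (746, PD),
            ),
            progression_time=746,
            discontinuation_time=746,
            discontinuation_reason="progression",
            death_time=900,
            last_contact_time=900,
        )
    )
    # PR: first response at day 55 (1.8 mo), progression 113 d later (3.7 mo)
    records.append(
        PatientRecord(
            patient_id="HN02",
            evaluations=((55, PR), (112, PR), (168, PD)),
            progression_time=168,
            discontinuation_time=168,
            discontinuation_reason="progression",
            death_time=310,
            last_contact_time=310,
        )
    )
    # durable SD: progression documented at 27 weeks (> 26-week cutoff)
    records.append(
        PatientRecord(
            patient_id="HN03",
            evaluations=((56, SD), (112, SD), (168, SD), (189, PD)),
            progression_time=189,
            discontinuation_time=189,
            discontinuation_reason="progression",
            death_time=400,
            last_contact_time=400,
        )
    )
    # 11 early progressors (PD documented at the first performed scan,
    # actual scan dates jitter around the 8-week schedule); two remain
    # alive at data cut-off
    pd_defs = [
        ("HN04", 30, 90),
        ("HN05", 50, 130),
        ("HN06", 54, 170),
        ("HN07", 54, 200),
        ("HN08", 55, 220),
        ("HN09", 55, 235),
        ("HN10", 55, 244),
        ("HN11", 58, 280),
        ("HN12", 61, None),
        ("HN13", 112, 340),
        ("HN14", 115, None),
    ]
    for pid, prog, death in pd_defs:
        evals = ((prog, PD),)
        records.append(
            PatientRecord(
                patient_id=pid,
                evaluations=evals,
                progression_time=prog,
                discontinuation_time=prog,
                discontinuation_reason="progression",
                death_time=death,
                last_contact_time=death if death is not None else 1100,
            )
        )
    # not evaluable: died of septic shock before the first scan
    records.append(
        PatientRecord(
            patient_id="HN15",
            evaluations=(),
            death_time=20,
            discontinuation_time=20,
            discontinuation_reason="death",
            last_contact_time=20,
        )
    )
    return records
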
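"""Sequential single-arm design: priors, futility rule, interim schedule.

The design stops a cohort for futility when the posterior probability that
the true clinical benefit rate is at or below the uninteresting bound
``p0`` reaches ``futility_threshold`` under the decision prior.  Interim
looks are triggered by counts of assessable patients: the first after
``first_interim_n`` patients complete their follow-up window (or classify
earlier through progression/death), then every ``interim_step`` patients
up to ``max_n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .priors import PROTOCOL_PRIORS, BetaParams

__all__ = ["TrialDesign", "interim_schedule"]


@dataclass(frozen=True)
class TrialDesign:
    """Design parameters of the sequential beta-binomial trial.

    Defaults are the head-and-neck cohort protocol: maximum 30 patients,
    futility bound p0 = 20%, stopping probability threshold 0.75, interims
    at 10 assessable patients then every 5, 24-week response follow-up,
    three priors with the flat prior driving the stopping decision.
    """

    max_n: int = 30
    p0: float = 0.20
    futility_threshold: float = 0.75
    priors: tuple[BetaParams, ...] = PROTOCOL_PRIORS
    decision_prior_label: str = "noninformative"
    first_interim_n: int = 10
    interim_step: int = 5
    followup_weeks: float = 24.0

    def __post_init__(self) -> None:
        if not 0 < self.first_interim_n <= self.max_n:
            raise ValueError(
                f"require 0 < first_interim_n <= max_n, got "
                f"{self.first_interim_n} / {self.max_n}"
            )
        if self.interim_step < 1:
            raise ValueError("interim_step must be >= 1")
        if not 0 < self.p0 < 1:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")
        # threshold 1.0 is legal and disables stopping (the posterior CDF
        # at p0 < 1 never reaches 1)
        if not 0 < self.futility_threshold <= 1:
            raise ValueError(
                f"futility_threshold must lie in (0, 1], got "
                f"{self.futility_threshold}"
            )
        if not any(
            p.label == self.decision_prior_label for p in self.priors
        ):
            raise ValueError(
                f"decision prior {self.decision_prior_label!r} not among "
                f"the design priors"
            )
        object.__setattr__(self, "priors", tuple(self.priors))

    @property
    def decision_prior(self) -> BetaParams:
        return next(
            p for p in self.priors if p.label == self.decision_prior_label
        )

    @property
    def followup_days(self) -> float:
        return self.followup_weeks * 7.0


def interim_schedule(design: TrialDesign) -> list[int]:
    """Assessable-patient counts at which analyses fire.

    The final count is always ``max_n`` (the final analysis), even when
    the step does not land on it exactly.
    """
    triggers = list(
        range(design.first_interim_n, design.max_n + 1, design.interim_step)
    )
    if triggers[-1] != design.max_n:
        triggers.append(design.max_n)
    return triggers
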
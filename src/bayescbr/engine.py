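"""Sequential conduct and Monte-Carlo operating characteristics.

``run_interim`` performs one analysis on real (or generated) patient
records; ``simulate_trial`` plays out one trial under an assumed true
clinical benefit rate; ``operating_characteristics`` aggregates replicates
into early-stopping probability, expected sample size, and the probability
of finishing with the futility criterion unmet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classify import UnclassifiableRecordError, classify_cbr
from .design import TrialDesign, interim_schedule
from .priors import (
    BinomialData,
    PosteriorSummary,
    futility_probability,
    posterior_update,
    summarize_posterior,
)
from .records import PatientRecord

__all__ = [
    "InterimResult",
    "TrialTrace",
    "run_interim",
    "simulate_trial",
    "operating_characteristics",
]

SeedLike = Union[int, np.random.SeedSequence]


@dataclass(frozen=True)
class InterimResult:
    """One interim (or final) analysis of the cohort."""

    analysis_index: int
    n_assessable: int
    successes: int
    posterior_summaries: tuple[PosteriorSummary, ...]
    decision: str  # "continue" | "stop_futility" | "complete"

    @property
    def decision_summary(self) -> PosteriorSummary:
        """The summary under the prior that drives the stopping decision."""
        return self.posterior_summaries[self._decision_idx]

    # set post-init by run_interim via object.__setattr__
    _decision_idx: int = 0


def _assessable_outcomes(
    records: Sequence[PatientRecord],
    design: TrialDesign,
    analysis_time: float,
):
    """Classify the records assessable at a cohort-clock analysis time.

    A patient is assessable once the response follow-up window has elapsed
    since inclusion, or earlier if the protocol rules already classify the
    truncated record decisively (early progression, death, CR/PR).
    """
    outcomes = []
    for r in records:
        t_rel = analysis_time - r.inclusion_time
        if t_rel < 0:
            continue  # not yet enrolled
        if t_rel >= design.followup_days:
            outcomes.append(classify_cbr(r, t_rel))
        else:
            try:
                outcomes.append(classify_cbr(r, t_rel))
            except UnclassifiableRecordError:
                continue  # pending: still within follow-up, undecided
    return outcomes


def run_interim(
    records: Sequence[PatientRecord],
    design: TrialDesign,
    analysis_time: float,
    analysis_index: int = 0,
) -> InterimResult:
    """One analysis: classify, update every prior, apply the futility rule."""
    outcomes = _assessable_outcomes(records, design, analysis_time)
    if not outcomes:
        raise ValueError("no classifiable records at this analysis time")
    data = BinomialData(
        successes=sum(o.is_success for o in outcomes), n=len(outcomes)
    )
    summaries = tuple(
        summarize_posterior(prior, data, design.p0) for prior in design.priors
    )
    decision_idx = next(
        i
        for i, p in enumerate(design.priors)
        if p.label == design.decision_prior_label
    )
    fut = summaries[decision_idx].futility_prob
    if fut >= design.futility_threshold:
        decision = "stop_futility"
    elif data.n >= design.max_n:
        decision = "complete"
    else:
        decision = "continue"
    result = InterimResult(
        analysis_index=analysis_index,
        n_assessable=data.n,
        successes=data.successes,
        posterior_summaries=summaries,
        decision=decision,
    )
    object.__setattr__(result, "_decision_idx", decision_idx)
    return result


@dataclass(frozen=True)
class TrialTrace:
    """Decision path of one simulated trial."""

    true_cbr: float
    final_n: int  # patients enrolled when the trial ended
    n_assessed: int  # patients classified at the deciding analysis
    successes: int  # successes at the deciding analysis
    stopped_early: bool
    futility_met_at_final: bool
    decisions: tuple[tuple[int, int, float, str], ...]
    # each: (n assessable, successes, futility prob, decision)


def simulate_trial(
    true_cbr: float,
    design: TrialDesign,
    accrual_rate: float = 1.8,
    seed: SeedLike = 0,
) -> TrialTrace:
    """Play out one trial under an assumed true clinical benefit rate.

    Patients enrol uniformly at ``accrual_rate`` patients/month over the
    implied accrual window.  Each patient's binary outcome is
    Bernoulli(true_cbr); successes become assessable when their follow-up
    window closes, failures at the tumor evaluation that documents them
    (a point of the 8-week evaluation grid within the window).  Interim
    looks fire per the design schedule on assessable counts; a futility
    stop freezes enrolment, so the final sample size counts everyone
    already enrolled at the stopping time (accrual overrun).
    """
    if not 0.0 <= true_cbr <= 1.0:
        raise ValueError("true_cbr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = design.max_n
    outcomes = rng.random(n) < true_cbr
    window_days = n / accrual_rate * 30.4375
    enroll = np.sort(rng.uniform(0.0, window_days, size=n))
    # failures surface at a scan within follow-up; successes at window close
    grid = np.arange(56.0, design.followup_days + 1e-9, 56.0)
    if grid.size == 0:
        grid = np.array([design.followup_days])
    delays = np.where(
        outcomes, design.followup_days, rng.choice(grid, size=n)
    )
    assess = enroll + delays
    order = np.argsort(assess, kind="stable")
    success_sorted = outcomes[order]
    assess_sorted = assess[order]

    decisions: list[tuple[int, int, float, str]] = []
    post = design.decision_prior
    for k in interim_schedule(design):
        s = int(success_sorted[:k].sum())
        data = BinomialData(successes=s, n=k)
        fut = futility_probability(posterior_update(post, data), design.p0)
        if fut >= design.futility_threshold:
            t_stop = assess_sorted[k - 1]
            n_final = int(np.sum(enroll <= t_stop))
            decisions.append((k, s, fut, "stop_futility"))
            return TrialTrace(
                true_cbr=true_cbr,
                final_n=n_final,
                n_assessed=k,
                successes=s,
                stopped_early=k < n,
                futility_met_at_final=k == n,
                decisions=tuple(decisions),
            )
        decisions.append((k, s, fut, "continue" if k < n else "complete"))
    s_final = int(success_sorted.sum())
    return TrialTrace(
        true_cbr=true_cbr,
        final_n=n,
        n_assessed=n,
        successes=s_final,
        stopped_early=False,
        futility_met_at_final=False,
        decisions=tuple(decisions),
    )


def operating_characteristics(
    design: TrialDesign,
    cbr_grid: Sequence[float],
    n_sim: int,
    seed: int = 0,
    accrual_rate: float = 1.8,
) -> pd.DataFrame:
    """Monte-Carlo frequentist behaviour of the design over true CBR values.

    Returns one row per grid point with the early-stop probability, the
    expected enrolled sample size, the probability of reaching the final
    analysis with the futility criterion unmet ("declare interesting"),
    and binomial Monte-Carlo standard errors.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    for point_ss, p in zip(root.spawn(len(cbr_grid)), cbr_grid):
        child_seeds = point_ss.spawn(n_sim)
        stops = np.empty(n_sim, dtype=bool)
        interesting = np.empty(n_sim, dtype=bool)
        final_n = np.empty(n_sim, dtype=float)
        for i, ss in enumerate(child_seeds):
            trace = simulate_trial(p, design, accrual_rate, ss)
            stops[i] = trace.stopped_early
            interesting[i] = (
                not trace.stopped_early and not trace.futility_met_at_final
            )
            final_n[i] = trace.final_n
        stop_p = stops.mean()
        int_p = interesting.mean()
        rows.append(
            {
                "true_cbr": p,
                "stop_probability": stop_p,
                "stop_probability_se": np.sqrt(stop_p * (1 - stop_p) / n_sim),
                "expected_n": final_n.mean(),
                "expected_n_se": final_n.std(ddof=1) / np.sqrt(n_sim),
                "prob_declare_interesting": int_p,
                "prob_declare_interesting_se": np.sqrt(
                    int_p * (1 - int_p) / n_sim
                ),
                "n_sim": n_sim,
            }
        )
    return pd.DataFrame(rows)
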
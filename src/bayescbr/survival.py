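"""Time-to-event endpoints: PFS, OS and duration of response.

Endpoint conventions (single-arm oncology reporting):

* PFS — first treatment administration to first documented RECIST
  progression or death from any cause; patients alive and progression-free
  are censored at their last tumor evaluation.
* OS — first administration to death from any cause; survivors censored
  at last contact.
* DOR — responders (best overall response CR/PR) only, from the first
  documented CR/PR to progression or death; censored at the last tumor
  evaluation otherwise.

Estimation is the Kaplan-Meier product-limit estimator with Greenwood
standard errors; the median confidence interval inverts the pointwise
band for S(t) (log(-log) transform by default, plain linear optionally),
the Brookmeyer-Crowley construction used in trial reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .records import CR, PR, PatientRecord

__all__ = [
    "DAYS_PER_MONTH",
    "SurvivalSample",
    "KmCurve",
    "derive_survival",
    "km_fit",
    "reverse_km_followup",
    "days_to_months",
]

#: Average Gregorian month length; used only when reporting days as months.
DAYS_PER_MONTH = 30.4375

ENDPOINTS = ("PFS", "OS", "DOR")


def days_to_months(days: float) -> float:
    return days / DAYS_PER_MONTH


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored durations (days) for one endpoint."""

    times: np.ndarray
    events: np.ndarray  # 1 = event, 0 = censored
    endpoint: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape:
            raise ValueError("times and events must have equal length")
        if np.any(t < 0):
            raise ValueError("negative event times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KmCurve:
    """A fitted product-limit survival curve.

    ``median`` (and either CI bound) is ``None`` when the curve never
    reaches the corresponding level within follow-up.
    """

    endpoint: str
    n: int
    n_events: int
    step_times: np.ndarray
    survival_probs: np.ndarray
    n_at_risk: np.ndarray
    median: Optional[float]
    median_ci: tuple[Optional[float], Optional[float]]
    ci_level: float = 0.95

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.step_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])

    def median_months(self) -> Optional[float]:
        return None if self.median is None else days_to_months(self.median)


def derive_survival(
    records: Sequence[PatientRecord], endpoint: str
) -> SurvivalSample:
    """Extract (time, event) pairs for one endpoint from patient records."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    times: list[float] = []
    events: list[int] = []
    for r in records:
        if endpoint == "PFS":
            candidates = [
                t for t in (r.progression_time, r.death_time) if t is not None
            ]
            if candidates:
                times.append(min(candidates))
                events.append(1)
            else:
                last_eval = r.last_evaluation_time()
                times.append(last_eval if last_eval is not None else 0.0)
                events.append(0)
        elif endpoint == "OS":
            if r.death_time is not None:
                times.append(r.death_time)
                events.append(1)
            else:
                times.append(r.last_contact_time)
                events.append(0)
        else:  # DOR: responders only
            onset = next(
                (t for t, s in r.evaluations if s in (CR, PR)), None
            )
            if onset is None:
                continue
            candidates = [
                t for t in (r.progression_time, r.death_time)
                if t is not None and t >= onset
            ]
            if candidates:
                times.append(min(candidates) - onset)
                events.append(1)
            else:
                last_eval = r.last_evaluation_time()
                times.append(max(last_eval - onset, 0.0))
                events.append(0)
    return SurvivalSample(np.asarray(times), np.asarray(events), endpoint)


def _median_ci_linear(
    kmf: KaplanMeierFitter, alpha: float
) -> tuple[Optional[float], Optional[float]]:
    """Median CI from a plain Greenwood band S(t) +/- z * se."""
    from scipy import stats as _stats

    z = _stats.norm.ppf(1 - alpha / 2)
    table = kmf.event_table
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((n - d) > 0, d / (n * (n - d)), 0.0)
    cum = np.cumsum(terms)
    sf = kmf.survival_function_.iloc[:, 0].reindex(table.index).ffill()
    se = sf.values * np.sqrt(cum)
    band = pd.DataFrame(
        {
            "lower": np.clip(sf.values - z * se, 0, 1),
            "upper": np.clip(sf.values + z * se, 0, 1),
        },
        index=table.index,
    )
    ci = median_survival_times(band)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)


def km_fit(
    sample: SurvivalSample,
    ci_level: float = 0.95,
    median_ci_method: str = "loglog",
) -> KmCurve:
    """Product-limit fit of a right-censored sample.

    Ties at a time are processed events-before-censorings (the standard
    convention).  An all-censored sample yields a flat curve with an
    undefined median.
    """
    if len(sample) == 0:
        raise ValueError("km_fit requires a non-empty sample")
    if median_ci_method not in ("loglog", "linear"):
        raise ValueError(f"unknown median CI method {median_ci_method!r}")
    kmf = KaplanMeierFitter(alpha=1 - ci_level)
    kmf.fit(sample.times, sample.events, label=sample.endpoint)

    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    step_times = event_rows.index.to_numpy(dtype=float)
    sf = kmf.survival_function_.iloc[:, 0]
    survival_probs = np.array([float(sf.loc[t]) for t in step_times])
    n_at_risk = event_rows["at_risk"].to_numpy(dtype=int)

    median = float(kmf.median_survival_time_)
    median = None if np.isinf(median) else median
    if median_ci_method == "loglog":
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        median_ci = (
            None if np.isinf(lo) else lo,
            None if np.isinf(hi) else hi,
        )
    else:
        median_ci = _median_ci_linear(kmf, 1 - ci_level)

    return KmCurve(
        endpoint=sample.endpoint,
        n=len(sample),
        n_events=int(sample.events.sum()),
        step_times=step_times,
        survival_probs=survival_probs,
        n_at_risk=n_at_risk,
        median=median,
        median_ci=median_ci,
        ci_level=ci_level,
    )


def reverse_km_followup(records: Sequence[PatientRecord]) -> Optional[float]:
    """Median follow-up by reverse Kaplan-Meier (censoring distribution).

    Deaths are censored, alive patients are events at last contact.
    """
    sample = derive_survival(records, "OS")
    flipped = SurvivalSample(sample.times, 1 - sample.events, "OS")
    curve = km_fit(flipped)
    return curve.median
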
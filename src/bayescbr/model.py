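"""Model/Results facade over the whole analysis.

Mirrors the fitting idiom of statistical modelling packages: build a
:class:`CbrTrialModel` from patient records and a design, call
:meth:`~CbrTrialModel.fit`, and read estimates, intervals and diagnostics
off the returned :class:`CbrTrialResults` (or print ``results.summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .classify import best_response_tally, cohort_cbr, orr
from .design import TrialDesign
from .engine import run_interim
from .io import AnalysisReport, config_hash, render_report
from .priors import BinomialData, PosteriorSummary, summarize_posterior
from .records import PatientRecord
from .survival import KmCurve, derive_survival, km_fit, reverse_km_followup

__all__ = ["CbrTrialModel", "CbrTrialResults"]


class CbrTrialModel:
    """Bayesian beta-binomial analysis of one single-arm cohort.

    Parameters
    ----------
    records
        Patient timelines (see :class:`~bayescbr.records.PatientRecord`).
    design
        Trial design; protocol defaults when omitted.
    """

    def __init__(
        self,
        records: Sequence[PatientRecord],
        design: Optional[TrialDesign] = None,
    ):
        if not records:
            raise ValueError("CbrTrialModel requires at least one record")
        self.records = list(records)
        self.design = design if design is not None else TrialDesign()

    @classmethod
    def from_csv(
        cls, evaluations_path, events_path,
        design: Optional[TrialDesign] = None,
    ) -> "CbrTrialModel":
        from .io import read_patient_records

        return cls(read_patient_records(evaluations_path, events_path), design)

    def fit(
        self,
        analysis_time: Optional[float] = None,
        denominator_policy: str = "assessable",
        endpoints: Sequence[str] = ("PFS", "OS", "DOR"),
    ) -> "CbrTrialResults":
        """Run the full final analysis.

        ``analysis_time`` (days on the within-patient clock) defaults to
        the latest recorded event, i.e. the data cut-off.
        """
        data, outcomes = cohort_cbr(self.records, analysis_time)
        posteriors = tuple(
            summarize_posterior(prior, data, self.design.p0)
            for prior in self.design.priors
        )
        orr_est = orr(self.records, denominator_policy)
        survival = {}
        for name in endpoints:
            sample = derive_survival(self.records, name)
            if len(sample):
                survival[name] = km_fit(sample)
        return CbrTrialResults(
            model=self,
            cbr_data=data,
            outcomes=tuple(outcomes),
            posterior_summaries=posteriors,
            orr=orr_est,
            survival=survival,
        )


@dataclass(frozen=True)
class CbrTrialResults:
    """Fitted quantities of a :class:`CbrTrialModel`."""

    model: CbrTrialModel
    cbr_data: BinomialData
    outcomes: tuple
    posterior_summaries: tuple[PosteriorSummary, ...]
    orr: object
    survival: dict

    @property
    def design(self) -> TrialDesign:
        return self.model.design

    @property
    def decision_summary(self) -> PosteriorSummary:
        """Posterior under the prior driving the futility decision."""
        return next(
            s
            for s in self.posterior_summaries
            if s.posterior.label == self.design.decision_prior_label
        )

    @property
    def futility_met(self) -> bool:
        return (
            self.decision_summary.futility_prob
            >= self.design.futility_threshold
        )

    def best_response_counts(self) -> dict:
        return dict(best_response_tally(self.model.records))

    def median_followup_days(self) -> Optional[float]:
        """Median follow-up by reverse Kaplan-Meier."""
        return reverse_km_followup(self.model.records)

    def interim(self, analysis_time: float, analysis_index: int = 0):
        """Re-run a design interim at a cohort-clock analysis time."""
        return run_interim(
            self.model.records, self.design, analysis_time, analysis_index
        )

    def to_report(self, provenance: Optional[dict] = None) -> AnalysisReport:
        prov = dict(provenance or {})
        prov.setdefault(
            "design_hash",
            config_hash(
                {
                    "max_n": self.design.max_n,
                    "p0": self.design.p0,
                    "futility_threshold": self.design.futility_threshold,
                    "priors": [
                        (p.alpha, p.beta, p.label) for p in self.design.priors
                    ],
                }
            ),
        )
        return AnalysisReport(
            cohort_summary=self.best_response_counts(),
            cbr=self.cbr_data,
            outcomes=self.outcomes,
            posterior_summaries=self.posterior_summaries,
            orr=self.orr,
            survival=self.survival,
            provenance=prov,
        )

    def summary(self) -> str:
        """Human-readable efficacy table."""
        return render_report(self.to_report(), format="text")
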
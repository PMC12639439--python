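"""Protocol success/failure rules, best response, and the ORR."""

import pytest

from bayescbr.classify import (
    UnclassifiableRecordError,
    best_response,
    best_response_tally,
    classify_cbr,
    cohort_cbr,
    orr,
)
from bayescbr.records import CR, NE, PD, PR, SD, PatientRecord

ANALYSIS = 1500.0  # well past every event in the records below


def record(pid="P", evals=(), prog=None, disc=None, reason=None, death=None):
    times = [t for t, _ in evals] + [
        t for t in (prog, disc, death) if t is not None
    ]
    return PatientRecord(
        patient_id=pid,
        evaluations=tuple(evals),
        progression_time=prog,
        discontinuation_time=disc,
        discontinuation_reason=reason,
        death_time=death,
        last_contact_time=max(times, default=0.0) + 1,
    )


@pytest.mark.parametrize(
    "evals, window, expected",
    [
        ([(56, SD), (112, PR)], 168, PR),
        ([], 168, NE),
        ([(56, PD)], 168, PD),
        ([(56, SD), (200, CR)], 168, SD),  # CR falls outside the window
        ([(56, SD), (200, CR)], None, CR),  # whole-record best response
        ([(56, PD), (112, SD)], 168, SD),
    ],
)
def test_best_response_window_and_ordering(evals, window, expected):
    assert best_response(record(evals=evals), window) == expected


@pytest.mark.parametrize(
    "kwargs, label, rule",
    [
        # CR at week 8: success regardless of anything later
        (dict(evals=[(56, CR)], prog=400, disc=400, reason="progression"),
         "success", "R1"),
        # durable SD still on treatment, last evaluation at 24 weeks
        (dict(evals=[(56, SD), (112, SD), (168, SD)]), "success", "R2"),
        # SD with progression at week 30 (> 26 weeks)
        (dict(evals=[(56, SD), (112, SD), (168, SD), (210, PD)], prog=210),
         "success", "R3"),
        # SD with progression at week 20 (within 26 weeks)
        (dict(evals=[(56, SD), (140, PD)], prog=140), "failure", "R4"),
        # SD, no documented progression, died on treatment at week 12
        (dict(evals=[(56, SD)], disc=84, reason="death", death=84),
         "failure", "R5"),
        # PD as best response within 24 weeks
        (dict(evals=[(56, PD)], prog=56), "failure", "R6"),
        # discontinued for death before any evaluation
        (dict(disc=21, reason="death", death=21), "failure", "R7"),
        # death recorded without an explicit discontinuation row
        (dict(death=21), "failure", "R7"),
    ],
)
def test_classification_rules(kwargs, label, rule):
    out = classify_cbr(record(**kwargs), ANALYSIS)
    assert (out.label, out.rule_fired) == (label, rule)


def test_response_within_window_wins_over_later_progression():
    """Any CR/PR evaluation within 24 weeks is success, full stop."""
    rec = record(
        evals=[(56, PR), (112, PD)], prog=112, disc=112, reason="progression"
    )
    out = classify_cbr(rec, ANALYSIS)
    assert out.label == "success" and out.rule_fired == "R1"


def test_pending_stable_disease_is_unclassifiable():
    """SD, on treatment, last evaluation before 22 weeks: protocol gap."""
    rec = record(evals=[(56, SD), (112, SD)])
    with pytest.raises(UnclassifiableRecordError) as exc:
        classify_cbr(rec, ANALYSIS)
    assert "P" in str(exc.value)


def test_classification_ignores_events_after_analysis_time():
    """The outcome reflects only what was known at the analysis."""
    rec = record(evals=[(56, SD), (112, SD), (168, SD), (400, PD)], prog=400)
    early = classify_cbr(rec, 200.0)
    late = classify_cbr(rec, ANALYSIS)
    assert early.rule_fired == "R2" and late.rule_fired == "R3"
    assert early.label == late.label == "success"


def test_cohort_cbr_reference(cohort):
    data, outcomes = cohort_cbr(cohort)
    assert (data.successes, data.n) == (3, 15)
    assert len(outcomes) == 15
    fired = {o.patient_id: o.rule_fired for o in outcomes}
    assert fired["HN02"] == "R1"  # the PR at 1.8 months
    assert fired["HN15"] == "R7"  # death before any evaluation
    assert sum(o.is_success for o in outcomes) == 3


def test_cohort_cbr_degenerate_cases():
    all_pd = [
        record(pid=f"P{i}", evals=[(56, PD)], prog=56) for i in range(15)
    ]
    data, _ = cohort_cbr(all_pd, ANALYSIS)
    assert (data.successes, data.n) == (0, 15)
    one_cr = [record(pid="X", evals=[(56, CR)])]
    data, _ = cohort_cbr(one_cr, ANALYSIS)
    assert (data.successes, data.n) == (1, 1)
    with pytest.raises(ValueError):
        cohort_cbr([], ANALYSIS)


def test_best_response_tally_reference(cohort):
    tally = best_response_tally(cohort)
    assert tally == {CR: 1, PR: 1, SD: 1, PD: 11, NE: 1}


def test_orr_policies(cohort):
    assessable = orr(cohort, "assessable")
    assert (assessable.count, assessable.denominator) == (2, 14)
    assert assessable.proportion == pytest.approx(2 / 14)
    full = orr(cohort, "full")
    assert (full.count, full.denominator) == (2, 15)
    with pytest.raises(ValueError):
        orr(cohort, "per_protocol")


def test_orr_zero_responders_and_zero_denominator():
    cohort = [
        record(pid=f"P{i}", evals=[(56, PD)], prog=56) for i in range(10)
    ]
    est = orr(cohort, "assessable")
    assert est.proportion == 0.0
    assert est.ci_low == 0.0 and est.ci_high > 0.0
    not_evaluable = [record(pid="Z", death=10)]
    with pytest.raises(ZeroDivisionError):
        orr(not_evaluable, "assessable")
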
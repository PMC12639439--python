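# Methods

## The model and the stopping rule

The primary endpoint is binary at the patient level: success (clinical
benefit) or failure, classified by the protocol rules below.  The true
clinical benefit rate *p* gets a Beta(α, β) prior; with *s* successes among
*n* classified patients the posterior is Beta(α + s, β + n − s).  All
inference is closed-form: the posterior mean is (α + s)/(α + β + n), the
credible interval is equal-tailed (beta quantiles at (1 − level)/2 and
1 − (1 − level)/2), and the futility probability is the regularized
incomplete beta function I_{p₀}(·, ·).  The equal-tailed convention was
confirmed numerically: it reproduces all three published interval bounds at
one-decimal rounding, so highest-posterior-density intervals are not
offered.

Three priors are carried in parallel (Beta(1, 1); Beta(1.8, 4.2);
Beta(0.75, 1.75), the latter two centred on a CBR of 30% with prior sample
sizes 6 and 2.5).  The protocol does not say which prior drives the
stopping decision; the package defaults to the noninformative prior — whose
posterior is also the headline estimate — and makes the choice configurable
(`TrialDesign.decision_prior_label`).

The futility comparison "P(p ≤ p₀) ≥ threshold" uses the continuous CDF;
inclusivity of the boundary p = p₀ is measure-zero and irrelevant.
Thresholds live in (0, 1]; a threshold of exactly 1 legitimately disables
stopping, since the posterior CDF at p₀ < 1 is always below 1.

## Patient classification (rules R1–R7)

Weeks convert to days at exactly 7 days/week: the best-response window is
168 d (24 wk), the SD durability bound 154 d (22 wk, inclusive), and the
progression cutoff 182 d (26 wk; "within" means ≤ 182, "after" means
> 182 — the literal protocol reading).  Treatment start is identified with
inclusion (day 0).  In order:

* **R1** success — best response within 168 d is CR or PR.
* For best response SD: **R2** success — no documented progression, no
  definitive discontinuation for progression or death, last evaluation
  ≥ 154 d; **R3** success — progression > 182 d; **R4** failure —
  progression ≤ 182 d; **R5** failure — discontinued for progression or
  death ≤ 182 d with no evaluation afterwards.
* **R6** failure — best response within 168 d is PD.
* **R7** failure — discontinued for progression or death before any
  evaluation.

A recorded death without an explicit discontinuation row counts as
definitive discontinuation for death.  One configuration is genuinely
undefined by the protocol (SD, on treatment, no progression, last
evaluation < 22 weeks): the classifier raises `UnclassifiableRecordError`
carrying the patient id rather than guess.  At an interim analysis that
same situation is interpreted as "not yet assessable" for patients still
inside the 24-week follow-up window, so early failures (R4–R7) and early
responders (R1) count before their window closes, as the event-based rules
imply.

Not-evaluable patients stay in the CBR denominator (they classify as
failures), but are excluded from the best-response percentages and the
objective response rate under the default `assessable` denominator policy;
`full` keeps them.  The ORR interval is exact Clopper–Pearson.  Best
*overall* response (for the tally and ORR) uses the whole record with
ordering CR > PR > SD > PD; the CBR rules use the 24-week window.

## Survival endpoints

PFS runs from first administration to documented progression or death,
censored at the last tumor evaluation; OS to death, censored at last
contact; DOR from the first documented CR/PR to progression or death,
responders only.  Estimation is the Kaplan–Meier product-limit estimator
(lifelines), ties processed events-before-censorings, Greenwood variance.
The median confidence interval inverts the pointwise band on the
log(−log) scale (the Brookmeyer–Crowley construction conventional in trial
reports); a plain linear band is available via
`km_fit(..., median_ci_method="linear")` since the reporting convention is
not universal.  Durations are stored in days and reported in months at
30.4375 days/month, display-rounded to one decimal.  Display rounding is
always half-up and happens only at render time; JSON reports carry full
precision.  Median follow-up is offered by reverse Kaplan–Meier (deaths
censored), the common definition, though no external value validates it.

## Sequential conduct and operating characteristics

Interim looks fire at assessable-patient counts: `first_interim_n` (10),
then every `interim_step` (5) up to `max_n` (30), the final count always
included.  "Assessable" counts patients classified by events or past the
24-week follow-up — interims are triggered by information, not enrolment.

`simulate_trial` draws per-patient binary outcomes Bernoulli(p) and
uniform enrolment at a configurable accrual rate (default 1.8
patients/month, matching a 30-patient cohort accrued over about 17
months).  A success becomes assessable when its follow-up window closes; a
failure at the scan that documents it, drawn uniformly from the 8-week
evaluation grid inside the window.  No within-patient timeline is
simulated at this layer — that is the cohort generator's job.  When a look
meets the futility criterion, enrolment freezes and the trial's final size
is everyone already enrolled, so expected sample sizes include accrual
overrun.  "Declare interesting" means reaching the final analysis with the
futility criterion unmet there (the protocol defines no superiority rule).
Randomness flows from one root `SeedSequence`; each replicate gets a
spawned child stream, so runs are reproducible and parallel-safe.
Operating characteristics report Monte-Carlo standard errors (binomial for
probabilities, empirical for expected n).

## The synthetic cohort generator

`generate_cohort` emulates a small recurrent/metastatic head-and-neck
cancer cohort under chemo-immunotherapy: a best-response mixture over
{CR, PR, durable SD, PD, not evaluable} (defaults 1/15, 1/15, 1/15, 11/15,
1/15), exponential latent progression and death with medians 1.8 and 8.0
months (rate = ln 2 / median), scans every 8 weeks from week 8, uniform
accrual over 17 months, exponential time-to-response (median 2 months) for
responders.  Progression is *documented* at the first scan at or after the
latent progression time, as in real RECIST data, so PFS events are
interval-censored onto the scan grid.

Two generator choices deserve emphasis:

* **Coupling of progression and death.**  One uniform draw drives both
  exponential quantile transforms (a comonotone copula).  Each marginal is
  then exactly exponential at its nominal median, and death cannot precede
  progression as long as the OS median exceeds the PFS median.  Rejection
  resampling (redrawing death until it follows progression) was rejected:
  it inflates the OS marginal by roughly 30% at these medians, which would
  silently break parameter recovery.
* **Category conditioning.**  The drawn category must survive
  classification: a "PD" patient's latent progression is conditioned to
  fall before the last scan at or under 26 weeks; a durable-SD patient's
  after it; a responder's after the (grid-snapped, ≤ 24 weeks) response
  onset.  When the category masses are chosen consistently with the latent
  law (e.g. P(progression ≤ 24 wk) for PD), the conditioned mixture
  reassembles the exact exponential marginal — the configuration used by
  the parameter-recovery tests.  Not-evaluable patients die uniformly
  before the first scan.

The generator does **not** model response depth, lesion-level RECIST
arithmetic, non-exponential hazards, dropout for toxicity, scan-date
jitter, or any covariates; passing tests demonstrate internal consistency
of the pipeline under these idealised conditions, not fidelity to any real
cohort beyond its response mix and medians.

`reference_cohort()` is a deterministic, hand-built synthetic stand-in for
the published 15-patient cohort: the response mix {1 CR, 1 PR, 1 durable
SD, 11 PD, 1 NE}, the reported response onsets (10.9 and 1.8 months) and
durations (13.6 and 3.7 months), a durable-SD progression at 27 weeks (any
date past 26 weeks classifies identically — asserted by test), one death
before any scan, and invented but consistent remaining event times chosen
so the cohort medians land on the published 1.8/8.0 months.  Patient-level
dates were never published, so survival medians are checked only against
the generator's known truths, not against external values.

## Problem sizes and numerical conventions

Tests run the median-recovery check at n = 5000 patients, the shrinkage
check at 200 cohorts of n = 30 (asserting the conjugate identity
E[posterior mean] = (α + np)/(α + β + n) within two Monte-Carlo standard
errors), and the operating-characteristics monotonicity check at 10⁴
replicates per grid point over true CBR {0.05, 0.1, 0.2, 0.3, 0.5} — sizes
at which Monte-Carlo error is well below the asserted tolerances while the
whole suite stays interactive.  Beta quantiles come from scipy's inverse
regularized incomplete beta, accurate to |CDF(q) − target| < 1e−10
(asserted).  All randomness is `numpy.random.Generator` seeded explicitly;
identical seeds give byte-identical cohorts and trial traces.

## Known limitations

* The classifier inherits the protocol's undefined SD configuration
  (raises rather than imputes).
* The interim assessability rule ("classified or past follow-up") is one
  reasonable reading of an ambiguous protocol; interim triggers count
  assessable, not enrolled, patients.
* The accrual model is uniform (or caller-supplied rate); no seasonal or
  ramp-up accrual.
* Reverse-KM median follow-up is provided but unvalidated externally.
* No efficacy early stopping, no multi-cohort borrowing, no lesion-level
  RECIST computation.
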
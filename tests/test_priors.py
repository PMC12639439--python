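"""Conjugate beta-binomial machinery: updating, intervals, futility."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from bayescbr.priors import (
    BetaParams,
    BinomialData,
    as_percent,
    credible_interval,
    futility_probability,
    posterior_mean,
    posterior_update,
    round_half_up,
    summarize_posterior,
)

priors_st = st.builds(
    BetaParams,
    st.floats(0.05, 50.0),
    st.floats(0.05, 50.0),
)
data_st = st.tuples(st.integers(0, 40), st.integers(0, 40)).map(
    lambda sn: BinomialData(min(sn), max(sn))
)


@pytest.mark.parametrize(
    "prior, s, n, expected",
    [
        (BetaParams(1, 1), 3, 15, (4.0, 13.0)),
        (BetaParams(1.8, 4.2), 3, 15, (4.8, 16.2)),
        (BetaParams(1, 1), 0, 0, (1.0, 1.0)),
        (BetaParams(0.75, 1.75), 3, 15, (3.75, 13.75)),
    ],
)
def test_conjugate_update(prior, s, n, expected):
    post = posterior_update(prior, BinomialData(s, n))
    assert (post.alpha, post.beta) == pytest.approx(expected)
    assert post.label == prior.label


def test_update_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        BetaParams(0.0, 1.0)
    with pytest.raises(ValueError):
        BetaParams(1.0, -2.0)
    with pytest.raises(ValueError):
        BinomialData(5, 3)
    with pytest.raises(ValueError):
        credible_interval(BetaParams(1, 1), 1.0)
    with pytest.raises(ValueError):
        futility_probability(BetaParams(1, 1), 1.5)


@given(priors_st, data_st, data_st)
def test_sequential_updates_compose(prior, d1, d2):
    """Updating with two batches equals one update with the pooled data."""
    twice = posterior_update(posterior_update(prior, d1), d2)
    pooled = posterior_update(
        prior, BinomialData(d1.successes + d2.successes, d1.n + d2.n)
    )
    # equal up to float addition order (one ulp)
    assert twice.alpha == pytest.approx(pooled.alpha, rel=1e-15)
    assert twice.beta == pytest.approx(pooled.beta, rel=1e-15)


@given(priors_st, data_st.filter(lambda d: d.n >= 1))
def test_posterior_mean_shrinks_toward_prior(prior, data):
    """The posterior mean lies strictly between prior mean and s/n."""
    post = posterior_update(prior, data)
    lo, hi = sorted([prior.mean, data.successes / data.n])
    if lo == hi:
        assert posterior_mean(post) == pytest.approx(lo)
    else:
        assert lo < posterior_mean(post) < hi


def test_uniform_prior_closed_forms():
    b = BetaParams(1, 1)
    assert posterior_mean(b) == 0.5
    assert futility_probability(b, 0.2) == pytest.approx(0.2, abs=1e-15)
    lo, hi = credible_interval(b, 0.95)
    assert (lo, hi) == pytest.approx((0.025, 0.975), abs=1e-12)


@pytest.mark.parametrize(
    "b, level",
    [
        (BetaParams(4, 13), 0.95),
        (BetaParams(4.8, 16.2), 0.95),
        (BetaParams(3.75, 13.75), 0.95),
        (BetaParams(0.3, 9.0), 0.8),
    ],
)
def test_credible_interval_tail_masses(b, level):
    """Equal-tailed: the CDF at each endpoint equals its tail mass."""
    lo, hi = credible_interval(b, level)
    dist = stats.beta(b.alpha, b.beta)
    assert dist.cdf(lo) == pytest.approx((1 - level) / 2, abs=1e-10)
    assert dist.cdf(hi) == pytest.approx(1 - (1 - level) / 2, abs=1e-10)
    assert 0 <= lo < hi <= 1


def test_futility_matches_quadrature_oracle():
    """P(p <= p0) agrees with direct integration of the beta density."""
    for a, b, p0 in [(4, 13, 0.2), (1, 31, 0.2), (4.8, 16.2, 0.3)]:
        oracle, err = integrate.quad(
            lambda x: stats.beta.pdf(x, a, b), 0.0, p0,
            epsabs=1e-13, epsrel=1e-13,
        )
        assert futility_probability(BetaParams(a, b), p0) == pytest.approx(
            oracle, abs=1e-10
        )
    # integer-beta closed form: Beta(1, b) CDF is 1 - (1-p)^b
    assert futility_probability(BetaParams(1, 31), 0.2) == pytest.approx(
        1 - 0.8**31, abs=1e-12
    )


@given(
    st.integers(0, 14),
    st.floats(0.05, 0.6),
    st.floats(0.01, 0.3),
)
def test_futility_monotone(successes, p0, dp):
    """Decreasing in successes at fixed n; increasing in the bound."""
    prior = BetaParams(1, 1)
    n = 15
    f = futility_probability(
        posterior_update(prior, BinomialData(successes, n)), p0
    )
    f_more = futility_probability(
        posterior_update(prior, BinomialData(successes + 1, n)), p0
    )
    assert f_more < f
    f_wider = futility_probability(
        posterior_update(prior, BinomialData(successes, n)), min(p0 + dp, 1.0)
    )
    assert f_wider >= f


def test_futility_agrees_with_posterior_draws():
    """Empirical CDF of posterior draws matches within 3 standard errors."""
    rng = np.random.default_rng(20260923)
    b = BetaParams(4, 13)
    draws = rng.beta(b.alpha, b.beta, size=10**5)
    for p0 in (0.1, 0.2, 0.4):
        exact = futility_probability(b, p0)
        emp = (draws <= p0).mean()
        se = np.sqrt(exact * (1 - exact) / draws.size)
        assert abs(emp - exact) <= 3 * se


def test_summarize_posterior_is_consistent():
    summ = summarize_posterior(BetaParams(1, 1), BinomialData(3, 15), p0=0.2)
    assert summ.posterior.alpha == 4 and summ.posterior.beta == 13
    assert summ.mean == pytest.approx(4 / 17)
    assert summ.futility_prob == pytest.approx(
        stats.beta(4, 13).cdf(0.2), abs=1e-12
    )
    rec = summ.as_record()
    assert rec["ci_low"] < rec["mean"] < rec["ci_high"]


@pytest.mark.parametrize(
    "x, expected",
    [(0.05, 0.1), (0.25, 0.3), (23.449, 23.4), (23.45, 23.5), (-0.05, -0.1)],
)
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected


def test_as_percent_scale():
    assert as_percent(4 / 17) == 23.5
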
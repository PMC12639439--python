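"""Conjugate beta-binomial inference for a response-rate endpoint.

The clinical benefit rate (CBR) is modelled as a Bernoulli success
probability ``p``.  A Beta(alpha, beta) prior updated with ``s`` successes
out of ``n`` patients yields the Beta(alpha + s, beta + n - s) posterior;
all reported quantities (posterior mean, equal-tailed credible interval,
futility probability P(p <= p0 | data)) are closed-form functionals of
that posterior.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

from scipy import special, stats

__all__ = [
    "BetaParams",
    "BinomialData",
    "PosteriorSummary",
    "PROTOCOL_PRIORS",
    "posterior_update",
    "posterior_mean",
    "credible_interval",
    "futility_probability",
    "summarize_posterior",
    "round_half_up",
    "as_percent",
]


class InvalidPriorError(ValueError):
    """Beta parameters are not strictly positive."""


class InvalidDataError(ValueError):
    """Binomial data with successes outside [0, n]."""


@dataclass(frozen=True)
class BetaParams:
    """A Beta(alpha, beta) distribution over the true response rate.

    ``alpha`` acts as pseudo-successes and ``beta`` as pseudo-failures;
    ``label`` is free text carried through updates (e.g. "noninformative").
    """

    alpha: float
    beta: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise InvalidPriorError(
                f"Beta parameters must be strictly positive, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class BinomialData:
    """Observed successes out of n classified patients."""

    successes: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 0 or not 0 <= self.successes <= self.n:
            raise InvalidDataError(
                f"require 0 <= successes <= n, got {self.successes}/{self.n}"
            )


#: The three protocol priors on the CBR: a flat prior, an informative
#: optimistic prior centred on 30% (prior sample size 6), and a less
#: informative optimistic prior with the same centre (prior sample size 2.5).
PROTOCOL_PRIORS: tuple[BetaParams, ...] = (
    BetaParams(1.0, 1.0, "noninformative"),
    BetaParams(1.8, 4.2, "informative optimistic"),
    BetaParams(0.75, 1.75, "less informative optimistic"),
)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior of the CBR under one prior, with decision quantities."""

    posterior: BetaParams
    mean: float
    ci_low: float
    ci_high: float
    futility_prob: float
    p0: float
    ci_level: float = 0.95

    def as_record(self) -> dict:
        """Flat record suitable for JSON serialisation."""
        return {
            "prior_label": self.posterior.label,
            "alpha_post": self.posterior.alpha,
            "beta_post": self.posterior.beta,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "futility_prob": self.futility_prob,
            "p0": self.p0,
        }


def posterior_update(prior: BetaParams, data: BinomialData) -> BetaParams:
    """Conjugate update: Beta(a, b) + (s, n) -> Beta(a + s, b + n - s)."""
    return BetaParams(
        prior.alpha + data.successes,
        prior.beta + (data.n - data.successes),
        prior.label,
    )


def posterior_mean(b: BetaParams) -> float:
    return b.mean


def credible_interval(
    b: BetaParams, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed credible interval: mass (1-level)/2 in each tail."""
    if not 0 < level < 1:
        raise ValueError(f"credible level must lie in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    dist = stats.beta(b.alpha, b.beta)
    return float(dist.ppf(tail)), float(dist.ppf(1.0 - tail))


def futility_probability(b: BetaParams, p0: float) -> float:
    """P(p <= p0) under ``b``: the regularized incomplete beta I_p0(a, b)."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"futility bound must lie in [0, 1], got {p0}")
    return float(special.betainc(b.alpha, b.beta, p0))


def summarize_posterior(
    prior: BetaParams,
    data: BinomialData,
    p0: float,
    level: float = 0.95,
) -> PosteriorSummary:
    """Update ``prior`` with ``data`` and package the reporting quantities."""
    post = posterior_update(prior, data)
    lo, hi = credible_interval(post, level)
    return PosteriorSummary(
        posterior=post,
        mean=post.mean,
        ci_low=lo,
        ci_high=hi,
        futility_prob=futility_probability(post, p0),
        p0=p0,
        ci_level=level,
    )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as trial reports display numbers.

    Python's built-in ``round`` is banker's rounding; display rounding in
    clinical tables is conventional half-up (e.g. 0.05 -> 0.1).
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def as_percent(x: float, ndigits: int = 1) -> float:
    """A proportion on the display scale: 0.2353 -> 23.5."""
    return round_half_up(100.0 * x, ndigits)
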
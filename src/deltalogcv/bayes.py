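"""Bayesian intervals for the common CV under two non-informative priors.

With delta* = 1 - delta (the zero probability), the conjugate posteriors per
population are

    independent Jeffreys:  delta* | x ~ Beta(n0 + 1/2, n1 + 1/2)
                           sigma2 | x ~ Inv-Gamma((n1-1)/2, (n1-1) s2_hat / 2)
    uniform:               delta* | x ~ Beta(n0 + 1, n1 + 1)
                           sigma2 | x ~ Inv-Gamma((n1-2)/2, (n1-2) s2_hat / 2)

(the uniform prior therefore needs n1 >= 3 for a proper sigma2 posterior).
Per posterior draw the common CV is formed exactly as for the point
estimate: the phi transform per group, precision weights, exponentiated
weighted mean.  Three weight treatments are offered, mirroring the FGPQ
module: ``"literal"`` (default) substitutes the drawn (delta, sigma2) into
the variance functional with n1 observed — faithful to the construction as
written, but the functional can change sign; ``"substituted"`` also replaces
n1 by n*delta, keeping the functional strictly positive; ``"frozen"`` keeps
the weights at their data estimates — the tamest variant, whose simulated
coverage tracks the nominal level most tightly.

Equal-tailed intervals cut alpha/2 posterior mass from each tail; "credible"
(HPD) intervals are the shortest window holding the required mass and are
never longer than the equal-tailed ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from ._quantiles import equal_tailed_bounds, hpd_bounds
from .distribution import (
    DegenerateSampleError,
    IntervalEstimate,
    Method,
    SampleSummary,
    log_cv_phi,
    var_phi_functional,
)

DEFAULT_DRAWS = 2000


class Prior(str, enum.Enum):
    JEFFREYS = "jeffreys"
    UNIFORM = "uniform"


@dataclass(frozen=True)
class PosteriorSpec:
    """Conjugate posterior parameters for one population.

    ``beta_a, beta_b`` parameterise the Beta posterior of delta* = 1 - delta;
    ``ig_shape, ig_scale`` the inverse-gamma posterior of sigma2.
    """

    prior: Prior
    beta_a: float
    beta_b: float
    ig_shape: float
    ig_scale: float


@dataclass(frozen=True)
class PosteriorDraws:
    """Posterior draws for k populations: matrices are (draws, groups)."""

    prior: Prior
    delta: np.ndarray
    sigma2: np.ndarray
    eta: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.eta.size

    @property
    def eta_max(self) -> float:
        return float(np.max(self.eta))


def _min_n1(prior: Prior) -> int:
    return 2 if prior is Prior.JEFFREYS else 3


def posterior_parameters(summary: SampleSummary, prior: Prior) -> PosteriorSpec:
    """Posterior (beta, inverse-gamma) parameters for one sample summary."""
    prior = Prior(prior)
    if summary.n1 < _min_n1(prior):
        raise DegenerateSampleError(
            f"the {prior.value} prior needs n1 >= {_min_n1(prior)} "
            f"(got n1={summary.n1}): the sigma2 posterior shape would be <= 0"
        )
    if prior is Prior.JEFFREYS:
        c, m = 0.5, summary.n1 - 1
    else:
        c, m = 1.0, summary.n1 - 2
    return PosteriorSpec(
        prior=prior,
        beta_a=summary.n0 + c,
        beta_b=summary.n1 + c,
        ig_shape=m / 2.0,
        ig_scale=m * summary.sigma2_hat / 2.0,
    )


def posterior_common_cv_draws(
    summaries: list[SampleSummary],
    prior: Prior,
    draws: int = DEFAULT_DRAWS,
    rng: np.random.Generator | None = None,
    weights: str = "literal",
) -> PosteriorDraws:
    """Posterior draws of the common CV for k populations.

    Inverse-gamma variates are realised as scale / Gamma(shape) draws.
    ``weights`` is 'literal', 'substituted' or 'frozen' (module docstring).
    """
    if not summaries:
        raise ValueError("need at least one summary")
    if weights not in ("literal", "substituted", "frozen"):
        raise ValueError(
            f"weights must be 'literal', 'substituted' or 'frozen', got {weights!r}"
        )
    prior = Prior(prior)
    specs = [posterior_parameters(s, prior) for s in summaries]
    rng = np.random.default_rng() if rng is None else rng
    k = len(summaries)
    delta = np.empty((draws, k))
    sigma2 = np.empty((draws, k))
    for i, spec in enumerate(specs):
        delta_star = rng.beta(spec.beta_a, spec.beta_b, draws)
        delta[:, i] = 1.0 - delta_star
        sigma2[:, i] = spec.ig_scale / rng.gamma(spec.ig_shape, 1.0, draws)
    n = np.array([s.n for s in summaries], dtype=float)
    n1 = np.array([s.n1 for s in summaries], dtype=float)
    phi = log_cv_phi(sigma2, delta)
    if weights == "literal":
        w = 1.0 / var_phi_functional(n, n1, delta, sigma2)
    elif weights == "substituted":
        w = 1.0 / var_phi_functional(n, n * delta, delta, sigma2)
    else:
        s2_hat = np.array([s.sigma2_hat for s in summaries])
        w = np.broadcast_to(
            1.0 / var_phi_functional(n, n1, n1 / n, s2_hat), (draws, k)
        )
    with np.errstate(over="ignore"):
        eta = np.exp(np.sum(w * phi, axis=1) / np.sum(w, axis=1))
    return PosteriorDraws(prior=prior, delta=delta, sigma2=sigma2, eta=eta)


def equal_tailed_interval(
    eta, level: float = 0.95, prior: Prior = Prior.JEFFREYS
) -> IntervalEstimate:
    """Equal-tailed credible interval from common-CV posterior draws."""
    lo, hi = equal_tailed_bounds(eta, level)
    method = (
        Method.EB_JEFFREYS if Prior(prior) is Prior.JEFFREYS else Method.EB_UNIFORM
    )
    return IntervalEstimate(method=method, level=level, lower=lo, upper=hi)


def hpd_interval(
    eta, level: float = 0.95, prior: Prior = Prior.JEFFREYS
) -> IntervalEstimate:
    """Highest-posterior-density interval from common-CV posterior draws."""
    lo, hi = hpd_bounds(eta, level)
    method = (
        Method.HPD_JEFFREYS if Prior(prior) is Prior.JEFFREYS else Method.HPD_UNIFORM
    )
    return IntervalEstimate(method=method, level=level, lower=lo, upper=hi)
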
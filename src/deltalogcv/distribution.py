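"""Delta-lognormal distribution primitives and the common coefficient of variation.

A delta-lognormal random variable is zero with probability 1 - delta and
lognormal(mu, sigma2) with probability delta.  It is the standard model for
semicontinuous environmental series such as daily rainfall, where dry days
contribute exact zeros and wet-day amounts are positively skewed.

The coefficient of variation of one population is

    eta = sqrt((exp(sigma2) - delta) / delta),

which is free of mu.  Inference is carried out on the log scale through

    phi = log eta = 0.5 * (log(exp(sigma2) - delta) - log delta),

and several populations are combined into a common CV by exponentiating a
precision-weighted mean of the per-population phi estimates, the weights
being reciprocals of an approximately unbiased variance of phi-hat.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np


class Method(str, enum.Enum):
    """Interval constructions available for the common CV."""

    FGCI = "fgci"
    EB_JEFFREYS = "eb-jeffreys"
    EB_UNIFORM = "eb-uniform"
    HPD_JEFFREYS = "hpd-jeffreys"
    HPD_UNIFORM = "hpd-uniform"
    MOVER = "mover"


ALL_METHODS: tuple[Method, ...] = tuple(Method)


class DegenerateSampleError(ValueError):
    """Raised when a sample has too few non-zero observations for a method."""


@dataclass(frozen=True)
class DeltaLNParams:
    """True parameters of one delta-lognormal population.

    Parameters
    ----------
    delta : float
        Probability of a non-zero observation, in (0, 1].
    mu : float
        Mean of the log of the non-zero part.
    sigma2 : float
        Variance of the log of the non-zero part, > 0.
    """

    delta: float
    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.delta <= 1.0):
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        if not (self.sigma2 > 0.0):
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")

    @property
    def cv(self) -> float:
        """Coefficient of variation eta of this population."""
        return delta_ln_cv(self)


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient statistics of one delta-lognormal sample.

    ``mu_hat`` and ``sigma2_hat`` are the sample mean and unbiased sample
    variance of the logs of the non-zero observations.  A summary with fewer
    than two non-zero observations is *degenerate*: ``sigma2_hat`` is
    undefined (NaN) and all interval methods reject it.
    """

    n: int
    n1: int
    mu_hat: float
    sigma2_hat: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 1 or not (0 <= self.n1 <= self.n):
            raise ValueError(f"need 0 <= n1 <= n, got n={self.n}, n1={self.n1}")
        if self.n1 >= 2 and not (self.sigma2_hat >= 0.0):
            raise ValueError(f"sigma2_hat must be >= 0, got {self.sigma2_hat}")

    @property
    def n0(self) -> int:
        return self.n - self.n1

    @property
    def delta_hat(self) -> float:
        return self.n1 / self.n

    @property
    def degenerate(self) -> bool:
        return self.n1 < 2

    @property
    def phi_hat(self) -> float:
        """Estimated log-CV, Eq.-6-style plug-in of (sigma2_hat, delta_hat)."""
        self.require_nondegenerate()
        return float(log_cv_phi(self.sigma2_hat, self.delta_hat))

    @property
    def cv_hat(self) -> float:
        return math.exp(self.phi_hat)

    def require_nondegenerate(self, minimum_n1: int = 2, context: str = "") -> None:
        if self.n1 < minimum_n1:
            where = f" for {context}" if context else ""
            raise DegenerateSampleError(
                f"sample {self.label or '<unnamed>'} has n1={self.n1} non-zero "
                f"observations; at least {minimum_n1} are required{where}"
            )

    @classmethod
    def from_delta_hat(
        cls,
        n: int,
        delta_hat: float,
        mu_hat: float,
        sigma2_hat: float,
        label: str = "",
    ) -> "SampleSummary":
        """Build a summary from a rounded published delta-hat.

        ``n1`` is recovered as round(delta_hat * n); the product must be
        within 0.01 of an integer, which any delta-hat printed to four
        decimals satisfies.
        """
        prod = delta_hat * n
        n1 = round(prod)
        if abs(prod - n1) >= 0.01:
            raise ValueError(
                f"delta_hat*n = {prod:.4f} is not within 0.01 of an integer; "
                "refusing to guess n1"
            )
        return cls(n=n, n1=n1, mu_hat=mu_hat, sigma2_hat=sigma2_hat, label=label)


@dataclass(frozen=True)
class IntervalEstimate:
    """A method-tagged two-sided interval for the common CV."""

    method: Method
    level: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if not (0.0 < self.lower <= self.upper):
            raise ValueError(
                f"need 0 < lower <= upper, got ({self.lower}, {self.upper})"
            )

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


# ---------------------------------------------------------------------------
# distribution primitives
# ---------------------------------------------------------------------------


def delta_ln_density(x, params: DeltaLNParams):
    """Density / point mass of the delta-lognormal law.

    Returns the point mass 1 - delta at x == 0 and delta times the
    lognormal(mu, sigma2) density for x > 0.  Negative x is a domain error.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("delta-lognormal support is x >= 0")
    sigma = math.sqrt(params.sigma2)
    out = np.zeros_like(x)
    zero = x == 0
    out = np.where(zero, 1.0 - params.delta, out)
    pos = ~zero
    if np.any(pos):
        xp = np.where(pos, x, 1.0)  # dummy 1.0 keeps log() quiet off-branch
        dens = (
            params.delta
            / (xp * sigma * math.sqrt(2.0 * math.pi))
            * np.exp(-0.5 * ((np.log(xp) - params.mu) / sigma) ** 2)
        )
        out = np.where(pos, dens, out)
    return out if out.ndim else float(out)


def delta_ln_moments(params: DeltaLNParams) -> tuple[float, float]:
    """Mean and variance of the delta-lognormal distribution."""
    d, mu, s2 = params.delta, params.mu, params.sigma2
    mean = d * math.exp(mu + s2 / 2.0)
    var = d * math.exp(2.0 * mu + s2) * (math.exp(s2) - d)
    return mean, var


def delta_ln_cv(params: DeltaLNParams) -> float:
    """Coefficient of variation eta = sqrt((exp(sigma2) - delta)/delta)."""
    return float(np.exp(log_cv_phi(params.sigma2, params.delta)))


def log_cv_phi(sigma2, delta):
    """Log coefficient of variation phi = 0.5*(log(exp(s2) - d) - log d).

    Evaluated in log space as 0.5*(s2 + log1p(-d*exp(-s2)) - log d) so that
    sigma2 values of several hundred (routine in pivotal / posterior draws
    at small n1) do not overflow exp.
    Vectorised over numpy arrays.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0.0):
        raise ValueError("delta must be > 0")
    if np.any(delta > 1.0):
        raise ValueError("delta must be <= 1")
    out = 0.5 * (sigma2 + np.log1p(-delta * np.exp(-sigma2)) - np.log(delta))
    return out if out.ndim else float(out)


def sample_delta_ln(params: DeltaLNParams, n: int, rng: np.random.Generator):
    """Draw ``n`` observations: 0 w.p. 1-delta, else exp(Normal(mu, sigma2))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    nonzero = rng.random(n) < params.delta
    x = np.zeros(n)
    k = int(nonzero.sum())
    if k:
        x[nonzero] = np.exp(rng.normal(params.mu, math.sqrt(params.sigma2), k))
    return x


def summarize(observations, label: str = "") -> SampleSummary:
    """Sufficient statistics of an observation vector.

    Exactly-zero entries count as zeros; any positive value (however small)
    belongs to the lognormal part.  With fewer than two positive entries the
    summary is returned degenerate (sigma2_hat = NaN) rather than raising,
    so callers can decide how to handle it.
    """
    x = np.asarray(observations, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("observations must be a non-empty 1-d vector")
    if np.any(x < 0):
        raise ValueError("observations must be non-negative")
    pos = x[x > 0]
    n1 = int(pos.size)
    if n1 >= 2:
        logs = np.log(pos)
        mu_hat = float(logs.mean())
        sigma2_hat = float(logs.var(ddof=1))
    elif n1 == 1:
        mu_hat, sigma2_hat = float(np.log(pos[0])), float("nan")
    else:
        mu_hat, sigma2_hat = float("nan"), float("nan")
    return SampleSummary(
        n=int(x.size), n1=n1, mu_hat=mu_hat, sigma2_hat=sigma2_hat, label=label
    )


# ---------------------------------------------------------------------------
# variance of phi-hat and the weighted common CV
# ---------------------------------------------------------------------------


def var_phi_functional(n, n1, delta, sigma2):
    """The approximately-unbiased variance functional of phi-hat.

    V(n, n1, delta, sigma2) =
        [(b - a)(1 - a b) - n1 (1 - a)^2] / [4 n1 (1 - a)^2]
        + sigma2^2 / (2 (n1 - 1)),
    with a = (1 - delta)^(n-1), b = 1 + (n-1) delta.

    Evaluated at the data estimates (delta = n1/n, sigma2 = sigma2_hat) the
    value is positive.  When pivotal or posterior draws are substituted for
    (delta, sigma2) while n1 stays at its observed value, the first term is
    negative whenever delta < (n1-1)/(n-1), and the total can change sign —
    a documented property of the plug-in construction, not a bug here.
    Vectorised over numpy arrays.
    """
    n = np.asarray(n, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    delta = np.asarray(delta, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    a = (1.0 - delta) ** (n - 1.0)
    b = 1.0 + (n - 1.0) * delta
    one_m_a = 1.0 - a
    first = ((b - a) * (1.0 - a * b) - n1 * one_m_a**2) / (4.0 * n1 * one_m_a**2)
    second = sigma2**2 / (2.0 * (n1 - 1.0))
    out = first + second
    return out if out.ndim else float(out)


def var_phi_hat(summary: SampleSummary) -> float:
    """Estimated variance of phi-hat from one sample summary."""
    summary.require_nondegenerate(context="var_phi_hat")
    v = var_phi_functional(
        summary.n, summary.n1, summary.delta_hat, summary.sigma2_hat
    )
    return float(v)


def common_log_cv(phis, weights) -> float:
    """Weighted mean of per-population log-CV estimates."""
    phis = np.asarray(phis, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if phis.size == 0 or phis.shape != weights.shape:
        raise ValueError("phis and weights must be equal-length, non-empty")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(weights * phis) / np.sum(weights))


def common_cv(summaries: list[SampleSummary]) -> float:
    """Common CV: exp of the precision-weighted mean of the phi-hats.

    Weights are reciprocals of the estimated variances of the phi-hats.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    phis = [s.phi_hat for s in summaries]
    weights = [1.0 / var_phi_hat(s) for s in summaries]
    return float(math.exp(common_log_cv(phis, weights)))
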
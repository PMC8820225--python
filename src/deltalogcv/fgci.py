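"""Fiducial generalized confidence interval (FGCI) for the common CV.

A fiducial generalized pivotal quantity (FGPQ) is a function of the data and
fresh auxiliary randomness whose observed value equals the parameter of
interest; the empirical (alpha/2, 1-alpha/2) quantiles of its draws form a
two-sided generalized confidence interval.

For one population the FGPQs are

    R_delta  ~ 0.5 Beta(n1, n0 + 1) + 0.5 Beta(n1 + 1, n0),
    R_sigma2 = (n1 - 1) sigma2_hat / U,   U ~ chi-square(n1 - 1),

which are pushed through the log-CV transform phi and the variance
functional to give per-draw weights R_w and the common-CV pivot R_eta.

The per-draw weights substitute (R_delta, R_sigma2) into the variance
functional.  Two substitution depths are offered:

* ``weights="literal"`` (default) keeps n1 at its observed value, exactly as
  the construction is usually written.  The functional then changes sign for
  draws with R_delta below (n1-1)/(n-1); near-zero values flip weight signs
  and produce occasional extreme R_eta draws, which is why FGCI interval
  lengths are erratic (sometimes enormous) at moderate-to-large sigma2 and
  why the pivot does not concentrate as n grows.
* ``weights="substituted"`` also replaces the n1 occurrences by n*R_delta
  (n1 is itself the estimate n*delta_hat, so a full substitution of the
  drawn delta is the coherent plug-in).  The functional is then strictly
  positive for every draw and the pivot is consistent.

``PivotalDraws`` records the draw extrema so users can inspect the tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._quantiles import equal_tailed_bounds
from .distribution import (
    IntervalEstimate,
    Method,
    SampleSummary,
    log_cv_phi,
    var_phi_functional,
)

DEFAULT_DRAWS = 2000


@dataclass(frozen=True)
class PivotalDraws:
    """FGPQ draws for k populations: matrices are (draws, groups)."""

    r_delta: np.ndarray
    r_sigma2: np.ndarray
    r_phi: np.ndarray
    r_w: np.ndarray
    r_eta: np.ndarray

    def __post_init__(self) -> None:
        k = self.r_delta.shape
        for name in ("r_sigma2", "r_phi", "r_w"):
            if getattr(self, name).shape != k:
                raise ValueError("pivotal matrices must share their shape")
        if self.r_eta.shape != (k[0],):
            raise ValueError("r_eta must have one entry per draw")

    @property
    def n_draws(self) -> int:
        return self.r_eta.size

    @property
    def eta_max(self) -> float:
        """Largest common-CV pivot draw (diagnostic for tail blow-ups)."""
        return float(np.max(self.r_eta))


def draw_pivotal_delta(
    n1: int, n0: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws of the FGPQ for delta: an equal mixture of two betas.

    Degenerate components (a zero shape parameter) are realised as point
    masses: Beta(n1+1, 0) is the constant 1 and Beta(0, n0+1) the constant 0.
    """
    if n1 < 0 or n0 < 0 or (n1 == 0 and n0 == 0):
        raise ValueError("need n1 + n0 >= 1 with non-negative counts")
    if size < 1:
        raise ValueError("size must be >= 1")
    use_second = rng.random(size) < 0.5
    first = (
        rng.beta(n1, n0 + 1.0, size) if n1 > 0 else np.zeros(size)
    )
    second = (
        rng.beta(n1 + 1.0, n0, size) if n0 > 0 else np.ones(size)
    )
    return np.where(use_second, second, first)


def draw_pivotal_sigma2(
    n1: int, sigma2_hat: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws of the FGPQ for sigma2: (n1-1) sigma2_hat / chi-square(n1-1)."""
    if n1 < 2:
        raise ValueError(f"need n1 >= 2 to pivot sigma2, got {n1}")
    if size < 1:
        raise ValueError("size must be >= 1")
    u = rng.chisquare(n1 - 1, size)
    return (n1 - 1) * sigma2_hat / u


def pivotal_common_cv(
    summaries: list[SampleSummary],
    draws: int = DEFAULT_DRAWS,
    rng: np.random.Generator | None = None,
    weights: str = "literal",
) -> PivotalDraws:
    """FGPQ draws of the common CV for k populations.

    ``weights`` selects the substitution depth in the per-draw variance
    functional: 'literal' (n1 observed) or 'substituted' (n1 -> n*R_delta,
    strictly positive); see the module docstring.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    if weights not in ("literal", "substituted"):
        raise ValueError(
            f"weights must be 'literal' or 'substituted', got {weights!r}"
        )
    for s in summaries:
        s.require_nondegenerate(context="the FGPQ for sigma2")
    rng = np.random.default_rng() if rng is None else rng
    k = len(summaries)
    r_delta = np.empty((draws, k))
    r_sigma2 = np.empty((draws, k))
    for i, s in enumerate(summaries):
        r_delta[:, i] = draw_pivotal_delta(s.n1, s.n0, draws, rng)
        r_sigma2[:, i] = draw_pivotal_sigma2(s.n1, s.sigma2_hat, draws, rng)
    n = np.array([s.n for s in summaries], dtype=float)
    n1 = np.array([s.n1 for s in summaries], dtype=float)
    r_phi = log_cv_phi(r_sigma2, r_delta)
    n1_eff = n * r_delta if weights == "substituted" else n1
    r_v = var_phi_functional(n, n1_eff, r_delta, r_sigma2)
    r_w = 1.0 / r_v
    with np.errstate(over="ignore"):
        r_eta = np.exp(np.sum(r_w * r_phi, axis=1) / np.sum(r_w, axis=1))
    return PivotalDraws(
        r_delta=r_delta, r_sigma2=r_sigma2, r_phi=r_phi, r_w=r_w, r_eta=r_eta
    )


def fgci_interval(r_eta, level: float = 0.95) -> IntervalEstimate:
    """Two-sided FGCI: empirical (alpha/2, 1-alpha/2) quantiles of R_eta."""
    lo, hi = equal_tailed_bounds(r_eta, level)
    return IntervalEstimate(method=Method.FGCI, level=level, lower=lo, upper=hi)
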
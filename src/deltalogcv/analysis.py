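"""One-call analysis: all requested intervals for a set of group summaries."""

from __future__ import annotations

import numpy as np

from . import bayes, fgci, mover
from .distribution import ALL_METHODS, Method, SampleSummary, common_cv
from .io import AnalysisReport


def analyze(
    summaries: list[SampleSummary],
    methods=ALL_METHODS,
    level: float = 0.95,
    draws: int = 2000,
    seed: int | None = None,
    weights: str = "literal",
) -> AnalysisReport:
    """Point estimate and the requested common-CV intervals.

    ``weights`` selects the treatment of the per-draw precision weights:
    'literal' (as written), 'substituted' (sign-safe) or 'frozen'
    (data-estimate weights; posterior sampler only — the FGPQ construction
    falls back to 'substituted' in that case).
    """
    methods = tuple(Method(m) for m in methods)
    rng = np.random.default_rng(seed)
    fgci_weights = "substituted" if weights == "frozen" else weights
    intervals: list = []
    if Method.FGCI in methods:
        piv = fgci.pivotal_common_cv(summaries, draws, rng, weights=fgci_weights)
        intervals.append(fgci.fgci_interval(piv.r_eta, level))
    for prior, et_m, hpd_m in (
        (bayes.Prior.JEFFREYS, Method.EB_JEFFREYS, Method.HPD_JEFFREYS),
        (bayes.Prior.UNIFORM, Method.EB_UNIFORM, Method.HPD_UNIFORM),
    ):
        if et_m in methods or hpd_m in methods:
            post = bayes.posterior_common_cv_draws(
                summaries, prior, draws, rng, weights=weights
            )
            if et_m in methods:
                intervals.append(bayes.equal_tailed_interval(post.eta, level, prior))
            if hpd_m in methods:
                intervals.append(bayes.hpd_interval(post.eta, level, prior))
    if Method.MOVER in methods:
        intervals.append(mover.mover_interval(summaries, level))
    return AnalysisReport(
        summaries=list(summaries),
        point_estimate=common_cv(summaries),
        intervals=intervals,
        level=level,
        draws=draws,
        seed=seed,
    )
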
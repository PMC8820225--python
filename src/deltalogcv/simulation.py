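"""Monte-Carlo coverage / expected-length study for the common-CV intervals.

Each scenario fixes k groups sharing (n, delta, sigma2); since the groups
share parameters, the true common CV equals the single-group CV
sqrt((exp(sigma2) - delta)/delta).  Per simulation run, k datasets are drawn,
summarised, and every requested interval is scored for containment of the
truth and for its length.  Datasets in which any group has fewer than four
non-zero observations are redrawn (and counted): below that, the uniform
prior's sigma2 posterior is improper and the variance functional is fragile.

One master seed spawns one child stream per run, so results are reproducible
and independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes, fgci, mover
from .distribution import (
    ALL_METHODS,
    DeltaLNParams,
    Method,
    delta_ln_cv,
    sample_delta_ln,
    summarize,
)

MIN_NONZERO = 4
DEFAULT_RUNS = 10_000
DEFAULT_DRAWS = 2_000
GRID_K = (3, 5, 10)
GRID_N = (25, 50, 100)
GRID_DELTA = (0.2, 0.5, 0.8)
GRID_SIGMA2 = (0.1, 0.5, 1.0, 2.0)
LOW_COUNT_THRESHOLD = 8  # flag cells whose expected non-zero count n*delta is below this


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation design."""

    k: int
    n: int
    delta: float
    sigma2: float
    level: float = 0.95
    runs: int = DEFAULT_RUNS
    draws: int = DEFAULT_DRAWS
    seed: int = 0
    mu: float = 0.0  # the CV is free of mu; kept explicit for the generator

    def __post_init__(self) -> None:
        if self.k < 1 or self.runs < 1 or self.draws < 100:
            raise ValueError("need k >= 1, runs >= 1, draws >= 100")

    @property
    def true_common_cv(self) -> float:
        return delta_ln_cv(DeltaLNParams(self.delta, self.mu, self.sigma2))

    @property
    def low_count_flag(self) -> bool:
        return self.n * self.delta < LOW_COUNT_THRESHOLD


@dataclass(frozen=True)
class MethodResult:
    """Coverage and length of one method in one scenario."""

    method: Method
    coverage: float
    coverage_se: float
    expected_length: float
    length_se: float
    max_upper: float  # largest interval endpoint seen (tail diagnostic)


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    methods: dict[Method, MethodResult]
    rejected_runs: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, r in self.methods.items():
            rows.append(
                {
                    "k": self.scenario.k,
                    "n": self.scenario.n,
                    "delta": self.scenario.delta,
                    "sigma2": self.scenario.sigma2,
                    "method": m.value,
                    "coverage": r.coverage,
                    "coverage_se": r.coverage_se,
                    "expected_length": r.expected_length,
                    "length_se": r.length_se,
                    "max_upper": r.max_upper,
                    "rejected_runs": self.rejected_runs,
                }
            )
        return pd.DataFrame(rows)


def _sample_group_summaries(sc: Scenario, rng: np.random.Generator):
    """Draw k datasets, redrawing any whose non-zero count is too small."""
    params = DeltaLNParams(sc.delta, sc.mu, sc.sigma2)
    summaries = []
    redraws = 0
    for _ in range(sc.k):
        while True:
            s = summarize(sample_delta_ln(params, sc.n, rng))
            if s.n1 >= MIN_NONZERO:
                summaries.append(s)
                break
            redraws += 1
    return summaries, redraws


def _intervals_for_run(sc: Scenario, summaries, rng, methods):
    out = {}
    if Method.FGCI in methods:
        piv = fgci.pivotal_common_cv(summaries, sc.draws, rng)
        out[Method.FGCI] = fgci.fgci_interval(piv.r_eta, sc.level)
    for prior, et_m, hpd_m in (
        (bayes.Prior.JEFFREYS, Method.EB_JEFFREYS, Method.HPD_JEFFREYS),
        (bayes.Prior.UNIFORM, Method.EB_UNIFORM, Method.HPD_UNIFORM),
    ):
        if et_m in methods or hpd_m in methods:
            post = bayes.posterior_common_cv_draws(summaries, prior, sc.draws, rng)
            if et_m in methods:
                out[et_m] = bayes.equal_tailed_interval(post.eta, sc.level, prior)
            if hpd_m in methods:
                out[hpd_m] = bayes.hpd_interval(post.eta, sc.level, prior)
    if Method.MOVER in methods:
        out[Method.MOVER] = mover.mover_interval(summaries, sc.level)
    return out


def run_scenario(sc: Scenario, methods=ALL_METHODS) -> ScenarioResult:
    """Estimate coverage and expected length for each requested method."""
    methods = tuple(Method(m) for m in methods)
    truth = sc.true_common_cv
    children = np.random.SeedSequence(sc.seed).spawn(sc.runs)
    hits = {m: 0 for m in methods}
    lengths = {m: np.empty(sc.runs) for m in methods}
    max_upper = {m: 0.0 for m in methods}
    rejected = 0
    for r in range(sc.runs):
        rng = np.random.default_rng(children[r])
        summaries, redraws = _sample_group_summaries(sc, rng)
        rejected += redraws
        for m, iv in _intervals_for_run(sc, summaries, rng, methods).items():
            hits[m] += iv.contains(truth)
            lengths[m][r] = iv.length
            max_upper[m] = max(max_upper[m], iv.upper)
    results = {}
    for m in methods:
        p = hits[m] / sc.runs
        el = lengths[m]
        results[m] = MethodResult(
            method=m,
            coverage=p,
            coverage_se=math.sqrt(p * (1.0 - p) / sc.runs),
            expected_length=float(el.mean()),
            length_se=float(el.std(ddof=1) / math.sqrt(sc.runs)) if sc.runs > 1 else 0.0,
            max_upper=max_upper[m],
        )
    return ScenarioResult(scenario=sc, methods=results, rejected_runs=rejected)


def scenario_grid(
    level: float = 0.95,
    runs: int = DEFAULT_RUNS,
    draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> list[Scenario]:
    """The full k x n x delta x sigma2 cross of the study design.

    Cells with expected non-zero count n*delta below 8 (all n=25, delta=0.2
    combinations) are emitted too but carry ``low_count_flag``; they need
    heavy redrawing and their results should be read with care.
    """
    grid = []
    for k in GRID_K:
        for n in GRID_N:
            for delta in GRID_DELTA:
                for sigma2 in GRID_SIGMA2:
                    grid.append(
                        Scenario(
                            k=k, n=n, delta=delta, sigma2=sigma2,
                            level=level, runs=runs, draws=draws, seed=seed,
                        )
                    )
    return grid


def summarize_results(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tabulate results and apply the winner rule per cell.

    A method is a *candidate* when its coverage is at least the nominal
    level; among candidates the shortest expected length wins.  If no method
    reaches nominal coverage, no winner is declared for the cell.
    """
    if not results:
        raise ValueError("need at least one scenario result")
    frames = []
    for res in results:
        df = res.to_frame()
        level = res.scenario.level
        covered = df["coverage"] >= level
        df["covers_nominal"] = covered
        df["winner"] = False
        if covered.any():
            cand = df[covered]
            df.loc[cand["expected_length"].idxmin(), "winner"] = True
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
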
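# Methods

## The model

Daily rainfall and similar semicontinuous series mix exact zeros (dry days)
with positive, right-skewed amounts.  `deltalogcv` models each population
i = 1..k as delta-lognormal: an observation is zero with probability
1 − δᵢ and otherwise lognormal(μᵢ, σᵢ²).  The mean and variance are

    E[X] = δ exp(μ + σ²/2),
    Var[X] = δ exp(2μ + σ²) (exp(σ²) − δ),

so the coefficient of variation (CV) is

    η = sqrt((exp(σ²) − δ)/δ),

free of μ.  All inference happens on the log scale through

    φ = log η = ½ (log(exp(σ²) − δ) − log δ),

estimated by plugging in δ̂ = n₁/n (n₁ = number of non-zeros) and the
unbiased variance σ̂² of the log non-zeros.  φ is always evaluated as
½(σ² + log1p(−δ e^{−σ²}) − log δ): posterior and pivotal σ² draws at small
n₁ can exceed several hundred, and the naive form overflows exp.

A single *common CV* summarises k independent populations:

    η̃ = exp( Σ wᵢ φ̂ᵢ / Σ wᵢ ),   wᵢ = 1 / V̂(φ̂ᵢ),

where V̂ is an approximately unbiased estimate of Var(φ̂):

    V̂ = [(b̂ − â)(1 − â b̂) − n₁ (1 − â)²] / [4 n₁ (1 − â)²] + σ̂⁴ / (2 (n₁ − 1)),
    â = (1 − δ̂)^(n−1),  b̂ = 1 + (n − 1) δ̂.

The implementation treats this formula as given and applies no higher-order
correction.

## Interval constructions

**FGCI.** Fiducial generalized pivotal quantities per population:
R_δ is an equal mixture of Beta(n₁, n₀+1) and Beta(n₁+1, n₀) (a zero shape
parameter degenerates to a point mass at 1 or 0), and
R_σ² = (n₁−1) σ̂² / U with U ~ χ²(n₁−1).  These are pushed through φ and the
variance functional to per-draw weights, giving the common-CV pivot R_η̃; the
empirical (α/2, 1−α/2) quantiles of its draws (linear interpolation between
order statistics, the common statistical default — no convention is
canonical here) form the interval.  Default 2,000 draws.

**Bayesian.** Conjugate posteriors for δ* = 1 − δ and σ²:
Beta(n₀+½, n₁+½) and Inv-Gamma((n₁−1)/2, (n₁−1)σ̂²/2) under the independent
Jeffreys prior; Beta(n₀+1, n₁+1) and Inv-Gamma((n₁−2)/2, (n₁−2)σ̂²/2) under
the uniform prior (which therefore needs n₁ ≥ 3).  δ is sampled via the δ*
route to match the conjugate parameterisation; inverse-gamma draws are
scale / Gamma(shape).  Per-draw common-CV values are formed exactly like the
point estimate; equal-tailed intervals take the (α/2, 1−α/2) quantiles, and
the "credible" interval is the highest-posterior-density (HPD) window: the
shortest contiguous run of sorted draws holding ⌈level·K⌉ of them, leftmost
window on ties.  HPD is never longer than equal-tailed by construction.

**MOVER.** Deterministic closed form.  Component intervals per population —
chi-square for σ² and the arcsine variance-stabilising interval for δ
(half-width z_{1−α/2}/(2√n), clamped to [0, 1]) — are pushed through φ
pairwise (lower with lower, upper with upper, as the construction is
written), then combined:

    L, U = exp( φ̃ ∓ sqrt( Σ wᵢ² (·)² / D ) ),

with (·) the lower/upper offsets from φ̂ᵢ.  Because φ is *decreasing* in δ,
the paired component bounds need not be ordered around φ̂ᵢ at small σ²; the
squares keep the final interval bracketing η̃ regardless, but this pairing is
the root of MOVER's severe undercoverage at small σ² (see Limitations).
Both denominator conventions found in the MOVER literature are implemented:
D = Σwᵢ² (default, the wider interval) and D = (Σwᵢ)².  A δ-component
interval that reaches 0 makes the φ limit unbounded; this is reported
(+inf / a clear error) rather than silently truncated.

## The weight-substitution choice

The per-draw weights substitute the drawn (δ, σ²) into the variance
functional.  How deep the substitution goes is a genuinely open design
point, and the three options are exposed in both samplers:

* `literal` (default): n₁ stays at its observed value, exactly as the
  construction is conventionally written.  The functional's first term is
  negative whenever the drawn δ < (n₁−1)/(n−1) — about half of all draws —
  and the total changes sign when the σ² draw is small.  Near-zero values
  make individual weights explode and the weight sum can cross zero, which
  is why FGCI interval lengths are erratic and sometimes enormous at
  moderate-to-large σ², and why the literal pivot does not concentrate as
  n → ∞.  This is a property of the construction itself and is reproduced,
  not patched; `PivotalDraws`/`PosteriorDraws` record draw maxima so users
  can inspect the tails.
* `substituted`: the n₁ occurrences are replaced by n·δ_draw as well (n₁ is
  itself the estimate n·δ̂, so full substitution is the coherent plug-in).
  The functional is then provably strictly positive for every draw and the
  pivot is consistent; intervals are systematically narrower.
* `frozen` (posterior sampler only): weights stay at their data estimates,
  so only φ varies per draw.  The tamest variant; in simulation its
  equal-tailed Jeffreys coverage tracks the nominal level most tightly.

## Simulation engine

`run_scenario` evaluates coverage and expected length on cells of the
design grid k ∈ {3, 5, 10} × n ∈ {25, 50, 100} × δ ∈ {0.2, 0.5, 0.8} ×
σ² ∈ {0.1, 0.5, 1.0, 2.0} at level 0.95.  All groups share parameters, so
the true common CV is the single-group η (an extension to unequal
parameters would need its own definition of the target).  The generator
uses μ = 0 — the CV is free of μ, so nothing else about the study depends
on it.  Datasets in which any group has n₁ < 4 are redrawn and counted:
below that the uniform prior's σ² posterior is improper and the variance
functional fragile.  Cells with expected non-zero count n·δ < 8 (all
n = 25, δ = 0.2 combinations) are flagged as low-count.  One master seed
spawns one `SeedSequence` child per run, so results are reproducible and
order-independent.  Coverage carries the binomial standard error
sqrt(p(1−p)/runs); lengths carry their sample standard error and are
strongly tail-dominated for the Monte-Carlo methods at σ² ≥ 1, where the
mean length is an unstable summary.  The winner rule per cell: methods with
coverage ≥ the nominal level qualify, and among those the shortest expected
length wins.

Default replication counts are 10,000 runs × 2,000 draws; the bundled
acceptance checks run 3,000 × 1,000, which keeps each cell in the
seconds-to-a-minute range at one CPU while holding the coverage SE near
0.004.

## What the generator does and does not emulate

`sample_delta_ln` reproduces the model exactly: independent Bernoulli wet
days and iid lognormal amounts.  Real rainfall has serial dependence (wet
spells), seasonality, and measurement rounding at the gauge resolution —
none of which are modelled.  Passing tests therefore demonstrate
correctness of the estimators and intervals *under the model*, not
robustness to real-data violations of it.

## Numerical choices

* φ in log space (see above); quantiles by linear interpolation;
  HPD ties broken leftmost.
* Exact-zero semantics: only a literal 0 counts as a zero; trace positives
  (0.1 mm) belong to the lognormal part, since the point mass sits at x = 0
  exactly.
* Summaries entered from rounded published tables recover n₁ as
  round(δ̂·n), refusing if δ̂·n is more than 0.01 from an integer.
* A summary with n₁ < 2 is explicitly degenerate and rejected by every
  method (no silent NaN).
* Reports round to 4 decimals.

## Worked example data

The package's worked example uses the summary statistics of daily rainfall
recorded in August 2018–2019 at three rain-gauge stations in Nan province,
Thailand (Chiang Klang, Tha Wang Pha, Pua): n = 62 days each,
δ̂ = 0.7258 / 0.7903 / 0.7419, μ̂ = 2.1189 / 1.6448 / 1.8971,
σ̂² = 1.7857 / 3.4406 / 1.8346.  The weighted common CV of these summaries
is 3.0233.  (Reports of this analysis elsewhere quote 3.2011 as the point
estimate; that figure is not consistent with the formulas above applied to
these summary statistics — the MOVER interval they print is centred on
ln 3.0233, not ln 3.2011 — so this package reports the value its own
formulas produce.)

## Known limitations

* MOVER's paired component bounds mis-shape the interval at small σ², where
  the δ-component dominates φ; coverage falls far below nominal.  This is
  inherent to the construction and is reproduced, not corrected.
* The literal weight treatment (the default, kept for fidelity) is
  tail-unstable by construction; use `substituted` or `frozen` when
  stability matters more than fidelity.
* Expected lengths of the Monte-Carlo intervals at σ² ≥ 1 are dominated by
  rare extreme draws; compare medians or endpoint quantiles across studies
  rather than mean lengths.
* Only equal per-group sample sizes and shared (δ, σ²) are supported in the
  simulation engine; the analysis functions accept arbitrary summaries.
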
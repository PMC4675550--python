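# Methods

## Model

The tissue is a fixed pool of `N` cells evolving by Moran dynamics:
each cell gives birth at rate 1 and its offspring replaces a uniformly
chosen cell of the pool (possibly its parent; such self-replacements
are dropped from the embedded jump chain, which leaves absorption
probabilities unchanged). Mutations happen at birth: wild-type →
type-I with probability `u`, type-I → type-II with probability `v`.
A type-II birth ends the process (state `E`) regardless of which cell
dies. The cell-count chain on `{0, …, N, E}` therefore has, from a
transient state `k` with `0 < k < N`, the surviving event rates

| transition | rate |
|---|---|
| `k → E` | `k v` |
| `k → k+1` | `k (1−v) (N−k)/N` |
| `k → k−1` | `(N−k) k /N` |

normalized into the embedded jump distribution. Type-I cells are
neutral (benign PA grow slowly or arrest), type-II cells are treated as
an immediate aggressive outcome; a per-cell success probability `s`
for type-II lineages would be equivalent to replacing `v` by `sv` and
is therefore not a separate parameter.

`u` matters only at state 0. In the rare-mutation regime `uN ≪ 1`
(enforced by `TGPParameters.require_rare_type_i()` for the analytic
routines) each type-I lineage is analyzed with `u = 0`; the full
process is recovered in the simulator by re-injecting single mutants
(`0 → 1`) until one lineage absorbs at `N` or `E`. The injection counts
as one embedded jump. The simulator's default `u` is `0.1/N`.

## Parameters

| parameter | meaning | default |
|---|---|---|
| `N` | critical tumor size / relevant competing cell number | — (≥ 2) |
| `u` | first-mutation probability per birth | `0.1/N` (simulator only) |
| `v` | second-mutation probability per birth | derived from `γ` |
| `γ = N²v` | risk coefficient; the only parameter surviving the large-`N` limit | calibrated `0.152` |
| critical volume | volume corresponding to `N` | `9 cm³` |

Exactly one of `v` and `γ` is supplied at construction; the other is
derived exactly. The scaling `γ = N²v` is the one under which the
fixation probability of a neutral lineage (`≈ 1/N`) and its tunneling
probability to a type-II lineage (`≈ √v`) stay comparable, so both
absorbing states keep positive probability as `N → ∞`.

## Absorption analysis

For finite `N`, first-step analysis gives, per absorbing target, a
tridiagonal linear system over the transient states, assembled and
solved with a banded LU routine (`scipy.linalg.solve_banded`). This is
mathematically the same system a determinant/Cramer elimination would
solve, but numerically stable and `O(N)`. The quantity compared to the
cohort data is the *conditional* benign probability of a single mutant,
`α^N(γ) = h_N(1) / (h_N(1) + h_E(1))`: the unconditional `h_N(1)`
vanishes as `N` grows because a lone neutral mutant almost surely dies
out, and the single-mutant decomposition conditions on the successful
lineage. `α^N(γ) → α(γ) = 1/I₀(2√γ)`; at `γ = 0.152` the error is
already below `5·10⁻³` at `N = 10³` and below `2·10⁻²` at `N = 10`.

Bessel functions come from `scipy.special.iv`; an independent
power-series evaluator (`bessel_i_series`, truncation at `1e-15`
relative) is kept as a cross-check and unit-tested against it.

## Regression function and linearity

`β_γ(ρ) = √(1−ρ) I₁(2√(γ(1−ρ)))/I₁(2√γ)` is the large-`N` extinction
probability from `k = ρN`; its finite-`N` analogue is the `hit 0`
component of the same linear solve. Below `γ = 1e-10` the Bessel ratio
is numerically 0/0-prone and the exact neutral limit `1 − ρ` is used
instead. The derivative needed for the Taylor tangent at `ρ = 0.5` is
implemented in closed form via `I₁′ = (I₀ + I₂)/2` and validated
against central finite differences (step `1e-6`). The sup-deviation
between curve and tangent is taken on a `ρ`-grid (default step `1e-5`,
endpoints included); since the curvature of `β_γ` does not change
sign, the supremum sits at an endpoint (at `ρ = 0`, value `0.0185` for
`γ = 0.152`) and the grid is a safety net rather than a necessity. The
analytic remainder bound is `γ/8 = 0.019`; the observed supremum
`0.0185` is reported separately from the bound and the two are not
conflated.

## Calibration

`p̂ = benign/total` with a Wald standard error `√(p̂(1−p̂)/n)`,
matching the one-standard-deviation band used to draw the uncertainty
curves; an exact Clopper–Pearson 68.27% interval is available via
`method="clopper-pearson"` as safer engineering for small cohorts.
`γ̂` solves `α(γ) = p̂` by bracketed root finding (`brentq`) on the
strictly decreasing `α`, upper bracket doubled until it straddles the
root, residual on `α` below `1e-10`. `p̂ = 1` maps to `γ̂ = 0`. The
`γ` interval is the image of `p̂ ∓ stderr` under the inverse (the
larger benign fraction gives the smaller risk). `γ̂` is kept at full
precision internally; comparisons against 3-decimal published-style
values round at the end. Note the estimate is, if anything, an
overestimate of the true risk: diagnosed benign tumors may exceed the
critical size `N` (diagnostic gap), which would only make the
regression curve more linear; this caveat is documented, not modeled.

## Prediction

Volume maps to `ρ` by pure proportion against the critical volume
(cell number ∝ volume). Probabilities are reported in percent, rounded
half-away-from-zero at 2 decimals (configurable) to match tabular
presentation conventions; Python's bankers' rounding would differ on
exact halves. Volumes at or above the critical volume return 0% with a
warning rather than an error, since the critical size is defined as
the point beyond which regression is no longer expected. Two published-
style table entries deserve note: at 0.1 cm³ the curve gives 98.81%
and at 7 cm³ it gives 20.97%; the package reports the computed values
(the full column is reproduced by `prediction_table()` and asserted in
the tests).

The linearity report contrasts the calibrated curve (max deviation
from its midpoint tangent 1.85 percentage points; mean gain ≈ 11.1
points per resected cm³ across integer volumes 1–8) with a fictive
high-risk curve `γ = 50` (deviation > 90 points, strongly convex) —
the quantitative content of the no-extent-of-resection-threshold
conclusion.

## Synthetic data

`generate_cohort` draws `benign ~ Binomial(n, α(γ_true))` — exactly
the sampling structure the calibration inverts, with the asymptotic
`α` as ground truth (a `finite_N` flag switches to `α^N` for
sensitivity checks of the large-`N` assumption). Cohorts with zero
aggressive cases calibrate to `γ̂ = 0` and stay in recovery samples;
rejecting them would bias the pipeline. What the generator does *not*
emulate: volumetric measurement error, the diagnostic-gap inflation of
`γ̂`, or between-study heterogeneity in the benign fraction — so
passing recovery tests certify the statistical consistency of the
estimator under the model's own assumptions, not robustness to
real-world misclassification.

`generate_resection_outcomes` samples trajectories of the `u = 0`
chain from the residual cell count and reports the empirical
regression fraction with its binomial standard error, cross-checked
against the exact solve.

## Simulation and reproducibility

Trajectory stepping is JIT-compiled (numba). Batches derive one uint32
stream seed per replicate from the master seed via
`numpy.random.SeedSequence(seed).generate_state(reps)`; replicate `r`
seeds its own legacy RNG with word `r`. Identical inputs give
bit-identical summaries. A step cap (default `10⁹` embedded jumps)
turns a non-terminating loop into an informative `StepCapExceeded`.

Problem sizes used in the shipped tests and checks — exact solves up
to `N = 2000`, Monte-Carlo batches of `10⁴` replicates at `N ≤ 200`,
200 synthetic cohorts of `10⁴` patients — were chosen as desk-scale
settings at which binomial 3-standard-error bands are tight enough to
be informative while the whole suite runs in seconds.

## Known limitations

- No spatial structure; the "relevant cell number" equals the critical
  size `N` by assumption.
- Type-I neutrality and instant type-II success are modeling choices;
  a success probability `s < 1` only rescales `v` and is not exposed.
- The asymptotic curve is used for prediction; finite-`N` corrections
  are available (`beta_finite`) but at `N` of clinical magnitude they
  are far below measurement uncertainty.
- Expected absorption times and quasi-stationary behavior are out of
  scope; only absorption probabilities are computed.
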
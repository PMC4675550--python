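# tgpmodel

Stochastic growth-and-progression modelling for pilocytic astrocytoma
(PA), the most common pediatric brain tumor. When a PA can only be
partially resected, the residual tumor may regrow, progress to an
aggressive form, or regress spontaneously. This package implements a
Moran-chain model of that competition, calibrates it against
epidemiological cohort counts, and turns the result into a quantitative
prediction: the probability of spontaneous regression as a function of
residual tumor volume.

It is a library first — the intended audience is computational
biologists and biostatisticians working from Python — with a thin
`tgpmodel` command-line wrapper for the common one-shot queries.

## The model

A homeostatic tissue of `N` competing cells evolves by Moran dynamics:
one cell dies, another reproduces. Wild-type cells mutate to *type-I*
(one oncogenic MAPK-pathway alteration, no fitness effect) with
probability `u` per birth; type-I cells mutate to *type-II* (a second
alteration, e.g. CDKN2A loss, aggressive behavior) with probability `v`.
The cell-count chain on `S = {0, 1, …, N, E}` absorbs at

- `N` — the type-I clone reaches the critical size: a benign **PA-I** tumor,
- `E` — a type-II cell appears first: an aggressive **PA-II** tumor,
- `0` — the clone dies out (for a residual tumor: spontaneous regression).

With rare first mutations (`uN ≪ 1`) each type-I lineage can be
analyzed alone, and as `N → ∞` with the **risk coefficient**
`γ = N²v` held fixed, the chance that a successful mutant founds a
benign rather than aggressive tumor has the closed form

    α(γ) = 1 / I₀(2√γ),

and the probability that a residual tumor occupying fraction
`ρ = k/N` of the critical size regresses is

    β_γ(ρ) = √(1−ρ) · I₁(2√(γ(1−ρ))) / I₁(2√γ),

where `I₀, I₁` are modified Bessel functions of the first kind. Both
closed forms are validated in the test suite against exact tridiagonal
first-step solves at finite `N` and against Monte-Carlo trajectories of
the jump chain.

Calibration matches `α(γ̂)` to the observed benign fraction
`p̂ = 57/66 ≈ 0.8636` from a 66-patient genetic-profiling cohort,
giving `γ̂ ≈ 0.152`. Mapping residual volume `V` to `ρ = V/9 cm³`
(the critical volume above which regression is not observed) yields the
prediction table below. The curve's first-order Taylor polynomial at
`ρ = 0.5` carries the remainder bound `|R₁| ≤ γ/8 < 0.02`, so the
volume–probability relationship is essentially linear: there is no
extent-of-resection threshold — every resected cm³ buys roughly the
same ~11 percentage points of regression probability.

## Worked example

```python
from tgpmodel import CohortCounts, calibrate, prediction_table, table_to_frame

result = calibrate(CohortCounts(benign=57, aggressive=9))
print(round(result.gamma_hat, 3))          # 0.152
print(table_to_frame(prediction_table()))
```

prints the calibrated risk coefficient `0.152` and the table

```
 residual_volume_cm3  regression_probability_pct
                 0.1                       98.81
                 0.5                       94.06
                 1.0                       88.16
                 2.0                       76.50
                 3.0                       65.03
                 4.0                       53.75
                 5.0                       42.64
                 6.0                       31.71
                 7.0                       20.97
                 8.0                       10.39
```

i.e. a residual tumor of 1 cm³ regresses with probability 88.16%, one
of 8 cm³ with only 10.39% — and the near-constant ~11-point drop per
cm³ is the no-threshold result. The scripts in `examples/` walk through
each capability (calibration, volume prediction, exact/simulated/
asymptotic absorption comparison, linearity analysis, synthetic-cohort
parameter recovery) and print the numbers they compute.

Equivalent shell one-liners:

```sh
tgpmodel calibrate --benign 57 --aggressive 9
tgpmodel predict --volume 1
tgpmodel table
tgpmodel compare --n-list 10,50,100 --gamma 0.152 --reps 10000 --seed 7
```

## Reproducibility of simulations

Every stochastic routine takes an integer seed. Batch simulations
derive one 32-bit stream seed per replicate from the master seed via
`numpy.random.SeedSequence(seed).generate_state(reps)`, so results are
bit-identical across runs and machines for the same
`(parameters, k0, reps, seed)`.
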
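"""Moran-type tumor growth-and-progression (TGP) chain.

The chain lives on S = {0, 1, ..., N, E}: state k counts type-I cells
(one oncogenic alteration, no fitness effect) in a homeostatic tissue of
N competing cells; E marks the appearance of the first type-II cell
(second alteration, aggressive progression). N and E are absorbing: a
tumor that accumulates N type-I cells is a benign PA-I tumor that can no
longer regress, while a single type-II cell means an aggressive PA-II
tumor. State 0 (all wild-type) is absorbing in the u = 0 sub-process.

Dynamics: each cell gives birth at rate 1 and its offspring replaces a
uniformly chosen cell of the N. A type-I birth produces a type-II
offspring with probability v, which jumps the chain to E regardless of
which cell dies. Self-replacements are dropped from the embedded jump
chain; they do not affect absorption behavior. From a transient state k
the surviving event rates are

    k -> E     at  k * v
    k -> k+1   at  k * (1 - v) * (N - k) / N
    k -> k-1   at  (N - k) * k / N

The wild-type -> type-I probability u only matters at state 0: under the
rare-mutation regime u*N << 1 each type-I lineage is analyzed in
isolation (u set to 0 while type-I cells are present), and the full
process is recovered by re-injecting single mutants at state 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._kernels import run_batch, run_trajectory

__all__ = [
    "TGPParameters",
    "TGPState",
    "JumpDistribution",
    "TrajectoryOutcome",
    "SimulationSummary",
    "StepCapExceeded",
    "jump_distribution",
    "simulate_trajectory",
    "simulate_batch",
    "trajectories_to_frame",
    "DEFAULT_STEP_CAP",
]

DEFAULT_STEP_CAP = 10**9

#: Outcome codes used by the compiled kernels.
_ABSORB_LABELS = {0: "0", 1: "N", 2: "E"}


@dataclass(frozen=True)
class TGPParameters:
    """Parameters of the TGP chain.

    Exactly one of ``v`` (type-I -> type-II mutation probability per
    birth) and ``gamma`` (risk coefficient, gamma = N**2 * v) is given;
    the other is derived. ``u`` is the wild-type -> type-I mutation
    probability per birth and defaults to the rare-mutation scale 0.1/N.
    """

    N: int
    u: float | None = None
    v: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if (self.v is None) == (self.gamma is None):
            raise ValueError("supply exactly one of v and gamma")
        if self.gamma is None:
            object.__setattr__(self, "gamma", self.N**2 * self.v)
        else:
            if self.gamma < 0:
                raise ValueError("gamma must be nonnegative")
            v = self.gamma / self.N**2
            if v >= 1:
                raise ValueError(
                    f"gamma={self.gamma} with N={self.N} implies v={v} >= 1"
                )
            object.__setattr__(self, "v", v)
        if not 0 <= self.v < 1:
            raise ValueError(f"v must lie in [0, 1), got {self.v}")
        if self.u is None:
            object.__setattr__(self, "u", 0.1 / self.N)
        if not 0 <= self.u < 1:
            raise ValueError(f"u must lie in [0, 1), got {self.u}")

    def require_rare_type_i(self) -> None:
        """Check the decomposition regime u*N < 1 for analytic use."""
        if self.u * self.N >= 1:
            raise ValueError(
                f"u*N = {self.u * self.N} >= 1: the single-mutant "
                "decomposition requires rare type-I mutations"
            )


@dataclass(frozen=True)
class TGPState:
    """A point of the state space {0..N} ∪ {E}."""

    tag: Literal["count", "aggressive"]
    k: int = 0

    def __post_init__(self) -> None:
        if self.tag not in ("count", "aggressive"):
            raise ValueError(f"unknown tag {self.tag!r}")


@dataclass(frozen=True)
class JumpDistribution:
    """Embedded one-step probabilities from a transient state k."""

    p_up: float
    p_down: float
    p_to_E: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_up, self.p_down, self.p_to_E])


@dataclass(frozen=True)
class TrajectoryOutcome:
    absorbing_state: Literal["0", "N", "E"]
    steps: int
    seed: int


@dataclass(frozen=True)
class SimulationSummary:
    """Empirical absorption fractions with binomial standard errors."""

    reps: int
    fraction_0: float
    fraction_N: float
    fraction_E: float
    stderr_0: float
    stderr_N: float
    stderr_E: float
    seed: int


class StepCapExceeded(RuntimeError):
    pass


def _event_rates(params: TGPParameters, k: int) -> tuple[float, float, float]:
    N, v = params.N, params.v
    return (
        k * (1.0 - v) * (N - k) / N,  # up
        (N - k) * k / N,  # down
        k * v,  # to E
    )


def jump_distribution(params: TGPParameters, k: int) -> JumpDistribution:
    """Normalized embedded jump probabilities from transient state k.

    Uses the u = 0 sub-process: the only events are type-I births
    (offspring type-II with probability v) and wild-type births, with
    self-replacements removed.
    """
    if not 0 < k < params.N:
        raise ValueError(f"k must lie strictly between 0 and N={params.N}, got {k}")
    up, down, to_e = _event_rates(params, k)
    total = up + down + to_e
    return JumpDistribution(p_up=up / total, p_down=down / total, p_to_E=to_e / total)


def simulate_trajectory(
    params: TGPParameters,
    k0: int,
    seed: int,
    step_cap: int = DEFAULT_STEP_CAP,
) -> TrajectoryOutcome:
    """Run one embedded-chain trajectory from k0 until absorption.

    Starting at an absorbing state returns immediately with steps = 0.
    Starting at 0 with u > 0 injects a single type-I mutant (0 -> 1,
    one step) and repeats the injection whenever the lineage goes
    extinct, so the trajectory ends at N or E — the full-process
    decomposition into unsuccessful and successful mutants.
    """
    if not 0 <= k0 <= params.N:
        raise ValueError(f"k0 must lie in [0, N={params.N}], got {k0}")
    inject = params.u > 0
    if k0 == 0 and not inject:
        return TrajectoryOutcome(absorbing_state="0", steps=0, seed=seed)
    code, steps = run_trajectory(
        params.N, params.v, inject, k0, int(seed) & 0xFFFFFFFF, step_cap
    )
    if code < 0:
        raise StepCapExceeded(
            f"trajectory from k0={k0} (N={params.N}, v={params.v}) did not "
            f"absorb within {step_cap} embedded steps"
        )
    return TrajectoryOutcome(absorbing_state=_ABSORB_LABELS[code], steps=int(steps), seed=seed)


def _replicate_seeds(seed: int, reps: int) -> np.ndarray:
    """Per-replicate RNG seeds: one uint32 word each, drawn from the
    master seed's SeedSequence. Deterministic and documented."""
    return np.random.SeedSequence(seed).generate_state(reps)


def simulate_batch(
    params: TGPParameters,
    k0: int,
    reps: int,
    seed: int,
    step_cap: int = DEFAULT_STEP_CAP,
) -> SimulationSummary:
    """Run ``reps`` independent trajectories and summarize absorption.

    Replicate r uses its own RNG stream seeded with the r-th uint32
    produced by ``numpy.random.SeedSequence(seed)``, so results are
    bit-identical for identical (params, k0, reps, seed).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if not 0 <= k0 <= params.N:
        raise ValueError(f"k0 must lie in [0, N={params.N}], got {k0}")
    inject = params.u > 0
    if k0 == 0 and not inject:
        raise ValueError("k0 = 0 with u = 0 is absorbing: nothing to simulate")
    seeds = _replicate_seeds(seed, reps)
    codes, steps = run_batch(params.N, params.v, inject, k0, seeds, step_cap)
    if (codes < 0).any():
        raise StepCapExceeded(
            f"{int((codes < 0).sum())} of {reps} trajectories exceeded the "
            f"step cap {step_cap}"
        )
    fracs = [float((codes == c).mean()) for c in (0, 1, 2)]
    errs = [float(np.sqrt(f * (1.0 - f) / reps)) for f in fracs]
    return SimulationSummary(
        reps=reps,
        fraction_0=fracs[0],
        fraction_N=fracs[1],
        fraction_E=fracs[2],
        stderr_0=errs[0],
        stderr_N=errs[1],
        stderr_E=errs[2],
        seed=seed,
    )


def trajectories_to_frame(
    params: TGPParameters,
    k0: int,
    reps: int,
    seed: int,
    step_cap: int = DEFAULT_STEP_CAP,
) -> pd.DataFrame:
    """Per-replicate outcome records (replicate, k0, absorbing_state,
    steps, seed) suitable for CSV export."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    seeds = _replicate_seeds(seed, reps)
    inject = params.u > 0
    codes, steps = run_batch(params.N, params.v, inject, k0, seeds, step_cap)
    if (codes < 0).any():
        raise StepCapExceeded("some trajectories exceeded the step cap")
    return pd.DataFrame(
        {
            "replicate": np.arange(reps),
            "k0": k0,
            "absorbing_state": [_ABSORB_LABELS[int(c)] for c in codes],
            "steps": steps.astype(np.int64),
            "seed": seeds.astype(np.int64),
        }
    )
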
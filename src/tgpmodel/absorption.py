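"""Absorption probabilities of the TGP chain: exact finite-N solves and
the large-N closed form.

First-step analysis on the u = 0 sub-process gives, for each absorbing
target A in {0, N, E}, a linear system over the transient states
k = 1..N-1:

    h(k) = p_up(k) h(k+1) + p_down(k) h(k-1) + p_to_E(k) [A == E]

with boundary values h(0) = [A == 0] and h(N) = [A == N]. The systems
are tridiagonal and solved with a banded LU routine.

As N -> infinity with gamma = N**2 * v held fixed, the probability that
a single successful type-I mutant produces a benign PA-I tumor (hits N)
rather than an aggressive PA-II tumor (hits E) converges to

    alpha(gamma) = 1 / I0(2 sqrt(gamma)),

with I0 the modified Bessel function of the first kind, order 0. alpha
is strictly decreasing in gamma, alpha(0) = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.special import iv

from .process import TGPParameters, jump_distribution, simulate_batch

__all__ = [
    "AbsorptionProfile",
    "AbsorptionComparisonRow",
    "absorption_probs_finite",
    "alpha_finite",
    "alpha_asymptotic",
    "bessel_i_series",
    "compare_absorption",
    "comparison_to_frame",
]


@dataclass(frozen=True)
class AbsorptionProfile:
    """Probabilities of hitting 0, N and E indexed by start state k = 0..N."""

    N: int
    gamma: float
    hit_zero: np.ndarray
    hit_N: np.ndarray
    hit_E: np.ndarray


@dataclass(frozen=True)
class AbsorptionComparisonRow:
    N: int
    alpha_exact: float
    alpha_simulated: float
    alpha_asymptotic: float
    reps: int
    stderr: float


def _jump_arrays(params: TGPParameters) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    N = params.N
    rows = [jump_distribution(params, k).as_array() for k in range(1, N)]
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1], arr[:, 2]  # p_up, p_down, p_to_E


def absorption_probs_finite(params: TGPParameters) -> AbsorptionProfile:
    """Exact absorption probabilities of the u = 0 sub-process.

    Solves the three first-step tridiagonal systems (one per absorbing
    target) with shared matrix and different right-hand sides.
    """
    params.require_rare_type_i()
    N = params.N
    p_up, p_down, p_to_e = _jump_arrays(params)

    # (I - P_transient) h = b, assembled in banded form for solve_banded.
    n = N - 1
    ab = np.zeros((3, n))
    ab[1, :] = 1.0
    ab[0, 1:] = -p_up[:-1]  # superdiagonal
    ab[2, :-1] = -p_down[1:]  # subdiagonal

    b_zero = np.zeros(n)
    b_zero[0] = p_down[0]
    b_n = np.zeros(n)
    b_n[-1] = p_up[-1]
    b_e = p_to_e.copy()

    h_zero = solve_banded((1, 1), ab, b_zero)
    h_n = solve_banded((1, 1), ab, b_n)
    h_e = solve_banded((1, 1), ab, b_e)

    hit_zero = np.concatenate(([1.0], h_zero, [0.0]))
    hit_n = np.concatenate(([0.0], h_n, [1.0]))
    hit_e = np.concatenate(([0.0], h_e, [0.0]))
    return AbsorptionProfile(
        N=N, gamma=params.gamma, hit_zero=hit_zero, hit_N=hit_n, hit_E=hit_e
    )


def alpha_finite(N: int, gamma: float) -> float:
    """Exact finite-N probability that a successful single mutant yields
    a PA-I tumor: hit_N[1] / (hit_N[1] + hit_E[1]).

    The unconditional hit_N[1] vanishes as N grows (a lone neutral
    mutant almost surely dies out); conditioning on non-extinction is
    what the single-mutant decomposition of the full process demands.
    """
    profile = absorption_probs_finite(TGPParameters(N=N, gamma=gamma, u=0.0))
    num = profile.hit_N[1]
    denom = profile.hit_N[1] + profile.hit_E[1]
    return float(num / denom)


def alpha_asymptotic(gamma: float) -> float:
    """Large-N absorption probability in state N: 1 / I0(2 sqrt(gamma))."""
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    return float(1.0 / iv(0, 2.0 * math.sqrt(gamma)))


def bessel_i_series(n: int, x: float, rtol: float = 1e-15) -> float:
    """Modified Bessel I_n(x) by its power series
    sum_k (x/2)^(2k+n) / (k! (k+n)!), truncated when a term drops below
    ``rtol`` relative to the partial sum. Cross-check path for the
    library Bessel routine."""
    if n < 0:
        raise ValueError("order must be nonnegative")
    half = x / 2.0
    term = half**n / math.factorial(n)
    total = term
    k = 1
    while True:
        term *= half * half / (k * (k + n))
        total += term
        if abs(term) <= rtol * abs(total):
            return total
        k += 1
        if k > 10_000:  # pragma: no cover - series converges long before
            raise RuntimeError(f"I_{n}({x}) series failed to converge")


def compare_absorption(
    N_list: Sequence[int],
    gamma: float,
    reps: int,
    seed: int,
) -> list[AbsorptionComparisonRow]:
    """Three-way comparison of the PA-I probability for a single mutant:
    exact linear solve, Monte-Carlo estimate from k0 = 1, and the
    asymptotic closed form.

    The simulated value conditions on non-extinction (trajectories
    ending at N or E); its standard error is binomial on that
    conditional sample.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    a_inf = alpha_asymptotic(gamma)
    rows = []
    for i, N in enumerate(N_list):
        if N < 2:
            raise ValueError(f"each N must be >= 2, got {N}")
        params = TGPParameters(N=N, gamma=gamma, u=0.0)
        summary = simulate_batch(params, k0=1, reps=reps, seed=seed + i)
        success = summary.fraction_N + summary.fraction_E
        a_sim = summary.fraction_N / success if success > 0 else float("nan")
        m = int(round(success * reps))
        err = math.sqrt(a_sim * (1 - a_sim) / m) if m > 0 else float("nan")
        rows.append(
            AbsorptionComparisonRow(
                N=N,
                alpha_exact=alpha_finite(N, gamma),
                alpha_simulated=a_sim,
                alpha_asymptotic=a_inf,
                reps=reps,
                stderr=err,
            )
        )
    return rows


def comparison_to_frame(rows: Sequence[AbsorptionComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "N": [r.N for r in rows],
            "alpha_exact": [r.alpha_exact for r in rows],
            "alpha_simulated": [r.alpha_simulated for r in rows],
            "stderr": [r.stderr for r in rows],
            "alpha_asymptotic": [r.alpha_asymptotic for r in rows],
        }
    )
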
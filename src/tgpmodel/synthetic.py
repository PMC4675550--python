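"""Synthetic cohorts and resection outcomes with the statistical
structure the analysis assumes.

The calibration pipeline interprets the observed benign fraction as the
model's absorption probability alpha(gamma); the matching generative
process draws the benign count binomially with success probability
alpha(true_gamma). Resection outcomes are trajectory samples of the
u = 0 sub-process started from the residual cell count. Both let the
generate -> calibrate -> predict loop be validated end to end without
any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .absorption import alpha_asymptotic, alpha_finite
from .calibration import CohortCounts, calibrate, calibrate_gamma
from .process import TGPParameters, simulate_batch, trajectories_to_frame

__all__ = [
    "SyntheticCohortSpec",
    "RecoveryReport",
    "ResectionOutcomes",
    "generate_cohort",
    "parameter_recovery",
    "generate_resection_outcomes",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    true_gamma: float
    n_patients: int
    seed: int
    finite_N: int | None = None  # draw with alpha^N instead of the asymptotic alpha

    def __post_init__(self) -> None:
        if self.true_gamma < 0:
            raise ValueError("true_gamma must be nonnegative")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass(frozen=True)
class RecoveryReport:
    true_gamma: float
    n_cohorts: int
    mean_gamma_hat: float
    sd_gamma_hat: float
    coverage: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "true_gamma": self.true_gamma,
            "n_cohorts": self.n_cohorts,
            "mean_gamma_hat": self.mean_gamma_hat,
            "sd_gamma_hat": self.sd_gamma_hat,
            "coverage": self.coverage,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ResectionOutcomes:
    records: pd.DataFrame
    regression_fraction: float
    regression_stderr: float
    seed: int


def generate_cohort(spec: SyntheticCohortSpec) -> CohortCounts:
    """Cohort counts with benign ~ Binomial(n, alpha(true_gamma)).

    With ``finite_N`` set, the exact finite-N conditional absorption
    probability is used instead of the asymptotic closed form — a
    sensitivity check on the large-N assumption baked into calibration.
    """
    if spec.finite_N is None:
        p = alpha_asymptotic(spec.true_gamma)
    else:
        p = alpha_finite(spec.finite_N, spec.true_gamma)
    rng = np.random.default_rng(spec.seed)
    benign = int(rng.binomial(spec.n_patients, p))
    return CohortCounts(benign=benign, aggressive=spec.n_patients - benign)


def parameter_recovery(
    true_gamma: float,
    n_patients: int,
    n_cohorts: int,
    seed: int,
) -> RecoveryReport:
    """Generate cohorts, calibrate each, and report bias, spread and
    coverage of the one-standard-error gamma interval.

    Degenerate cohorts with zero aggressive cases calibrate to
    gamma_hat = 0 (p_hat = 1) and stay in the sample; their interval is
    the point {0} and covers only true_gamma = 0.
    """
    if n_cohorts < 2:
        raise ValueError("n_cohorts must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cohorts)
    gamma_hats = np.empty(n_cohorts)
    covered = 0
    for i, s in enumerate(child_seeds):
        cohort = generate_cohort(
            SyntheticCohortSpec(true_gamma=true_gamma, n_patients=n_patients, seed=int(s))
        )
        result = calibrate(cohort)
        gamma_hats[i] = result.gamma_hat
        lo, hi = result.gamma_interval
        if lo <= true_gamma <= hi:
            covered += 1
    return RecoveryReport(
        true_gamma=true_gamma,
        n_cohorts=n_cohorts,
        mean_gamma_hat=float(gamma_hats.mean()),
        sd_gamma_hat=float(gamma_hats.std(ddof=1)),
        coverage=covered / n_cohorts,
        seed=seed,
    )


def generate_resection_outcomes(
    N: int,
    gamma: float,
    k0: int,
    reps: int,
    seed: int,
) -> ResectionOutcomes:
    """Trajectory outcomes of a residual tumor of k0 cells (u = 0
    sub-process) plus the empirical regression fraction with its
    binomial standard error."""
    if not 0 < k0 < N:
        raise ValueError(f"k0 must lie strictly between 0 and N={N}, got {k0}")
    params = TGPParameters(N=N, gamma=gamma, u=0.0)
    records = trajectories_to_frame(params, k0=k0, reps=reps, seed=seed)
    frac = float((records["absorbing_state"] == "0").mean())
    err = math.sqrt(frac * (1.0 - frac) / reps)
    return ResectionOutcomes(
        records=records, regression_fraction=frac, regression_stderr=err, seed=seed
    )
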
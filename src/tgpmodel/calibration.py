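"""Calibration of the risk coefficient from cohort counts.

The clinically observed fraction of benign (PA-I) tumors among all PA,
p_hat = benign / (benign + aggressive), is matched to the model's
asymptotic probability of absorbing at N:

    alpha(gamma) = 1 / I0(2 sqrt(gamma)) = p_hat.

Strict monotonicity of alpha makes the inverse unique; a bracketed root
find recovers gamma_hat. Sampling noise in p_hat (binomial) is pushed
through the inverse to a gamma interval, and the calibrated regression
curve beta_{gamma_hat} is exposed with its two printed-form constants,
the prefactor 1 / I1(2 sqrt(gamma_hat)) and the Bessel argument
coefficient 2 sqrt(gamma_hat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import iv
from scipy.stats import beta as beta_dist

from .absorption import alpha_asymptotic
from .regression import beta_asymptotic

__all__ = [
    "CohortCounts",
    "CalibrationResult",
    "CalibratedRegressionCurve",
    "estimate_fraction",
    "calibrate_gamma",
    "gamma_uncertainty",
    "pa_regression_function",
    "calibrate",
]

_ALPHA_TOL = 1e-10


@dataclass(frozen=True)
class CohortCounts:
    """Benign (PA-I) and aggressive (PA-II) case counts."""

    benign: int
    aggressive: int

    def __post_init__(self) -> None:
        if self.benign < 0 or self.aggressive < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("cohort must contain at least one case")

    @property
    def total(self) -> int:
        return self.benign + self.aggressive


@dataclass(frozen=True)
class CalibrationResult:
    p_hat: float
    p_hat_stderr: float
    gamma_hat: float
    gamma_interval: tuple[float, float]
    solver_tolerance: float = _ALPHA_TOL

    def to_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "p_hat_stderr": self.p_hat_stderr,
            "gamma_hat": self.gamma_hat,
            "gamma_low": self.gamma_interval[0],
            "gamma_high": self.gamma_interval[1],
        }


def estimate_fraction(
    cohort: CohortCounts, method: str = "wald"
) -> tuple[float, float]:
    """Benign fraction p_hat and its uncertainty.

    ``method='wald'`` returns the binomial standard error
    sqrt(p (1-p) / n); ``method='clopper-pearson'`` returns half the
    width of the exact central 68.27% interval, a safer scale for small
    cohorts.
    """
    n = cohort.total
    p = cohort.benign / n
    if method == "wald":
        err = math.sqrt(p * (1.0 - p) / n)
    elif method == "clopper-pearson":
        level = 0.6827  # matches the one-standard-deviation band
        lo = (
            0.0
            if cohort.benign == 0
            else beta_dist.ppf((1 - level) / 2, cohort.benign, n - cohort.benign + 1)
        )
        hi = (
            1.0
            if cohort.benign == n
            else beta_dist.ppf((1 + level) / 2, cohort.benign + 1, n - cohort.benign)
        )
        err = (hi - lo) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, err


def calibrate_gamma(p_hat: float) -> float:
    """The unique gamma with alpha(gamma) = p_hat.

    Bracketed root find on the strictly decreasing alpha, with the upper
    bracket doubled until it straddles the root; residual |alpha - p|
    held below 1e-10.
    """
    if not 0 < p_hat <= 1:
        raise ValueError(f"p_hat must lie in (0, 1], got {p_hat}")
    if p_hat == 1.0:
        return 0.0
    hi = 1.0
    while alpha_asymptotic(hi) > p_hat:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError(f"bracket expansion failed for p_hat={p_hat}")
    root = brentq(lambda g: alpha_asymptotic(g) - p_hat, 0.0, hi, xtol=1e-14)
    if abs(alpha_asymptotic(root) - p_hat) > _ALPHA_TOL:
        raise RuntimeError("root finder failed to reach tolerance")
    return float(root)


def gamma_uncertainty(
    cohort: CohortCounts, method: str = "wald"
) -> tuple[float, float]:
    """(low, high) gamma interval from p_hat -/+ one standard error.

    alpha is decreasing, so the larger benign fraction maps to the
    smaller risk coefficient.
    """
    p, err = estimate_fraction(cohort, method=method)
    if p - err <= 0:
        raise ValueError(
            "p_hat - stderr is not positive; the upper gamma bound is undefined"
        )
    low = calibrate_gamma(min(p + err, 1.0))
    high = calibrate_gamma(p - err)
    return low, high


@dataclass(frozen=True)
class CalibratedRegressionCurve:
    """beta_{gamma_hat}(rho) in its printed form
    prefactor * sqrt(1-rho) * I1(arg_coefficient * sqrt(1-rho))."""

    gamma_hat: float
    prefactor: float
    arg_coefficient: float

    def __call__(self, rho):
        return beta_asymptotic(self.gamma_hat, rho)


def pa_regression_function(gamma_hat: float) -> CalibratedRegressionCurve:
    if gamma_hat <= 0:
        raise ValueError(f"gamma_hat must be positive, got {gamma_hat}")
    arg = 2.0 * math.sqrt(gamma_hat)
    return CalibratedRegressionCurve(
        gamma_hat=gamma_hat, prefactor=float(1.0 / iv(1, arg)), arg_coefficient=arg
    )


def calibrate(cohort: CohortCounts, method: str = "wald") -> CalibrationResult:
    """Full calibration: fraction estimate, risk coefficient, and the
    gamma interval implied by one standard error on p_hat."""
    p, err = estimate_fraction(cohort, method=method)
    gamma_hat = calibrate_gamma(p)
    if err == 0.0:
        interval = (gamma_hat, gamma_hat)
    elif p - err <= 0:
        interval = (calibrate_gamma(min(p + err, 1.0)), float("inf"))
    else:
        interval = gamma_uncertainty(cohort, method=method)
    return CalibrationResult(
        p_hat=p, p_hat_stderr=err, gamma_hat=gamma_hat, gamma_interval=interval
    )
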
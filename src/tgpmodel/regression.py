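"""The tumor-regression function and its linearity analysis.

After partial resection leaves k type-I cells of the critical size N
(residual fraction rho = k/N), the same Moran competition that built the
tumor decides its fate: regression (state 0), regrowth to a benign PA-I
tumor (state N), or progression (state E). The regression function is
the probability of hitting 0 from k. Its large-N diffusion limit, at
fixed risk coefficient gamma = N**2 * v, has the closed form

    beta_gamma(rho) = sqrt(1 - rho) * I1(2 sqrt(gamma (1 - rho)))
                                    / I1(2 sqrt(gamma)),

with beta_gamma(0) = 1, beta_gamma(1) = 0, strictly decreasing in rho.
At gamma = 0 this degenerates to the neutral Moran extinction
probability 1 - rho. The function is nearly linear for small gamma: its
first-order Taylor polynomial T1 at rho = 0.5 carries a remainder bound
|R1(rho)| <= gamma / 8 on [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import iv

from .absorption import absorption_probs_finite
from .process import TGPParameters

__all__ = [
    "TaylorApproximation",
    "beta_asymptotic",
    "beta_prime",
    "beta_finite",
    "taylor_t1",
    "taylor_coefficients",
    "remainder_bound",
    "max_taylor_deviation",
    "curve_frame",
    "NEUTRAL_GAMMA_CUTOFF",
]

#: Below this gamma the Bessel ratio is numerically 0/0-prone; beta is
#: evaluated by its exact neutral limit 1 - rho instead.
NEUTRAL_GAMMA_CUTOFF = 1e-10


@dataclass(frozen=True)
class TaylorApproximation:
    """First-order Taylor description of beta_gamma around rho = 0.5."""

    gamma: float
    expansion_point: float
    intercept_at_0: float
    slope: float
    remainder_bound: float
    max_observed_deviation: float


def _check_rho(rho: np.ndarray | float) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must lie in [0, 1]")
    return rho


def beta_asymptotic(gamma: float, rho: np.ndarray | float):
    """Asymptotic regression probability beta_gamma(rho); vectorized in rho."""
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    rho = _check_rho(rho)
    if gamma < NEUTRAL_GAMMA_CUTOFF:
        out = 1.0 - rho
    else:
        a = 2.0 * math.sqrt(gamma)
        s = np.sqrt(1.0 - rho)
        out = s * iv(1, a * s) / iv(1, a)
    return float(out) if out.ndim == 0 else out


def beta_prime(gamma: float, rho: np.ndarray | float):
    """d beta_gamma / d rho, from the closed form with I1'(x) = (I0 + I2)/2."""
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    rho = _check_rho(rho)
    if gamma < NEUTRAL_GAMMA_CUTOFF:
        out = np.full_like(rho, -1.0)
    else:
        a = 2.0 * math.sqrt(gamma)
        s = np.sqrt(1.0 - rho)
        x = a * s
        out = -(iv(1, x) + s * a * (iv(0, x) + iv(2, x)) / 2.0) / (
            2.0 * s * iv(1, a)
        )
    return float(out) if out.ndim == 0 else out


def beta_finite(N: int, gamma: float, k: int) -> float:
    """Exact finite-N regression probability: the chance of hitting 0
    from k in the u = 0 sub-process with three absorbing states."""
    if not 0 <= k <= N:
        raise ValueError(f"k must lie in [0, N={N}], got {k}")
    profile = absorption_probs_finite(TGPParameters(N=N, gamma=gamma, u=0.0))
    return float(profile.hit_zero[k])


def taylor_coefficients(gamma: float) -> tuple[float, float]:
    """(value, slope) of beta_gamma at the expansion point rho = 0.5."""
    return beta_asymptotic(gamma, 0.5), beta_prime(gamma, 0.5)


def taylor_t1(gamma: float, rho: np.ndarray | float):
    """First-order Taylor polynomial of beta_gamma at rho = 0.5."""
    rho = _check_rho(rho)
    value, slope = taylor_coefficients(gamma)
    out = value + slope * (rho - 0.5)
    return float(out) if out.ndim == 0 else out


def remainder_bound(gamma: float) -> float:
    """Analytic bound gamma / 8 on the Taylor remainder |R1| over [0, 1]."""
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    return gamma / 8.0


def max_taylor_deviation(gamma: float, grid_step: float = 1e-5) -> TaylorApproximation:
    """Supremum of |beta_gamma - T1| on a rho grid covering [0, 1].

    The curvature of beta_gamma does not change sign, so the tangent at
    the midpoint deviates most at the endpoints; the grid is a safety
    check rather than a necessity.
    """
    if not 0 < grid_step <= 1e-3:
        raise ValueError(f"grid_step must lie in (0, 1e-3], got {grid_step}")
    n = int(math.ceil(1.0 / grid_step))
    rho = np.linspace(0.0, 1.0, n + 1)
    value, slope = taylor_coefficients(gamma)
    dev = np.abs(beta_asymptotic(gamma, rho) - (value + slope * (rho - 0.5)))
    return TaylorApproximation(
        gamma=gamma,
        expansion_point=0.5,
        intercept_at_0=value - 0.5 * slope,
        slope=slope,
        remainder_bound=remainder_bound(gamma),
        max_observed_deviation=float(dev.max()),
    )


def curve_frame(gamma: float, grid_step: float = 1e-3) -> pd.DataFrame:
    """Regression curve, its Taylor line and their gap on a rho grid,
    ready for CSV export or plotting."""
    n = int(math.ceil(1.0 / grid_step))
    rho = np.linspace(0.0, 1.0, n + 1)
    beta = beta_asymptotic(gamma, rho)
    t1 = taylor_t1(gamma, rho)
    return pd.DataFrame(
        {"rho": rho, "beta": beta, "t1": t1, "abs_deviation": np.abs(beta - t1)}
    )
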
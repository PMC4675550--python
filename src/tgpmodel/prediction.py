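"""Volume-based prediction of post-resection regression probability.

Residual tumor volume maps to the residual fraction rho by pure
proportion against a critical volume (default 9 cm^3, the size above
which spontaneous regression of cerebellar PA has not been reported);
the calibrated regression curve then gives the regression probability
on the percent scale. The near-linearity of the curve at the calibrated
risk coefficient means every resected cm^3 buys roughly the same
probability gain — there is no extent-of-resection threshold, unlike in
glioblastoma.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .regression import beta_asymptotic, max_taylor_deviation

__all__ = [
    "PredictionConfig",
    "PredictionRow",
    "EORLinearityReport",
    "DEFAULT_VOLUMES",
    "regression_probability",
    "prediction_table",
    "table_to_frame",
    "eor_linearity_report",
]

logger = logging.getLogger(__name__)

#: Volume grid of the headline prediction table (cm^3).
DEFAULT_VOLUMES: tuple[float, ...] = (0.1, 0.5, 1, 2, 3, 4, 5, 6, 7, 8)

DEFAULT_GAMMA = 0.152
DEFAULT_CRITICAL_VOLUME = 9.0


@dataclass(frozen=True)
class PredictionConfig:
    critical_volume: float = DEFAULT_CRITICAL_VOLUME
    gamma: float = DEFAULT_GAMMA
    output_precision: int = 2

    def __post_init__(self) -> None:
        if self.critical_volume <= 0:
            raise ValueError("critical_volume must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.output_precision < 0:
            raise ValueError("output_precision must be nonnegative")


@dataclass(frozen=True)
class PredictionRow:
    volume_cm3: float
    rho: float
    regression_probability_pct: float


@dataclass(frozen=True)
class EORLinearityReport:
    gamma: float
    max_deviation_pct: float
    avg_gain_per_cm3_pct: float
    comparison_gamma: float
    comparison_max_deviation_pct: float
    comparison_avg_gain_per_cm3_pct: float


def _round_half_up(x: float, digits: int) -> float:
    """Round half away from zero, matching the printed-table convention
    (Python's round() would round half to even)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def regression_probability(
    volume_cm3: float, config: PredictionConfig = PredictionConfig()
) -> float:
    """Regression probability in percent for a residual volume.

    Volumes at or above the critical volume return 0 with a warning:
    the critical size is defined as the size beyond which regression is
    no longer expected.
    """
    if volume_cm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_cm3}")
    if volume_cm3 >= config.critical_volume:
        warnings.warn(
            f"residual volume {volume_cm3} cm^3 is at or above the critical "
            f"volume {config.critical_volume} cm^3: regression probability 0",
            stacklevel=2,
        )
        return 0.0
    rho = volume_cm3 / config.critical_volume
    pct = 100.0 * beta_asymptotic(config.gamma, rho)
    return _round_half_up(pct, config.output_precision)


def prediction_table(
    volumes: Sequence[float] = DEFAULT_VOLUMES,
    config: PredictionConfig = PredictionConfig(),
) -> list[PredictionRow]:
    """One prediction row per residual volume."""
    if len(volumes) == 0:
        raise ValueError("volumes must be nonempty")
    rows = []
    for vol in volumes:
        if vol >= config.critical_volume:
            logger.warning(
                "volume %s cm^3 >= critical volume %s cm^3; emitting 0%%",
                vol,
                config.critical_volume,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pct = regression_probability(vol, config)
            rho = 1.0
        else:
            pct = regression_probability(vol, config)
            rho = vol / config.critical_volume
        rows.append(
            PredictionRow(volume_cm3=vol, rho=rho, regression_probability_pct=pct)
        )
    return rows


def table_to_frame(rows: Sequence[PredictionRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residual_volume_cm3": [r.volume_cm3 for r in rows],
            "regression_probability_pct": [r.regression_probability_pct for r in rows],
        }
    )


def eor_linearity_report(
    gamma: float = DEFAULT_GAMMA,
    config: PredictionConfig | None = None,
    comparison_gamma: float = 50.0,
) -> EORLinearityReport:
    """Quantify how linear the volume-to-probability relationship is.

    Reports (in percentage points) the maximal deviation of the curve
    from its midpoint tangent, and the average probability gained per
    resected cm^3 across the integer volumes of the default grid; the
    same two numbers for a fictitious high risk coefficient (default 50)
    show what threshold-like, strongly convex behavior would look like.
    """
    if config is None:
        config = PredictionConfig(gamma=gamma)

    def _metrics(g: float) -> tuple[float, float]:
        dev = 100.0 * max_taylor_deviation(g, grid_step=1e-5).max_observed_deviation
        vols = [v for v in (1, 2, 3, 4, 5, 6, 7, 8) if v < config.critical_volume]
        cfg = PredictionConfig(
            critical_volume=config.critical_volume,
            gamma=g,
            output_precision=10,
        )
        probs = [regression_probability(v, cfg) for v in vols]
        gains = [
            (probs[i] - probs[i + 1]) / (vols[i + 1] - vols[i])
            for i in range(len(vols) - 1)
        ]
        return dev, sum(gains) / len(gains)

    dev, gain = _metrics(gamma)
    cdev, cgain = _metrics(comparison_gamma)
    return EORLinearityReport(
        gamma=gamma,
        max_deviation_pct=dev,
        avg_gain_per_cm3_pct=gain,
        comparison_gamma=comparison_gamma,
        comparison_max_deviation_pct=cdev,
        comparison_avg_gain_per_cm3_pct=cgain,
    )
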
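"""Elongation-rate estimation, division intervals, and division asymmetry.

Single *E. coli* cells elongate exponentially within a cycle, so the
elongation rate r (min⁻¹) is estimated as the slope of an ordinary
least-squares fit of log-length on time -- deterministic, closed form, and
exact on noiseless exponential input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .lineage import DivisionPair

__all__ = [
    "GrowthMetrics",
    "DiameterRate",
    "fit_elongation_rate",
    "asymmetry_ratio",
    "lineage_diameter_rates",
]


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit."""


@dataclass
class GrowthMetrics:
    """Per-cycle growth summary from the log-linear elongation fit."""

    elongation_rate: float  # min^-1
    division_interval: float  # minutes between first and last length frame
    birth_length: float  # µm, first observed length
    fit_r_squared: float

    def __post_init__(self) -> None:
        if self.division_interval <= 0:
            raise ValueError("division_interval must be positive")


@dataclass
class DiameterRate:
    """Diameter change between two observed generations of one lineage."""

    generation: int  # later generation of the pair
    rate_per_hour: float  # µm/h
    rate_per_generation: float  # µm per generation step
    gap_spanning: bool  # True when intervening generations were missed


def fit_elongation_rate(length_series: Sequence[Tuple[float, float]]) -> GrowthMetrics:
    """OLS fit of ln(length) on time over one cell cycle.

    Requires at least three observations with strictly positive lengths.
    Returns the rate (slope, min⁻¹), the observed interval between the
    first and last frame, the birth length, and the R² of the log-linear
    fit (defined as 1 for a constant series, where the slope is exactly 0).
    """
    if len(length_series) < 3:
        raise InsufficientDataError(
            f"elongation fit needs >= 3 observations, got {len(length_series)}"
        )
    t = np.asarray([p[0] for p in length_series], dtype=float)
    length = np.asarray([p[1] for p in length_series], dtype=float)
    if np.any(length <= 0):
        raise ValueError("lengths must be strictly positive")
    y = np.log(length)
    t_c = t - t.mean()
    denom = float(t_c @ t_c)
    if denom == 0.0:
        raise ValueError("degenerate time axis (all observations at one time)")
    slope = float(t_c @ (y - y.mean())) / denom
    resid = (y - y.mean()) - slope * t_c
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float((resid**2).sum()) / ss_tot
    return GrowthMetrics(
        elongation_rate=slope,
        division_interval=float(t[-1] - t[0]),
        birth_length=float(length[0]),
        fit_r_squared=float(np.clip(r2, 0.0, 1.0)),
    )


def asymmetry_ratio(pair: DivisionPair) -> float:
    """Morphological asymmetry A = mother birth length / daughter birth length.

    A > 1 indicates an off-center fission leaving the old-pole cell longer;
    swapping the two cells maps A to 1/A.
    """
    lm = pair.mother.birth_length
    ld = pair.daughter.birth_length
    if lm <= 0 or ld <= 0:
        raise ValueError("birth lengths must be positive")
    return lm / ld


def lineage_diameter_rates(
    calls_by_generation: Iterable[Tuple[int, float, float]],
) -> List[DiameterRate]:
    """Per-step aggregate diameter change rates for one mother lineage.

    Input is an ordered sequence of ``(generation, time_min, diameter_um)``
    for the generations where a focus was detected.  Each consecutive pair
    of observations yields one rate over the actually elapsed time;
    generation gaps (missed detections) are spanned, not interpolated, and
    flagged ``gap_spanning``.  Fewer than two observations yield an empty
    list.
    """
    obs = sorted(calls_by_generation)
    rates: List[DiameterRate] = []
    for (g1, t1, d1), (g2, t2, d2) in zip(obs, obs[1:]):
        if g2 <= g1:
            raise ValueError(f"duplicate or unordered generation index {g2}")
        if t2 <= t1:
            raise ValueError("observation times must increase with generation")
        hours = (t2 - t1) / 60.0
        rates.append(
            DiameterRate(
                generation=g2,
                rate_per_hour=(d2 - d1) / hours,
                rate_per_generation=(d2 - d1) / (g2 - g1),
                gap_spanning=(g2 - g1) > 1,
            )
        )
    return rates
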
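"""Critical thermal limits, environmental extremes, and thermal safety margins.

Critical thermal limits (CTmax / CTmin) are the temperatures at which a fish
loses equilibrium (LOE) under a constant water-temperature ramp (0.1 degC
per minute by default). Because internal body temperature lags the water
ramp in a mass-dependent way, the water temperature read at LOE
overestimates (CTmax) or underestimates (CTmin) the true internal limit;
:func:`internal_temp_at_loe` corrects for this with a first-order lag model.

Thermal safety margins (TSMs) compare an individual's critical limit with
the environmental extreme it actually experiences: the mean annual maximum
sea surface temperature in summer, the mean annual minimum in winter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CTTrial",
    "TSMRecord",
    "lag_coefficient",
    "internal_temp_at_loe",
    "env_extremes",
    "annual_stats",
    "thermal_safety_margin",
]


@dataclass
class CTTrial:
    """One critical-thermal ramp trial for one fish."""

    fish_id: str
    species: str
    region: str
    acclimation_temp: float
    direction: str  # "max" or "min"
    ramp_rate: float  # degC / min
    water_temp_at_loe: float
    mass: float  # g
    internal_temp_at_loe: float | None = None
    #: populated only by the synthetic generator, for recovery tests
    true_internal_limit: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("max", "min"):
            raise ValueError("direction must be 'max' or 'min'")
        if self.direction == "max" and self.water_temp_at_loe <= self.acclimation_temp:
            raise ValueError("CTmax endpoint must exceed the start temperature")
        if self.direction == "min" and self.water_temp_at_loe >= self.acclimation_temp:
            raise ValueError("CTmin endpoint must be below the start temperature")


@dataclass
class TSMRecord:
    """Thermal safety margin of one fish against one environmental extreme."""

    fish_id: str
    species: str
    region: str
    season: str  # "summer" or "winter"
    critical_limit: float
    environmental_extreme: float
    margin: float
    flagged: bool = False  # negative margin


def lag_coefficient(mass: float, lag_k0: float, lag_gamma: float) -> float:
    """First-order lag rate k = lag_k0 * mass^(-lag_gamma), 1/min.

    Larger fish equilibrate more slowly (k decreases with mass for
    lag_gamma > 0). ``lag_k0`` is the coefficient at 1 g.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    k = lag_k0 * mass ** (-lag_gamma)
    if k <= 0:
        raise ValueError("lag coefficient must be positive")
    return k


def internal_temp_at_loe(
    water_temp_at_loe: float,
    start_temp: float,
    ramp_rate: float,
    mass: float,
    lag_k0: float,
    lag_gamma: float,
) -> float:
    """Internal body temperature when LOE was observed, degC.

    Body temperature follows dTb/dt = k (Tw - Tb) with
    k = lag_k0 * mass^(-lag_gamma). Under a linear ramp Tw = T0 +/- r t the
    closed form is

        Tb = Tw -/+ (r/k) (1 - exp(-k t)),

    i.e. the body lags the water by up to r/k degrees: below the water on a
    heating ramp, above it on a cooling ramp. ``t`` is the elapsed ramp time
    |Tw_loe - T0| / r.
    """
    if ramp_rate <= 0:
        raise ValueError("ramp rate must be positive")
    k = lag_coefficient(mass, lag_k0, lag_gamma)
    delta = water_temp_at_loe - start_temp
    t_elapsed = abs(delta) / ramp_rate
    lag = (ramp_rate / k) * (1.0 - math.exp(-k * t_elapsed))
    return water_temp_at_loe - math.copysign(lag, delta)


# ---------------------------------------------------------------------------
# environmental summaries

#: months whose full coverage is required for a year to contribute its
#: maximum (summer) or minimum (winter); northern-hemisphere defaults,
#: configurable for other climates
SUMMER_MONTHS: tuple[int, ...] = (7, 8, 9)
WINTER_MONTHS: tuple[int, ...] = (1, 2, 3)

#: minimum days present in a season-month for it to count as covered
_MIN_DAYS_PER_MONTH = 20


def _season_covered(sub: pd.DataFrame, months: Sequence[int]) -> bool:
    counts = sub["date"].dt.month.value_counts()
    return all(counts.get(m, 0) >= _MIN_DAYS_PER_MONTH for m in months)


def env_extremes(
    series: pd.DataFrame,
    window: tuple[str, str] | None = None,
    *,
    summer_months: Sequence[int] = SUMMER_MONTHS,
    winter_months: Sequence[int] = WINTER_MONTHS,
) -> tuple[float, float]:
    """Mean annual maximum and mean annual minimum SST over a window.

    Per calendar year the daily maximum and minimum are taken; the returned
    pair is the across-year mean of each. A partially covered year (for
    example the trailing year of an observation window) contributes its
    maximum only if the configured summer months are covered and its
    minimum only if the winter months are — otherwise a truncated year
    would bias the extreme toward the season it happens to include.
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    if window is not None:
        lo, hi = pd.to_datetime(window[0]), pd.to_datetime(window[1])
        df = df[(df["date"] >= lo) & (df["date"] <= hi)]
    if df.empty:
        raise ValueError("no SST observations in the requested window")
    maxima, minima = [], []
    for _year, sub in df.groupby(df["date"].dt.year):
        if _season_covered(sub, summer_months):
            maxima.append(sub["sst_c"].max())
        if _season_covered(sub, winter_months):
            minima.append(sub["sst_c"].min())
    if not maxima or not minima:
        raise ValueError("window does not cover a complete seasonal cycle")
    return float(np.mean(maxima)), float(np.mean(minima))


def annual_stats(series: pd.DataFrame, *, min_days: int = 300) -> pd.DataFrame:
    """Per calendar year median and range (max - min) of daily SST.

    Years with fewer than ``min_days`` observations are dropped with a
    warning; their extremes would not be comparable to complete years.
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    rows = []
    for year, sub in df.groupby(df["date"].dt.year):
        if len(sub) < min_days:
            logger.warning("dropping year %s: only %d days of SST", year, len(sub))
            continue
        rows.append(
            {
                "year": int(year),
                "median": float(sub["sst_c"].median()),
                "range": float(sub["sst_c"].max() - sub["sst_c"].min()),
            }
        )
    return pd.DataFrame(rows, columns=["year", "median", "range"])


def thermal_safety_margin(critical_limit: float, extreme: float, season: str) -> float:
    """Signed thermal safety margin, degC.

    Summer: CTmax minus the mean annual environmental maximum.
    Winter: mean annual environmental minimum minus CTmin.
    Positive margins mean the environment stays inside the fish's tolerance;
    negative margins are allowed (and should be flagged by callers).
    """
    if season == "summer":
        return critical_limit - extreme
    if season == "winter":
        return extreme - critical_limit
    raise ValueError(f"unknown season {season!r}")
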
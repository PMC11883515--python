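"""Oxygen traces to metabolic traits.

The raw unit of intermittent-flow respirometry is an oxygen trace: a
time-stamped dissolved-O2 series for one chamber, alternating sealed
"measure" phases (during which the fish draws oxygen down) and "flush"
phases (which re-equilibrate the chamber). This module turns such traces
into per-fish metabolic traits:

* per-cycle oxygen uptake rates (MO2, mg O2 kg^-1 h^-1) from ordinary
  least-squares slopes of O2 against time within each measure phase;
* maximum metabolic rate (MMR): the MO2 of the *first* measure phase after
  the exhaustive chase protocol;
* standard metabolic rate (SMR): a low quantile (default the 0.20 quantile)
  of MO2 over the remainder of the overnight trial, excluding the first
  five hours of post-exercise elevation;
* background correction: microbial oxygen consumption measured in the
  empty chamber before and after the trial, converted to the same
  mass-specific units and subtracted (pre-trial background from MMR,
  post-trial background from SMR);
* aerobic scope (AS): corrected MMR minus corrected SMR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SlopeFit",
    "MetabolicTraits",
    "segment_cycles",
    "fit_slope",
    "compute_mo2",
    "background_mo2",
    "mo2_series",
    "estimate_mmr",
    "estimate_smr",
    "correct_background",
    "aerobic_scope",
    "extract_traits",
]


@dataclass(frozen=True)
class SlopeFit:
    slope: float  # mg O2 / L / min
    r2: float  # NaN when the window has zero O2 variance
    n: int


@dataclass
class MetabolicTraits:
    """SMR / MMR / aerobic scope for one fish (mg O2 kg^-1 h^-1)."""

    fish_id: str
    smr_raw: float
    mmr_raw: float
    smr_corrected: float
    mmr_corrected: float
    aerobic_scope: float
    background_pre: float  # mass-specific equivalents subtracted from MMR
    background_post: float  # ... and from SMR
    mass: float  # g
    acclimation_temp: float
    species: str = ""
    region: str = ""
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# cycle segmentation and slope fitting


def segment_cycles(
    trace: pd.DataFrame,
    schedule: "object | None" = None,
    *,
    min_samples: int = 2,
) -> list[pd.DataFrame]:
    """Split a trace into its measure-phase windows, in time order.

    Phase labels take precedence; a cycle schedule (an object with
    ``total`` and ``measure`` attributes, in minutes) is used only when the
    trace carries no usable labels. Windows shorter than ``min_samples``
    are dropped with a warning — a mislabeled or empty phase should not
    produce a degenerate slope.
    """
    has_labels = "phase" in trace.columns and trace["phase"].isin(["measure"]).any()
    if not has_labels and schedule is None:
        raise ValueError("trace has no measure-phase labels and no schedule given")
    if has_labels:
        measuring = (trace["phase"] == "measure").to_numpy()
    else:
        t = trace["time_min"].to_numpy(dtype=float)
        t_in = np.mod(t, schedule.total)
        measuring = t_in < schedule.measure
    # contiguous runs of measuring samples
    idx = np.flatnonzero(measuring)
    if idx.size == 0:
        raise ValueError("no measure windows found in trace")
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [idx.size]))
    windows = []
    for s, e in zip(starts, ends):
        win = trace.iloc[idx[s]:idx[e - 1] + 1]
        if len(win) < min_samples:
            logger.warning(
                "dropping measure window at t=%.2f min with %d sample(s)",
                win["time_min"].iloc[0] if len(win) else float("nan"), len(win),
            )
            continue
        windows.append(win)
    if not windows:
        raise ValueError("no measure windows of usable length found")
    return windows


def fit_slope(window: pd.DataFrame) -> SlopeFit:
    """OLS slope of O2 against time within one measure window.

    A window with zero O2 variance (a stuck sensor, or a truly inactive
    chamber) has an undefined r2; it is reported as slope 0 with r2 = NaN
    so callers can flag rather than crash.
    """
    t = window["time_min"].to_numpy(dtype=float)
    y = window["o2_mg_per_l"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("slope fit needs at least 2 samples")
    sxx = np.sum((t - t.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if np.ptp(y) == 0.0:
        return SlopeFit(slope=0.0, r2=float("nan"), n=len(t))
    sxy = np.sum((t - t.mean()) * (y - y.mean()))
    slope = sxy / sxx
    ss_res = syy - slope * sxy
    return SlopeFit(slope=float(slope), r2=float(1.0 - ss_res / syy), n=len(t))


def compute_mo2(slope: float, chamber_volume: float, fish_mass: float) -> float:
    """Mass-specific oxygen uptake from a chamber O2 slope.

    mo2 = (-slope) * (V_chamber - V_fish) * 60 / mass_kg, in
    mg O2 kg^-1 h^-1, where the fish displaces its own volume of water
    (density 1 g/mL). A positive chamber slope (O2 rising) yields a
    negative mo2 — callers flag it, the sign convention is preserved.
    """
    if fish_mass <= 0:
        raise ValueError("fish mass must be positive")
    mass_kg = fish_mass / 1000.0
    v_eff = chamber_volume - fish_mass / 1000.0
    if v_eff <= 0:
        raise ValueError("fish volume reaches or exceeds chamber volume")
    return (-slope) * v_eff * 60.0 / mass_kg


def background_mo2(bg_slope: float, chamber_volume: float, fish_mass: float) -> float:
    """Background (empty-chamber) slope as a mass-specific MO2 equivalent.

    The chamber is empty during the background measurement, so the full
    chamber volume applies; normalisation is still by the fish's mass so
    the equivalent can be subtracted from its traits.
    """
    if fish_mass <= 0:
        raise ValueError("fish mass must be positive")
    return (-bg_slope) * chamber_volume * 60.0 / (fish_mass / 1000.0)


def mo2_series(
    trace: pd.DataFrame,
    chamber_volume: float,
    fish_mass: float,
    *,
    schedule: "object | None" = None,
    r2_threshold: float = 0.9,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Per-cycle MO2 table: cycle_index, cycle_start_time, mo2, slope_r2, flagged.

    One row per measure phase. Cycles whose slope r2 falls below
    ``r2_threshold`` (or whose slope is positive) are flagged, never
    dropped — downstream estimators decide what to do with them.
    """
    windows = segment_cycles(trace, schedule, min_samples=min_samples)
    rows = []
    for i, win in enumerate(windows):
        fit = fit_slope(win)
        mo2 = compute_mo2(fit.slope, chamber_volume, fish_mass)
        flagged = (not math.isnan(fit.r2) and fit.r2 < r2_threshold) or fit.slope > 0
        rows.append(
            {
                "cycle_index": i,
                "cycle_start_time": float(win["time_min"].iloc[0]),
                "mo2": mo2,
                "slope_r2": fit.r2,
                "flagged": bool(flagged or math.isnan(fit.r2)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait estimators


def estimate_mmr(series: pd.DataFrame, *, use_max_cycle: bool = False) -> float:
    """Maximum metabolic rate from a per-cycle MO2 series.

    By protocol the fish enters the chamber immediately after exhaustive
    exercise, so MMR is the MO2 of the *first* measurement cycle — even if
    a later cycle happens to be larger. ``use_max_cycle=True`` switches to
    the maximum over cycles (off by default).
    """
    if len(series) == 0:
        raise ValueError("empty MO2 series")
    if use_max_cycle:
        return float(series["mo2"].max())
    first = series.loc[series["cycle_index"].idxmin()]
    return float(first["mo2"])


def estimate_smr(
    series: pd.DataFrame,
    exclude_hours: float = 5.0,
    q: float = 0.20,
    *,
    min_cycles: int = 10,
    method: str = "quantile",
) -> float:
    """Standard metabolic rate: a low quantile of overnight MO2.

    Cycles starting before ``exclude_hours`` are discarded (post-exercise
    recovery keeps MO2 elevated early in the trial); the boundary cycle at
    exactly ``exclude_hours`` is *included* (half-open convention). Over
    the remaining cycles the default estimator is the linear-interpolation
    ``q`` quantile; ``method="mean_lowest"`` instead averages the lowest
    ``q`` fraction of values (an alternative reading of "lowest 20th
    percentile" — see the methods note).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    keep = series[series["cycle_start_time"] >= exclude_hours * 60.0]
    if len(keep) < min_cycles:
        raise ValueError(
            f"only {len(keep)} cycles remain after excluding the first "
            f"{exclude_hours} h (need >= {min_cycles})"
        )
    vals = keep["mo2"].to_numpy(dtype=float)
    if method == "quantile":
        return float(np.quantile(vals, q))  # linear interpolation
    if method == "mean_lowest":
        k = max(1, math.ceil(q * len(vals)))
        return float(np.sort(vals)[:k].mean())
    raise ValueError(f"unknown SMR method {method!r}")


def correct_background(
    mmr_raw: float,
    smr_raw: float,
    bg_pre_slope: float,
    bg_post_slope: float,
    chamber_volume: float,
    fish_mass: float,
) -> tuple[float, float, float, float, list[str]]:
    """Subtract empty-chamber respiration from the raw traits.

    The pre-trial background (measured in the 30 min before the fish went
    in) is deducted from MMR; the post-trial background from SMR — the
    microbial load grows over the trial, so the two differ. Returns
    (mmr_corrected, smr_corrected, bg_pre, bg_post, flags) with backgrounds
    in mass-specific units.
    """
    bg_pre = background_mo2(bg_pre_slope, chamber_volume, fish_mass)
    bg_post = background_mo2(bg_post_slope, chamber_volume, fish_mass)
    mmr_c = mmr_raw - bg_pre
    smr_c = smr_raw - bg_post
    flags = []
    if mmr_c < 0 or smr_c < 0:
        flags.append("negative_corrected_trait")
    if mmr_c < smr_c:
        flags.append("mmr_below_smr")
    return mmr_c, smr_c, bg_pre, bg_post, flags


def aerobic_scope(mmr_corrected: float, smr_corrected: float) -> float:
    """AS = corrected MMR minus corrected SMR (may be negative; callers flag)."""
    if not (math.isfinite(mmr_corrected) and math.isfinite(smr_corrected)):
        raise ValueError("corrected traits must be finite")
    return mmr_corrected - smr_corrected


def extract_traits(
    trace: pd.DataFrame,
    fish_mass: float,
    chamber_volume: float,
    *,
    fish_id: str = "fish",
    species: str = "",
    region: str = "",
    acclimation_temp: float = float("nan"),
    bg_pre_slope: float = 0.0,
    bg_post_slope: float = 0.0,
    exclude_hours: float = 5.0,
    q: float = 0.20,
    smr_method: str = "quantile",
    schedule: "object | None" = None,
) -> MetabolicTraits:
    """Full per-fish chain: trace -> MO2 series -> corrected SMR/MMR/AS."""
    series = mo2_series(trace, chamber_volume, fish_mass, schedule=schedule)
    mmr_raw = estimate_mmr(series)
    smr_raw = estimate_smr(series, exclude_hours=exclude_hours, q=q, method=smr_method)
    mmr_c, smr_c, bg_pre, bg_post, flags = correct_background(
        mmr_raw, smr_raw, bg_pre_slope, bg_post_slope, chamber_volume, fish_mass
    )
    as_ = aerobic_scope(mmr_c, smr_c)
    if as_ < 0 and "mmr_below_smr" not in flags:
        flags.append("mmr_below_smr")
    return MetabolicTraits(
        fish_id=fish_id,
        smr_raw=smr_raw,
        mmr_raw=mmr_raw,
        smr_corrected=smr_c,
        mmr_corrected=mmr_c,
        aerobic_scope=as_,
        background_pre=bg_pre,
        background_post=bg_post,
        mass=fish_mass,
        acclimation_temp=acclimation_temp,
        species=species,
        region=region,
        flags=flags,
    )


def traits_table(traits: Sequence[MetabolicTraits]) -> pd.DataFrame:
    """One row per fish, suitable for delimited-text output."""
    return pd.DataFrame(
        [
            {
                "fish_id": t.fish_id,
                "species": t.species,
                "region": t.region,
                "acclimation_temp": t.acclimation_temp,
                "mass_g": t.mass,
                "smr_raw": t.smr_raw,
                "mmr_raw": t.mmr_raw,
                "smr_corrected": t.smr_corrected,
                "mmr_corrected": t.mmr_corrected,
                "aerobic_scope": t.aerobic_scope,
                "background_pre": t.background_pre,
                "background_post": t.background_post,
                "flags": ";".join(t.flags),
            }
            for t in traits
        ]
    )
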
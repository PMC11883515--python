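"""Allometric mass correction of metabolic traits.

Metabolic rates scale with body mass, so raw per-fish traits confound
physiology with size. For each species x trait the log10 trait is regressed
on log10 mass (pooling regions and acclimation temperatures), and every
fish's value is adjusted to the species' mean body mass with the fitted
exponent:

    adjusted = value * (mean_mass / mass) ** b

Critical thermal limits are absolute temperatures and are deliberately
*never* passed through this module; body mass enters those models as a
covariate instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ScalingFit", "fit_mass_scaling", "adjust_to_mean_mass", "adjust_table"]

TRAITS = ("SMR", "MMR", "AS")


@dataclass(frozen=True)
class ScalingFit:
    species: str
    trait: str
    exponent_b: float
    intercept_log10a: float
    r2: float
    mean_mass: float  # g, arithmetic mean of the fish entering the fit
    n: int


def fit_mass_scaling(
    values,
    masses,
    species: str = "",
    trait: str = "",
    *,
    space: str = "log10",
) -> ScalingFit:
    """Fit the mass-scaling exponent for one species x trait.

    Default is OLS of log10(value) on log10(mass); non-positive values are
    excluded with a warning before the log transform. ``space="linear"``
    regresses raw value on raw mass instead (slope then plays the role of
    the exponent only loosely; provided for sensitivity analysis).
    """
    values = np.asarray(values, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if values.shape != masses.shape:
        raise ValueError("values and masses must have the same length")
    ok = np.isfinite(values) & np.isfinite(masses) & (masses > 0)
    if space == "log10":
        pos = ok & (values > 0)
        if pos.sum() < ok.sum():
            logger.warning(
                "%s/%s: excluding %d non-positive value(s) before log transform",
                species, trait, int(ok.sum() - pos.sum()),
            )
        ok = pos
    values, masses = values[ok], masses[ok]
    if len(values) < 3:
        raise ValueError("mass scaling requires at least 3 usable fish")
    if np.unique(masses).size < 2:
        raise ValueError("all masses identical: scaling exponent is unidentifiable")
    if space == "log10":
        x, y = np.log10(masses), np.log10(values)
    elif space == "linear":
        x, y = masses, values
    else:
        raise ValueError(f"unknown regression space {space!r}")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else float("nan")
    return ScalingFit(
        species=species,
        trait=trait,
        exponent_b=float(slope),
        intercept_log10a=float(intercept),
        r2=float(r2),
        mean_mass=float(masses.mean()),
        n=int(len(values)),
    )


def adjust_to_mean_mass(value, mass, fit: ScalingFit):
    """Adjust trait value(s) to the species' mean mass using a fitted exponent.

    adjusted = value * (mean_mass / mass) ** exponent_b; at the pivot
    (mass == mean_mass) the value is unchanged, and order within a fixed
    mass is preserved.
    """
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be positive")
    out = np.asarray(value, dtype=float) * (fit.mean_mass / mass) ** fit.exponent_b
    return float(out) if out.ndim == 0 else out


def adjust_table(
    traits: pd.DataFrame,
    *,
    value_cols: dict[str, str] | None = None,
    mass_col: str = "mass_g",
    species_col: str = "species",
    space: str = "log10",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mass-adjust a per-fish traits table, per species x trait.

    ``value_cols`` maps trait name -> column (default the corrected traits:
    SMR -> smr_corrected, MMR -> mmr_corrected, AS -> aerobic_scope).
    Returns (adjusted table with ``<col>_adj`` columns, scaling-fit audit
    table).
    """
    if value_cols is None:
        value_cols = {
            "SMR": "smr_corrected",
            "MMR": "mmr_corrected",
            "AS": "aerobic_scope",
        }
    out = traits.copy()
    fits = []
    for species, sub in traits.groupby(species_col):
        for trait, col in value_cols.items():
            fit = fit_mass_scaling(
                sub[col], sub[mass_col], species=str(species), trait=trait, space=space
            )
            fits.append(fit)
            out.loc[sub.index, f"{col}_adj"] = adjust_to_mean_mass(
                sub[col].to_numpy(), sub[mass_col].to_numpy(), fit
            )
    fit_table = pd.DataFrame([f.__dict__ for f in fits])
    return out, fit_table
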
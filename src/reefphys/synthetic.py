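"""Synthetic raw data with known ground truth.

Every raw input the pipeline consumes can be generated here from explicit
generative parameters: intermittent-flow respirometry oxygen traces, whole
cohorts of fish (species x region x acclimation temperature), critical
thermal limit ramp trials, and daily sea-surface-temperature series. Because
the generative parameters are known, every downstream estimator (SMR/MMR
extraction, allometric exponents, thermal-performance-curve parameters,
critical limits, environmental extremes) can be validated by parameter
recovery, including exact recovery in the zero-noise limit.

The generative model, in the order the pipeline consumes it:

* A fish's standard metabolic rate follows an exponential thermal
  performance curve, ``SMR(T) = a * exp(b * T)``, and its aerobic scope a
  Gaussian curve, ``AS(T) = amplitude * exp(-(T - topt)^2 / (2 sd^2))``;
  maximum metabolic rate is ``MMR = SMR + AS``. All three scale
  allometrically as ``mass^b_allom`` relative to the reference mass, with
  optional lognormal inter-individual variation.
* An oxygen trace alternates measure and flush phases on a fixed cycle.
  During a measure phase the chamber oxygen declines at the rate implied by
  the fish's instantaneous oxygen uptake (elevated immediately after the
  exhaustive chase and decaying exponentially toward SMR with time constant
  ``epoc_tau``), plus a background (microbial) slope that drifts linearly
  from its pre-trial to its post-trial level, plus Gaussian sensor noise.
  Flush phases reset oxygen to saturation.
* A critical-thermal trial ramps water temperature at a constant rate while
  internal body temperature follows a first-order lag with mass-dependent
  rate coefficient; loss of equilibrium occurs when internal temperature
  crosses the individual's true limit.
* Sea surface temperature is an annual sinusoid plus Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .thermal_limits import CTTrial

__all__ = [
    "CycleSpec",
    "SSTParams",
    "SyntheticConfig",
    "FishRecord",
    "AG_SST",
    "GO_SST",
    "generate_o2_trace",
    "generate_cohort",
    "generate_ct_trial",
    "generate_sst",
    "cohort_tables",
    "write_cohort",
]

#: Default dissolved-oxygen saturation baseline, mg O2 / L. Typical for
#: warm (~31 degC) seawater; traces are generated in concentration units.
O2_SATURATION_DEFAULT = 6.8


@dataclass(frozen=True)
class CycleSpec:
    """Intermittent-flow respirometry cycle, minutes."""

    total: float = 10.0
    measure: float = 6.0
    flush: float = 4.0

    def __post_init__(self) -> None:
        if self.measure + self.flush > self.total + 1e-9:
            raise ValueError("measure + flush must not exceed the cycle length")
        if min(self.total, self.measure, self.flush) < 0:
            raise ValueError("cycle durations must be non-negative")


@dataclass(frozen=True)
class SSTParams:
    """Annual sinusoid for daily sea surface temperature, degC."""

    mean: float = 27.25
    amplitude: float = 9.25
    noise_sd: float = 0.3
    years: int = 9
    #: day-of-year of the annual minimum (mid February by default)
    min_doy: float = 45.0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.noise_sd < 0 or self.amplitude < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")


#: Presets for the two study regions: a strongly seasonal sea (annual range
#: ~18.5 degC) and a moderate one (annual range ~11 degC).
AG_SST = SSTParams(mean=27.25, amplitude=9.25, noise_sd=0.3, years=9)
GO_SST = SSTParams(mean=27.0, amplitude=5.5, noise_sd=0.3, years=9)


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for one species x region cell.

    Trait units are mg O2 kg^-1 h^-1 at the reference body mass
    ``exp(mass_log_mean)`` grams; per-fish truths scale as
    ``(mass / reference_mass) ** allometric_exponent_b`` with optional
    multiplicative lognormal individual variation of coefficient of
    variation ``individual_cv``.
    """

    seed: int = 0
    species_label: str = "blenny"
    region_label: str = "AG"
    acclimation_temps: tuple[float, ...] = (18.0, 22.0, 27.0, 31.5, 35.5)
    n_fish_per_cell: int = 8
    mass_log_mean: float = math.log(1.4)  # log-grams
    mass_log_sd: float = 0.5
    allometric_exponent_b: float | Mapping[str, float] = 0.8
    smr_tpc: tuple[float, float] = (28.0, 0.063)  # a (mg O2/kg/h), b (1/degC)
    as_tpc: tuple[float, float, float] = (420.0, 29.2, 11.8)  # amp, topt, sd
    individual_cv: float = 0.10
    epoc_tau: float = 60.0  # minutes; 0 means "instant recovery after cycle 1"
    background_slope_pre: float = -2.0e-4  # mg O2 / L / min, empty chamber
    background_slope_post: float = -4.0e-4
    o2_noise_sd: float = 0.005  # mg / L per sample
    o2_saturation: float = O2_SATURATION_DEFAULT
    cycle: CycleSpec = field(default_factory=CycleSpec)
    duration_h: float = 18.0
    sample_dt_s: float = 10.0
    chamber_volume_l: float = 0.175
    ct_max_limit: float = 39.5
    ct_min_limit: float = 8.7
    ct_limit_sd: float = 0.3
    lag_k0: float = 1.2  # 1/min at 1 g
    lag_gamma: float = 0.33  # mass exponent of the lag coefficient
    ramp_rate: float = 0.1  # degC / min
    sst: SSTParams = field(default_factory=SSTParams)

    def __post_init__(self) -> None:
        if self.n_fish_per_cell < 1:
            raise ValueError("n_fish_per_cell must be >= 1")
        for name in ("mass_log_sd", "individual_cv", "o2_noise_sd",
                     "ct_limit_sd", "epoc_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        amp, _topt, sd = self.as_tpc
        if amp <= 0 or sd <= 0:
            raise ValueError("Gaussian aerobic-scope amplitude and breadth must be > 0")
        if self.smr_tpc[0] <= 0:
            raise ValueError("SMR curve coefficient a must be > 0")
        # MMR_true = SMR_true + AS_true > SMR_true needs AS_true > 0,
        # guaranteed by amp > 0; verify anyway on the configured grid.
        for temp in self.acclimation_temps:
            if self.as_true(temp) <= 0:
                raise ValueError(f"aerobic scope ground truth <= 0 at {temp} degC")

    # -- ground-truth curves (reference mass, no individual variation) -----

    @property
    def reference_mass(self) -> float:
        return math.exp(self.mass_log_mean)

    def exponent_for(self, trait: str) -> float:
        b = self.allometric_exponent_b
        if isinstance(b, Mapping):
            return float(b[trait])
        return float(b)

    def smr_true(self, temp: float, mass: float | None = None) -> float:
        a, b = self.smr_tpc
        v = a * math.exp(b * temp)
        if mass is not None:
            v *= (mass / self.reference_mass) ** self.exponent_for("SMR")
        return v

    def as_true(self, temp: float, mass: float | None = None) -> float:
        amp, topt, sd = self.as_tpc
        v = amp * math.exp(-((temp - topt) ** 2) / (2.0 * sd * sd))
        if mass is not None:
            v *= (mass / self.reference_mass) ** self.exponent_for("AS")
        return v

    def mmr_true(self, temp: float, mass: float | None = None) -> float:
        return self.smr_true(temp, mass) + self.as_true(temp, mass)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, Mapping):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return plain(dataclasses.asdict(self))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# oxygen traces


def _cv_to_sigma(cv: float) -> float:
    """Log-sd of a mean-one lognormal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


def generate_o2_trace(
    config: SyntheticConfig,
    fish_mass: float,
    temp: float,
    seed: int,
    *,
    smr_true: float | None = None,
    mmr_true: float | None = None,
    chamber_id: str = "ch1",
) -> pd.DataFrame:
    """Simulate one overnight intermittent-flow respirometry trace.

    The fish enters the chamber immediately after the exhaustive chase, so
    the first measure phase starts at elevated (~MMR) uptake which decays
    exponentially toward SMR with time constant ``config.epoc_tau``. With
    ``epoc_tau == 0`` the first measure phase runs at exactly MMR and every
    later phase at exactly SMR (the idealised noiseless limit).

    Returns a data frame with columns ``time_min, o2_mg_per_l, temp_c,
    phase, chamber_id``; the generative truths are stored in ``df.attrs``
    for recovery tests.
    """
    if fish_mass <= 0:
        raise ValueError("fish mass must be positive")
    smr = config.smr_true(temp, fish_mass) if smr_true is None else float(smr_true)
    mmr = config.mmr_true(temp, fish_mass) if mmr_true is None else float(mmr_true)
    cyc = config.cycle
    dt = config.sample_dt_s / 60.0
    if cyc.measure / dt < 2:
        raise ValueError("measure window shorter than 2 samples")
    total_min = config.duration_h * 60.0
    n = int(round(total_min / dt))
    t = np.arange(n) * dt
    cycle_idx = np.floor(t / cyc.total).astype(int)
    t_in = t - cycle_idx * cyc.total
    measuring = t_in < cyc.measure

    mass_kg = fish_mass / 1000.0
    v_eff = config.chamber_volume_l - fish_mass / 1000.0  # fish displaces water
    if v_eff <= 0:
        raise ValueError("fish volume exceeds chamber volume")

    # cumulative fish O2 consumption (mg O2 per kg) since trial start
    tau = config.epoc_tau
    if tau > 0:
        m_int = smr * t + (mmr - smr) * tau * (1.0 - np.exp(-t / tau))
        m_int_start = smr * (cycle_idx * cyc.total) + (mmr - smr) * tau * (
            1.0 - np.exp(-(cycle_idx * cyc.total) / tau)
        )
    else:
        # degenerate limit: cycle 0 at MMR, later cycles at SMR
        rate = np.where(cycle_idx == 0, mmr, smr)
        m_int = rate * t_in  # within-phase only; start integral is zero
        m_int_start = np.zeros_like(t)

    # background drift: linear from pre- to post-trial slope (mg/L/min)
    pre, post = config.background_slope_pre, config.background_slope_post
    span = t[-1] if t[-1] > 0 else 1.0
    b_int = pre * t + 0.5 * (post - pre) * t * t / span
    t_start = cycle_idx * cyc.total
    b_int_start = pre * t_start + 0.5 * (post - pre) * t_start * t_start / span

    o2 = np.full(n, config.o2_saturation)
    fish_drop = (m_int - m_int_start) * mass_kg / (v_eff * 60.0)
    o2_measure = config.o2_saturation - fish_drop + (b_int - b_int_start)
    o2 = np.where(measuring, o2_measure, o2)

    rng = np.random.default_rng(seed)
    if config.o2_noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.o2_noise_sd, size=n)
    o2 = np.maximum(o2, 0.0)

    df = pd.DataFrame(
        {
            "time_min": t,
            "o2_mg_per_l": o2,
            "temp_c": np.full(n, float(temp)),
            "phase": np.where(measuring, "measure", "flush"),
            "chamber_id": chamber_id,
        }
    )
    df.attrs.update(
        smr_true=smr,
        mmr_true=mmr,
        as_true=mmr - smr,
        mass_g=float(fish_mass),
        temp_c=float(temp),
        chamber_volume_l=config.chamber_volume_l,
        background_slope_pre=pre,
        background_slope_post=post,
        seed=int(seed),
    )
    return df


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class FishRecord:
    """One synthetic fish: metadata, ground truth and its oxygen trace."""

    fish_id: str
    species: str
    region: str
    acclimation_temp: float
    mass: float
    chamber_volume: float
    smr_true: float
    mmr_true: float
    as_true: float
    background_slope_pre: float
    background_slope_post: float
    trace: pd.DataFrame


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> list[FishRecord]:
    """Generate a full cohort for one species x region cell.

    Masses are lognormal; each fish's trait truths scale as
    ``mass ** allometric_exponent_b`` around the configured thermal
    performance curves, with multiplicative lognormal individual variation
    (``individual_cv``). An oxygen trace is simulated per fish.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    trace_seeds = ss.spawn(1)[0].generate_state(
        len(config.acclimation_temps) * config.n_fish_per_cell
    ) % (2**31)
    sigma = _cv_to_sigma(config.individual_cv)
    cohort: list[FishRecord] = []
    i = 0
    for temp in config.acclimation_temps:
        for j in range(config.n_fish_per_cell):
            mass = float(rng.lognormal(config.mass_log_mean, config.mass_log_sd))
            if sigma > 0:
                eps_smr = float(rng.lognormal(-0.5 * sigma * sigma, sigma))
                eps_as = float(rng.lognormal(-0.5 * sigma * sigma, sigma))
            else:
                eps_smr = eps_as = 1.0
            smr = config.smr_true(temp, mass) * eps_smr
            as_ = config.as_true(temp, mass) * eps_as
            mmr = smr + as_
            trace = generate_o2_trace(
                config, mass, temp, int(trace_seeds[i]), smr_true=smr, mmr_true=mmr
            )
            fish_id = f"{config.species_label}-{config.region_label}-T{temp:g}-{j:02d}"
            cohort.append(
                FishRecord(
                    fish_id=fish_id,
                    species=config.species_label,
                    region=config.region_label,
                    acclimation_temp=float(temp),
                    mass=mass,
                    chamber_volume=config.chamber_volume_l,
                    smr_true=smr,
                    mmr_true=mmr,
                    as_true=as_,
                    background_slope_pre=config.background_slope_pre,
                    background_slope_post=config.background_slope_post,
                    trace=trace,
                )
            )
            i += 1
    return cohort


def cohort_tables(cohort: Sequence[FishRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(metadata, ground-truth) tables for a cohort, one row per fish."""
    meta = pd.DataFrame(
        {
            "fish_id": [f.fish_id for f in cohort],
            "species": [f.species for f in cohort],
            "region": [f.region for f in cohort],
            "acclimation_temp": [f.acclimation_temp for f in cohort],
            "mass_g": [f.mass for f in cohort],
            "chamber_volume_l": [f.chamber_volume for f in cohort],
            "background_slope_pre": [f.background_slope_pre for f in cohort],
            "background_slope_post": [f.background_slope_post for f in cohort],
        }
    )
    truth = pd.DataFrame(
        {
            "fish_id": [f.fish_id for f in cohort],
            "smr_true": [f.smr_true for f in cohort],
            "mmr_true": [f.mmr_true for f in cohort],
            "as_true": [f.as_true for f in cohort],
        }
    )
    return meta, truth


def write_cohort(cohort: Sequence[FishRecord], outdir: str | Path,
                 config: SyntheticConfig | None = None) -> Path:
    """Write a cohort as delimited text: one trace CSV per fish plus
    ``metadata.csv`` and ``truth.csv`` (and ``config.yaml`` if given)."""
    outdir = Path(outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    meta, truth = cohort_tables(cohort)
    meta.to_csv(outdir / "metadata.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)
    for f in cohort:
        f.trace.to_csv(outdir / "traces" / f"{f.fish_id}.csv", index=False)
    if config is not None:
        config.to_yaml(outdir / "config.yaml")
    return outdir


# ---------------------------------------------------------------------------
# critical-thermal trials


def generate_ct_trial(
    config: SyntheticConfig,
    fish_mass: float,
    direction: str,
    seed: int,
    *,
    start_temp: float | None = None,
    fish_id: str = "fish",
    species: str | None = None,
    region: str | None = None,
) -> CTTrial:
    """Simulate one critical-thermal ramp trial.

    Water temperature ramps linearly at ``config.ramp_rate`` from the start
    (acclimation) temperature. Internal body temperature follows the
    first-order lag dTb/dt = k (Tw - Tb) with k = lag_k0 * mass^(-lag_gamma);
    loss of equilibrium fires when internal temperature crosses the
    individual's true limit (configured limit plus N(0, ct_limit_sd)).
    The recorded endpoint is the *water* temperature at that moment; the
    true internal limit is kept on the trial for recovery tests.
    """
    if fish_mass <= 0:
        raise ValueError("fish mass must be positive")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    rng = np.random.default_rng(seed)
    heating = direction == "max"
    if start_temp is None:
        start_temp = (max if heating else min)(config.acclimation_temps)
    base = config.ct_max_limit if heating else config.ct_min_limit
    limit = base + float(rng.normal(0.0, config.ct_limit_sd))
    r = config.ramp_rate
    k = config.lag_k0 * fish_mass ** (-config.lag_gamma)
    sgn = 1.0 if heating else -1.0
    if sgn * (limit - start_temp) <= 0:
        raise ValueError(
            f"CT{direction} ramp from {start_temp} degC cannot reach the "
            f"true limit {limit:.2f} degC"
        )

    def body_minus_limit(t: float) -> float:
        tb = start_temp + sgn * (r * t - (r / k) * (1.0 - math.exp(-k * t)))
        return sgn * (tb - limit)

    # bracket: body temperature reaches the limit within the water-ramp time
    # to the limit plus a few lag time constants
    from scipy.optimize import brentq

    t_hi = abs(limit - start_temp) / r + 10.0 / k + 10.0
    t_loe = brentq(body_minus_limit, 0.0, t_hi, xtol=1e-10)
    water_at_loe = start_temp + sgn * r * t_loe
    return CTTrial(
        fish_id=fish_id,
        species=species or config.species_label,
        region=region or config.region_label,
        acclimation_temp=float(start_temp),
        direction=direction,
        ramp_rate=r,
        water_temp_at_loe=float(water_at_loe),
        mass=float(fish_mass),
        true_internal_limit=float(limit),
    )


# ---------------------------------------------------------------------------
# sea surface temperature


def generate_sst(
    config: SyntheticConfig | SSTParams,
    seed: int,
    *,
    site: str = "site",
    start: str = "2010-01-01",
) -> pd.DataFrame:
    """Daily SST series: annual sinusoid plus Gaussian noise.

    Returns a data frame with columns ``date, sst_c, site``. The sinusoid
    has its minimum at ``min_doy`` (mid February by default) so annual
    maxima fall in late summer.
    """
    params = config.sst if isinstance(config, SyntheticConfig) else config
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=round(params.years * 365.25), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    sst = params.mean - params.amplitude * np.cos(
        2.0 * np.pi * (doy - params.min_doy) / 365.25
    )
    if params.noise_sd > 0:
        sst = sst + rng.normal(0.0, params.noise_sd, size=len(dates))
    return pd.DataFrame({"date": dates, "sst_c": sst, "site": site})
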
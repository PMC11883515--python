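"""End-to-end orchestration.

One entry point, :func:`run_pipeline`, chains every stage on synthetic (or
user-supplied) inputs: cohort generation -> trait extraction -> allometric
adjustment -> thermal-performance-curve fits and Q10 -> critical thermal
limits with internal-temperature correction -> environmental extremes and
thermal safety margins -> regional comparison statistics. Each run
serialises its configuration and a manifest (seed, config hash, output
hashes) into the output directory so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry, respirometry, stats, thermal_limits, tpc
from .synthetic import SyntheticConfig, SSTParams, AG_SST, GO_SST, generate_cohort, \
    generate_ct_trial, generate_sst

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "TSMSummary", "run_pipeline", "summarize_tsm"]

#: seasonal acclimation temperatures per region (degC): the temperature a
#: fish must be acclimatised to for its CT trial to enter the seasonal TSM
SEASONAL_TEMPS = {
    "AG": {"summer": 35.5, "winter": 18.0},
    "GO": {"summer": 31.5, "winter": 22.0},
}


def _default_ag() -> SyntheticConfig:
    return SyntheticConfig(region_label="AG", sst=AG_SST)


def _default_go() -> SyntheticConfig:
    return SyntheticConfig(
        region_label="GO",
        acclimation_temps=(18.0, 22.0, 27.0, 31.5),
        sst=GO_SST,
        ct_max_limit=39.1,
    )


@dataclass
class RunConfig:
    """Everything a pipeline run reads; serialised into the output directory."""

    ag: SyntheticConfig = field(default_factory=_default_ag)
    go: SyntheticConfig = field(default_factory=_default_go)
    seasonal_temps: dict = field(default_factory=lambda: {
        r: dict(v) for r, v in SEASONAL_TEMPS.items()
    })
    smr_q: float = 0.20
    exclude_hours: float = 5.0
    smr_method: str = "quantile"
    n_ct_per_cell: int = 8
    n_perm: int = 999
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ag"] = self.ag.to_dict()
        d["go"] = self.go.to_dict()
        return d

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class TSMSummary:
    """Regional / seasonal thermal-safety-margin summary."""

    cells: pd.DataFrame  # species x region x season: mean, se, n
    gaps: pd.DataFrame  # per species x season: GO mean - AG mean
    mean_gap: dict  # season -> unweighted mean of per-species gaps
    grand_mean_ag: dict  # season -> unweighted mean of per-species AG means


@dataclass
class RunResult:
    traits: pd.DataFrame
    scaling_fits: pd.DataFrame
    tpc_fits: pd.DataFrame
    q10_table: pd.DataFrame
    ct_trials: pd.DataFrame
    env_extremes: pd.DataFrame
    tsm_records: pd.DataFrame
    tsm_summary: TSMSummary
    comparisons: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# TSM summarisation


def summarize_tsm(records: pd.DataFrame) -> TSMSummary:
    """Summarise per-fish TSM records by species x region x season.

    Cross-species averages are *unweighted* means of per-species means (so
    a well-sampled species does not dominate the regional comparison): the
    per-season regional gap is the mean over species of (GO mean - AG mean),
    and the seasonal grand mean is the mean over species of the AG means.
    """
    if records.empty:
        raise ValueError("no TSM records to summarise")
    cells = (
        records.groupby(["species", "region", "season"])["margin"]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size")
        .reset_index()
    )
    wide = cells.pivot_table(index=["species", "season"], columns="region",
                             values="mean")
    gaps = wide.reset_index()
    mean_gap: dict = {}
    grand_mean_ag: dict = {}
    if {"AG", "GO"}.issubset(wide.columns):
        gaps["gap"] = gaps["GO"] - gaps["AG"]
        for season, sub in gaps.groupby("season"):
            mean_gap[season] = float(sub["gap"].mean())
    if "AG" in wide.columns:
        for season, sub in gaps.groupby("season"):
            grand_mean_ag[season] = float(sub["AG"].mean())
    return TSMSummary(cells=cells, gaps=gaps, mean_gap=mean_gap,
                      grand_mean_ag=grand_mean_ag)


# ---------------------------------------------------------------------------
# pipeline stages


def _extract_all_traits(cohort, config: RunConfig) -> pd.DataFrame:
    traits = []
    for fish in cohort:
        traits.append(
            respirometry.extract_traits(
                fish.trace,
                fish.mass,
                fish.chamber_volume,
                fish_id=fish.fish_id,
                species=fish.species,
                region=fish.region,
                acclimation_temp=fish.acclimation_temp,
                bg_pre_slope=fish.background_slope_pre,
                bg_post_slope=fish.background_slope_post,
                exclude_hours=config.exclude_hours,
                q=config.smr_q,
                smr_method=config.smr_method,
            )
        )
    return respirometry.traits_table(traits)


def _fit_tpcs(adjusted: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (species, region), sub in adjusted.groupby(["species", "region"]):
        for trait, col, fitter in (
            ("SMR", "smr_corrected_adj", tpc.fit_exponential),
            ("MMR", "mmr_corrected_adj", tpc.fit_poly2),
            ("AS", "aerobic_scope_adj", tpc.fit_gaussian),
        ):
            vals = sub[col]
            temps = sub["acclimation_temp"]
            if trait == "SMR":
                keep = vals > 0
                temps, vals = temps[keep], vals[keep]
            try:
                fit = fitter(temps, vals, trait=trait)
            except ValueError as exc:
                logger.warning("TPC fit skipped (%s %s %s): %s",
                               species, region, trait, exc)
                continue
            rows.append(
                {
                    "species": species, "region": region, "trait": trait,
                    "model": fit.model, "r2": fit.r2, "n": fit.n,
                    "converged": fit.converged, "flags": ";".join(fit.flags),
                    **{f"param_{k}": v for k, v in fit.params.items()},
                }
            )
    return pd.DataFrame(rows)


def _q10_table(adjusted: pd.DataFrame, t_low: float = 22.0,
               t_high: float = 31.5) -> pd.DataFrame:
    """Q10 from group-mean traits at the two commonly shared temperatures."""
    rows = []
    for (species, region), sub in adjusted.groupby(["species", "region"]):
        for trait, col in (("SMR", "smr_corrected_adj"),
                           ("MMR", "mmr_corrected_adj"),
                           ("AS", "aerobic_scope_adj")):
            lo = sub.loc[sub["acclimation_temp"] == t_low, col]
            hi = sub.loc[sub["acclimation_temp"] == t_high, col]
            if lo.empty or hi.empty or lo.mean() <= 0 or hi.mean() <= 0:
                continue
            rows.append(
                {
                    "species": species, "region": region, "trait": trait,
                    "t_low": t_low, "t_high": t_high,
                    "q10": tpc.q10(lo.mean(), hi.mean(), t_low, t_high),
                }
            )
    return pd.DataFrame(rows)


def _ct_and_tsm(config: RunConfig, rng: np.random.Generator):
    """CT trials at each region's seasonal temperatures, internal-temperature
    correction, environmental extremes, and per-fish TSM records."""
    ct_rows, tsm_rows, env_rows = [], [], []
    for region, syn in (("AG", config.ag), ("GO", config.go)):
        sst = generate_sst(syn, int(rng.integers(2**31)), site=region)
        env_max, env_min = thermal_limits.env_extremes(sst)
        env_rows.append({"region": region, "mean_annual_max": env_max,
                         "mean_annual_min": env_min})
        for season, direction in (("summer", "max"), ("winter", "min")):
            start = config.seasonal_temps[region][season]
            extreme = env_max if season == "summer" else env_min
            for j in range(config.n_ct_per_cell):
                mass = float(rng.lognormal(syn.mass_log_mean, syn.mass_log_sd))
                trial = generate_ct_trial(
                    syn, mass, direction, int(rng.integers(2**31)),
                    start_temp=start,
                    fish_id=f"{syn.species_label}-{region}-{season}-{j:02d}",
                    region=region,
                )
                trial.internal_temp_at_loe = thermal_limits.internal_temp_at_loe(
                    trial.water_temp_at_loe, start, trial.ramp_rate, mass,
                    syn.lag_k0, syn.lag_gamma,
                )
                margin = thermal_limits.thermal_safety_margin(
                    trial.internal_temp_at_loe, extreme, season
                )
                ct_rows.append({
                    "fish_id": trial.fish_id, "species": trial.species,
                    "region": region, "season": season,
                    "acclimation_temp": start, "direction": direction,
                    "ramp_rate": trial.ramp_rate, "mass_g": mass,
                    "water_temp_at_loe": trial.water_temp_at_loe,
                    "internal_temp_at_loe": trial.internal_temp_at_loe,
                })
                tsm_rows.append({
                    "fish_id": trial.fish_id, "species": trial.species,
                    "region": region, "season": season,
                    "critical_limit": trial.internal_temp_at_loe,
                    "environmental_extreme": extreme, "margin": margin,
                    "flagged": margin < 0,
                })
    return (pd.DataFrame(ct_rows), pd.DataFrame(env_rows), pd.DataFrame(tsm_rows))


def _comparisons(adjusted: pd.DataFrame, config: RunConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Regional comparison per trait, restricted to temperatures sampled in
    both regions (unshared acclimation cells are flagged and skipped)."""
    rows = []
    shared = sorted(
        set(adjusted.loc[adjusted["region"] == "AG", "acclimation_temp"])
        & set(adjusted.loc[adjusted["region"] == "GO", "acclimation_temp"])
    )
    skipped = sorted(set(adjusted["acclimation_temp"]) - set(shared))
    if skipped:
        logger.warning("temperatures %s present in one region only: excluded "
                       "from regional comparisons", skipped)
    sub = adjusted[adjusted["acclimation_temp"].isin(shared)]
    for trait, col in (("SMR", "smr_corrected_adj"),
                       ("MMR", "mmr_corrected_adj"),
                       ("AS", "aerobic_scope_adj")):
        res = stats.auto_compare(
            sub.rename(columns={col: "value"}), "value",
            n_perm=config.n_perm, seed=int(rng.integers(2**31)),
        )
        if res.method in ("lm", "lm_transformed"):
            tab = res.anova_table
            for term in tab.index:
                if term == "Residual":
                    continue
                rows.append({
                    "trait": trait, "method": res.method, "term": term,
                    "statistic": float(tab.loc[term, "F"]),
                    "p": float(tab.loc[term, "PR(>F)"]),
                    "notes": json.dumps(res.notes),
                    "shared_temps": json.dumps(shared),
                })
        else:
            for r in res.permanova_results:
                rows.append({
                    "trait": trait, "method": "permanova", "term": r.test_name,
                    "statistic": r.statistic, "p": r.p_raw,
                    "notes": json.dumps(res.notes),
                    "shared_temps": json.dumps(shared),
                })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage; optionally write all tables plus a manifest."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(4) % (2**31)
    cohort = generate_cohort(config.ag, int(seeds[0])) + generate_cohort(
        config.go, int(seeds[1])
    )
    traits = _extract_all_traits(cohort, config)
    if traits.empty:
        raise ValueError("no traits extracted: empty cohort")
    adjusted, scaling = allometry.adjust_table(traits)
    tpc_fits = _fit_tpcs(adjusted)
    q10_tab = _q10_table(adjusted)
    rng_ct = np.random.default_rng(int(seeds[2]))
    ct_trials, env_tab, tsm_records = _ct_and_tsm(config, rng_ct)
    tsm_summary = summarize_tsm(tsm_records)
    rng_cmp = np.random.default_rng(int(seeds[3]))
    comparisons = _comparisons(adjusted, config, rng_cmp)

    tables = {
        "traits.csv": adjusted,
        "scaling_fits.csv": scaling,
        "tpc_fits.csv": tpc_fits,
        "q10.csv": q10_tab,
        "ct_trials.csv": ct_trials,
        "env_extremes.csv": env_tab,
        "tsm_records.csv": tsm_records,
        "tsm_cells.csv": tsm_summary.cells,
        "comparisons.csv": comparisons,
    }
    digest = hashlib.sha256()
    for name in sorted(tables):
        digest.update(name.encode())
        digest.update(tables[name].to_csv(index=False).encode())
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "output_hash": digest.hexdigest(),
        "n_fish": int(len(traits)),
        "tables": sorted(tables),
    }
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(out / name, index=False)
        (out / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(
        traits=adjusted, scaling_fits=scaling, tpc_fits=tpc_fits,
        q10_table=q10_tab, ct_trials=ct_trials, env_extremes=env_tab,
        tsm_records=tsm_records, tsm_summary=tsm_summary,
        comparisons=comparisons, manifest=manifest,
    )
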
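# reefphys

Thermal physiology of reef fishes, end to end: from raw intermittent-flow
respirometry oxygen traces to standard and maximum metabolic rates (SMR,
MMR) and aerobic scope (AS), allometric mass correction, thermal
performance curves with Q10 sensitivities, critical thermal limits
(CTmax / CTmin) corrected for the internal-temperature lag, thermal safety
margins (TSMs) against sea-surface-temperature extremes, and the regional
comparison statistics — plus a synthetic-data generator with known ground
truth so every estimator in the chain is testable by parameter recovery.

It is written for comparative ecophysiologists who phenotype ectotherm
thermal performance: anyone who runs overnight respirometry trials,
CT ramping assays, and then asks whether populations from thermally
different seas differ in their physiology.

## The models at the core

**Respirometry.** Within each sealed "measure" phase the chamber O2
declines linearly; the mass-specific uptake is

    MO2 = (−slope) · (V_chamber − V_fish) · 60 / m_kg   [mg O2 kg⁻¹ h⁻¹]

MMR is the MO2 of the *first* post-chase measurement cycle; SMR is the
0.20 quantile of MO2 over the rest of the overnight trial, excluding the
first 5 h of post-exercise elevation. Empty-chamber (background) slopes are
converted to the same units and subtracted — the pre-trial background from
MMR, the post-trial background from SMR. AS = MMR − SMR.

**Allometry.** Per species × trait, log10(value) is regressed on
log10(mass); every fish is adjusted to the species mean mass with
`value · (m̄/m)^b`. Critical thermal limits are never mass-scaled; mass
enters their models as a covariate.

**Thermal performance curves.** SMR: `a·e^{bT}` (exponential); MMR:
second-order polynomial; AS: Gaussian
`A·exp(−(T−T_opt)²/(2σ²))`, whose centre is the thermal optimum and whose
σ is the performance breadth. Q10 = (R₂/R₁)^{10/(T₂−T₁)}.

**Critical limits and safety margins.** During a 0.1 °C min⁻¹ ramp, body
temperature follows dT_b/dt = k(T_w − T_b) with k = k₀·m^(−γ); the closed
form T_b = T_w ∓ (r/k)(1 − e^{−kt}) converts the water temperature at loss
of equilibrium into the internal critical limit. Summer
TSM = CTmax − mean annual SST maximum; winter TSM = mean annual SST
minimum − CTmin.

**Statistics.** Factorial linear models (temperature × region, Type-II SS),
Shapiro–Wilk gating with a Tukey ladder-of-powers fallback, and — when
residuals stay non-normal — a permutation MANOVA (pseudo-F on Euclidean
distances, McArdle–Anderson partition) with seeded permutations; pairwise
contrasts with Benjamini–Hochberg FDR adjustment; pooled-t and
Mann–Whitney two-sample tests.

## Worked example

```python
import dataclasses
from reefphys.pipeline import RunConfig, run_pipeline, _default_ag, _default_go

ag = dataclasses.replace(_default_ag(), n_fish_per_cell=4, duration_h=12.0)
go = dataclasses.replace(_default_go(), n_fish_per_cell=4, duration_h=12.0)
result = run_pipeline(RunConfig(ag=ag, go=go, seed=7, n_perm=199, n_ct_per_cell=6))

print(result.tsm_summary.cells.round(2).to_string(index=False))
print("summer gap:", round(result.tsm_summary.mean_gap["summer"], 2))
```

prints

```
species region season  mean   se  n
 blenny     AG summer  2.45 0.10  6
 blenny     AG winter  8.78 0.13  6
 blenny     GO summer  5.96 0.18  6
 blenny     GO winter 12.09 0.10  6
summer gap: 3.51
```

Fish simulated in the strongly seasonal region (annual SST range
~18.5 °C, "AG") sit only ~2.5 °C below their summer extreme, while the
moderate-region ("GO") fish keep ~6 °C in hand: the summer safety-margin
gap of 3.51 °C is the regional contrast the pipeline is built to measure.
The same run yields Q10 tables (e.g. SMR Q10 ≈ 2.1 over 22–31.5 °C,
matching the generative rate constant b = 0.063 since e^{10b} ≈ 1.9) and
Gaussian aerobic-scope fits (seed 7 recovers T_opt 29.3 °C / breadth
14.9 °C in AG against a generative 29.2 / 11.8 from n = 4 fish per
temperature).

The same stages are exposed as a CLI:

```sh
reefphys simulate --seed 1 --out sim/
reefphys extract-traits --traces sim/traces --meta sim/metadata.csv --out traits.csv
reefphys mass-adjust --traits traits.csv --out adjusted.csv
reefphys fit-tpc --traits adjusted.csv --model gaussian --out gaussians.csv
reefphys run-all --seed 1 --out run/
```

## Layout

- `src/reefphys/synthetic.py` — ground-truth generators (traces, cohorts, CT ramps, SST)
- `src/reefphys/respirometry.py` — trace → MO2 → SMR/MMR/AS
- `src/reefphys/allometry.py` — mass-scaling fits and adjustment
- `src/reefphys/tpc.py` — curve fits and Q10
- `src/reefphys/thermal_limits.py` — lag model, SST extremes, TSMs
- `src/reefphys/stats.py` — comparison layer incl. the permutation MANOVA
- `src/reefphys/pipeline.py` — orchestration, manifests
- `docs/methods.md` — modelling assumptions, defaults, numerical choices
- `docs/data_dictionary.md` — every table column the package reads/writes
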
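# Data dictionary

All tables are comma-delimited text with a header row. Units are fixed at
ingest: oxygen in mg O2 L⁻¹, rates in mg O2 kg⁻¹ h⁻¹, mass in grams,
volume in litres, temperature in °C, time in minutes unless stated.

## Oxygen trace (`traces/<fish_id>.csv`)

| column | type | description |
|---|---|---|
| `time_min` | float | minutes from trial start (fish enters post-chase at 0), strictly increasing |
| `o2_mg_per_l` | float | dissolved oxygen concentration |
| `temp_c` | float | water temperature |
| `phase` | text | `measure` (sealed) / `flush` (re-equilibrating); labels take precedence over any schedule |
| `chamber_id` | text | chamber identifier |

## Trial metadata (`metadata.csv`)

| column | type | description |
|---|---|---|
| `fish_id` | text | unique fish identifier; also the trace file stem |
| `species`, `region` | text | grouping labels |
| `acclimation_temp` | float | °C |
| `mass_g` | float | body mass |
| `chamber_volume_l` | float | chamber volume |
| `background_slope_pre`, `background_slope_post` | float | empty-chamber O2 slopes (mg L⁻¹ min⁻¹, negative = consumption) measured before/after the trial |

## Ground truth (`truth.csv`, synthetic cohorts only)

`fish_id`, `smr_true`, `mmr_true`, `as_true` — the generative per-fish
trait values, for parameter-recovery tests.

## Traits table (`traits.csv`, one row per fish)

`fish_id`, `species`, `region`, `acclimation_temp`, `mass_g`,
`smr_raw`, `mmr_raw`, `smr_corrected`, `mmr_corrected`, `aerobic_scope`,
`background_pre`, `background_post` (mass-specific equivalents
subtracted), `flags` (`;`-separated: `negative_corrected_trait`,
`mmr_below_smr`). Mass adjustment appends `smr_corrected_adj`,
`mmr_corrected_adj`, `aerobic_scope_adj`.

## Scaling fits (`scaling_fits.csv`)

`species`, `trait` (SMR/MMR/AS), `exponent_b`, `intercept_log10a`, `r2`,
`mean_mass` (g, pivot of the adjustment), `n`.

## TPC fits (`tpc_fits.csv`)

`species`, `region`, `trait`, `model`
(`exponential`/`poly2`/`gaussian`), `r2`, `n`, `converged`, `flags`, and
`param_*` columns per model: `a`, `b` (exponential); `c0`, `c1`, `c2`,
`vertex_temp`, `vertex_value` (poly2); `amplitude`, `topt`, `breadth_sd`
(gaussian).

## Q10 table (`q10.csv`)

`species`, `region`, `trait`, `t_low`, `t_high`, `q10` — computed from
group-mean adjusted traits at the two temperatures.

## CT trials (`ct_trials.csv`)

`fish_id`, `species`, `region`, `season`, `acclimation_temp` (ramp start),
`direction` (`max`/`min`), `ramp_rate` (°C min⁻¹), `mass_g`,
`water_temp_at_loe`, `internal_temp_at_loe` (lag-corrected critical
limit). The CLI `ct-limits` subcommand also records `lag_k0`, `lag_gamma`.

## SST series

`date` (ISO daily), `sst_c`, `site`.

## TSM records (`tsm_records.csv`)

`fish_id`, `species`, `region`, `season` (`summer`/`winter`),
`critical_limit` (internal °C), `environmental_extreme` (mean annual
max/min °C), `margin` (°C, signed), `flagged` (true when negative).

## Comparisons (`comparisons.csv`)

`trait`, `method` (`lm`/`lm_transformed`/`permanova`), `term`,
`statistic` (F or pseudo-F), `p`, `notes` (JSON: transformation, reasons),
`shared_temps` (JSON list of temperatures present in both regions).
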
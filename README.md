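# enviromort

Short-term effects of extreme heat, cold and air-pollution episodes on
weekly excess mortality from natural causes, implemented as a tested,
reusable pipeline:

1. **Exposure construction** (`enviromort.exposure`) — inverse
   distance-weighted downscaling of station/model fields to a fine grid,
   monthly empirical quantile mapping (EQM) bias correction, and
   population-weighted aggregation (cell → region → national).
2. **Episode detection** (`enviromort.episodes`) — daily exceedances of
   absolute health-risk thresholds (heat: tmax ≥ 35 °C with previous-day
   tmean ≥ 23 °C; cold: tmin ≤ −15 °C; PM2.5 ≥ 25, NO2 ≥ 50 (24-h mean),
   O3 ≥ 160 µg/m³ (1-h max)), aggregated to two-week cumulative weekly
   covariates.
3. **Baseline and p-scores** (`enviromort.baseline`) — weekly
   age-standardized mortality rates (ESP 2013), a penalized median
   (quantile-0.5) regression baseline with long-term trend and cyclic
   seasonal splines, and relative-excess p-scores
   `Y_t = 100 (ASMR_t − B_t)/B_t`.
4. **Distributional regression** (`enviromort.distreg`) — maximum-likelihood
   logistic location–scale regression of weekly p-scores (both μ and
   log σ linear in covariates), stepwise covariate selection on the
   Hannan–Quinn criterion, normalized quantile residual diagnostics, and a
   week-resampling bootstrap.
5. **Attributable mortality** (`enviromort.attribution`) — weekly/yearly
   attributable deaths `Σ n_t μ_j X_{t,j}/100` and attributable ASMR
   `Σ B_t μ_j X_{t,j}/100`, with period summaries.
6. **Extreme-event indicators** (`enviromort.extremes`) — empirical
   90th-percentile threshold, conditional exceedance probabilities,
   closed-form per-unit odds ratios `exp(μ_j / exp(σ_0))`, a binomial
   logistic comparison model, the Ferro–Segers intervals estimator of the
   extremal index, return levels/periods from the covariate-averaged weekly
   distribution, and an exponential tail comparison.
7. **Synthetic data** (`enviromort.synthetic`) — a generator producing daily
   exposures, station/grid fixtures and weekly mortality with *known*
   ground-truth coefficients, so that every stage is testable offline
   (parameter recovery, selection consistency, calibration).

## Command-line usage

```bash
# generate a synthetic scenario
enviromort simulate --years 26 --seed 1 --out synthetic/

# individual stages
enviromort episodes synthetic/exposures.csv --out work/
enviromort baseline synthetic/weekly_mortality.csv work/weekly_covariates.csv --out work/
enviromort fit work/weekly.csv --out work/

# full pipeline from a YAML config
enviromort run-all config.yaml
```

A minimal synthetic-mode `config.yaml`:

```yaml
output_dir: out
seed: 1
scenario:
  n_years: 26
bootstrap_B: 0           # >= 200 enables bootstrap CIs
return_periods: [5, 10, 25, 50, 100]
```

Real-data mode replaces `scenario:` with CSV paths
(`exposures_csv`: `date,tmax,tmin,tmean,pm25,no2,o3`;
`mortality_csv`: `iso_week,age_band,deaths,population`;
optional `covariates_csv`: `iso_week,p_flu,p_COVID`).
Outputs are CSV tables (coefficients, attribution, odds ratios, return
levels/periods, diagnostics) plus a JSON run manifest and a log.

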
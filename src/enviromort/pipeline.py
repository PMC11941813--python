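"""End-to-end pipeline: simulate/ingest -> episodes -> baseline/p-scores ->
distributional regression -> attribution -> extreme-event indicators.

All stage outputs are written as CSV tables into the configured output
directory together with a JSON run manifest sufficient to reproduce the
run.  Configuration is a YAML file; exactly one of a synthetic scenario or
a set of real-input CSV paths must be present.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, attribution, baseline, distreg, episodes, extremes
from .synthetic import ExposureParams, ScenarioConfig, TruthBundle, generate_daily_exposures, generate_weekly_mortality

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("enviromort")

DEFAULT_CANDIDATES = (
    "COLD", "HEAT", "NO2", "O3", "PM25", "PSCORE_LAG1", "p_COVID", "p_flu",
)
EPISODE_COVARIATES = ("HEAT", "COLD", "PM25", "NO2", "O3")


class PipelineError(RuntimeError):
    """Stage failure with the stage name attached."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    output_dir: str = "out"
    seed: int | None = None
    scenario: ScenarioConfig | None = None
    exposures_csv: str | None = None
    mortality_csv: str | None = None
    covariates_csv: str | None = None
    thresholds: episodes.EpisodeThresholds = field(
        default_factory=episodes.EpisodeThresholds
    )
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    bootstrap_B: int = 0
    return_periods: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0, 100.0)

    def __post_init__(self) -> None:
        synthetic = self.scenario is not None
        real = self.exposures_csv is not None or self.mortality_csv is not None
        if synthetic == real:
            raise ValueError(
                "exactly one of a synthetic scenario or real input paths required"
            )
        if synthetic and self.seed is None:
            raise ValueError("seed is mandatory in synthetic mode")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {}
        for key in ("output_dir", "seed", "exposures_csv", "mortality_csv",
                    "covariates_csv", "bootstrap_B"):
            if key in raw:
                kwargs[key] = raw[key]
        if "candidates" in raw:
            kwargs["candidates"] = tuple(raw["candidates"])
        if "return_periods" in raw:
            kwargs["return_periods"] = tuple(float(t) for t in raw["return_periods"])
        if "thresholds" in raw:
            kwargs["thresholds"] = episodes.EpisodeThresholds(**raw["thresholds"])
        if "scenario" in raw:
            sc = dict(raw["scenario"])
            if "truth" in sc:
                sc["truth"] = TruthBundle(**sc["truth"])
            if "exposure" in sc:
                sc["exposure"] = ExposureParams(**sc["exposure"])
            if "age_groups" in sc:
                sc["age_groups"] = [(str(b), float(s)) for b, s in sc["age_groups"]]
            if "seed" not in sc and "seed" in raw:
                sc["seed"] = raw["seed"]
            kwargs["scenario"] = ScenarioConfig(**sc)
        return cls(**kwargs)


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / name, index=False, float_format="%.10g")


def _build_inputs(config: PipelineConfig, outdir: Path):
    """Return (exposures, mortality_long, extra_weekly) from either mode."""
    if config.scenario is not None:
        scenario = config.scenario
        if config.seed is not None and scenario.seed != config.seed:
            scenario = dataclasses.replace(scenario, seed=config.seed)
        exposures = generate_daily_exposures(scenario)
        bundle = generate_weekly_mortality(scenario, exposures)
        extra = bundle.weekly[["iso_week", "p_flu", "p_COVID"]].copy()
        _write(exposures, outdir, "exposures.csv")
        _write(bundle.mortality, outdir, "weekly_mortality.csv")
        _write(bundle.weekly, outdir, "synthetic_weekly_truth.csv")
        return exposures, bundle.mortality, extra
    exposures = pd.read_csv(config.exposures_csv, parse_dates=["date"])
    mortality = pd.read_csv(config.mortality_csv)
    extra = None
    if config.covariates_csv:
        extra = pd.read_csv(config.covariates_csv)
    return exposures, mortality, extra


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write result tables; returns a result dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        try:
            exposures, mortality, extra = _build_inputs(config, outdir)
            log.info("inputs ready: %d days, %d mortality rows",
                     len(exposures), len(mortality))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("inputs", str(e)) from e

        try:
            cal = episodes.detect_episode_days(exposures, config.thresholds)
            weekly_cov = episodes.weekly_cumulative_counts(cal)
            _write(cal, outdir, "episode_calendar.csv")
            _write(weekly_cov, outdir, "weekly_covariates.csv")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("episodes", str(e)) from e

        try:
            deaths = mortality.pivot(index="iso_week", columns="age_band",
                                     values="deaths")
            pop = mortality.pivot(index="iso_week", columns="age_band",
                                  values="population")
            weeks = weekly_cov.set_index("iso_week")
            common = [w for w in weeks.index if w in deaths.index]
            deaths, pop = deaths.loc[common], pop.loc[common]
            asmr = baseline.weekly_asmr(deaths, pop)
            asmr.index = pd.to_datetime(weeks.loc[common, "week_start"].to_numpy())
            bfit, B = baseline.fit_median_baseline(asmr)
            ps = baseline.compute_pscores(asmr, B)
            base_tab = pd.DataFrame(
                {
                    "iso_week": common,
                    "asmr": asmr.to_numpy(),
                    "baseline": B.to_numpy(),
                    "pscore": ps["pscore"].to_numpy(),
                    "pscore_lag1": ps["pscore_lag1"].to_numpy(),
                }
            )
            _write(base_tab, outdir, "baseline_pscores.csv")
            (outdir / "baseline_fit.json").write_text(bfit.to_json())
        except Exception as e:  # noqa: BLE001
            raise PipelineError("baseline", str(e)) from e

        try:
            table = weekly_cov.merge(base_tab, on="iso_week", how="inner")
            table = table.rename(columns={"pscore_lag1": "PSCORE_LAG1"})
            table["deaths"] = deaths.sum(axis=1).to_numpy()
            table["year"] = table["iso_year"]
            if extra is not None:
                table = table.merge(extra, on="iso_week", how="left")
            for c in config.candidates:
                if c not in table.columns:
                    raise ValueError(f"candidate covariate {c!r} unavailable")
            fit = distreg.stepwise_select(table, config.candidates)
            _write(fit.summary(), outdir, "coefficients.csv")
            qr = distreg.quantile_residuals(fit, table)
            _write(
                pd.DataFrame(
                    {
                        "ks_statistic": [qr.ks_statistic],
                        "ks_pvalue": [qr.ks_pvalue],
                    }
                ),
                outdir,
                "diagnostics.csv",
            )
            _write(
                pd.DataFrame({"worm_x": qr.worm_x, "worm_y": qr.worm_y}),
                outdir,
                "worm_plot.csv",
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("distreg", str(e)) from e

        try:
            attr_covs = [c for c in EPISODE_COVARIATES if c in fit.mu_terms]
            if attr_covs:
                yearly = attribution.yearly_attribution(fit, table, attr_covs)
                lo, hi = int(table["year"].min()), int(table["year"].max())
                day_cols = {c: f"{c.lower()}_days" for c in attr_covs}
                epi = table.melt(
                    id_vars="year",
                    value_vars=[day_cols[c] for c in attr_covs],
                    var_name="covariate", value_name="days",
                )
                epi["covariate"] = epi["covariate"].map(
                    {v: k for k, v in day_cols.items()}
                )
                epi_days = epi.groupby(["year", "covariate"])["days"].sum()
                summary = attribution.summarize_attribution(
                    yearly, (lo, hi), episode_days=epi_days
                )
                _write(yearly, outdir, "attribution_yearly.csv")
                _write(summary, outdir, "attribution_summary.csv")
            else:
                yearly = summary = None
        except Exception as e:  # noqa: BLE001
            raise PipelineError("attribution", str(e)) from e

        try:
            pscores = table["pscore"]
            u90 = extremes.empirical_threshold(pscores, 0.90)
            theta = extremes.extremal_index(pscores, u90)
            or_rows = []
            for c in attr_covs:
                if c not in fit.sigma_terms:
                    or_rows.append(
                        {"covariate": c, "model": "logistic",
                         "odds_ratio": extremes.odds_ratio(fit, c)}
                    )
            bin_ors, _ = extremes.fit_binomial_occurrence(
                table, u90, list(config.candidates)
            )
            for c, v in bin_ors.items():
                if c != "const":
                    or_rows.append(
                        {"covariate": c, "model": "binomial", "odds_ratio": float(v)}
                    )
            _write(
                pd.DataFrame(or_rows, columns=["covariate", "model", "odds_ratio"]),
                outdir,
                "odds_ratios.csv",
            )

            tail = extremes.exponential_tail(pscores, u90, theta)
            rl_rows = []
            for T in config.return_periods:
                rl_rows.append(
                    {
                        "return_period_years": T,
                        "logistic": extremes.return_level(fit, table, T, theta),
                        "exponential": tail.return_level(T),
                    }
                )
            _write(pd.DataFrame(rl_rows), outdir, "return_levels.csv")

            top = table.nlargest(2, "pscore")
            rp_rows = []
            for _, row in top.iterrows():
                y_ev = float(row["pscore"])
                rp_rows.append(
                    {
                        "iso_week": row["iso_week"],
                        "pscore": y_ev,
                        "logistic_return_period": extremes.return_period(
                            fit, table, y_ev, theta
                        ),
                        "exponential_return_period": tail.return_period(y_ev),
                    }
                )
            _write(pd.DataFrame(rp_rows), outdir, "return_periods.csv")
            results["u90"] = u90
            results["theta"] = theta
        except Exception as e:  # noqa: BLE001
            raise PipelineError("extremes", str(e)) from e

        if config.bootstrap_B >= 200:
            try:
                def indicators(f, sample):
                    out = {}
                    u = extremes.empirical_threshold(sample["pscore"], 0.90)
                    th = extremes.extremal_index(sample["pscore"], u)
                    out["u90"], out["theta"] = u, th
                    for c in attr_covs:
                        if c not in f.sigma_terms:
                            out[f"OR_{c}"] = extremes.odds_ratio(f, c)
                    for T in config.return_periods:
                        out[f"rl_{T:g}"] = extremes.return_level(f, sample, T, th)
                    return out

                boot = distreg.bootstrap_cis(
                    table, fit.mu_terms, fit.sigma_terms,
                    B=config.bootstrap_B, seed=config.seed or 0,
                    indicator_fn=indicators,
                )
                _write(boot.ci(), outdir, "bootstrap_coefficient_cis.csv")
                _write(boot.indicator_ci(), outdir, "bootstrap_indicator_cis.csv")
            except Exception as e:  # noqa: BLE001
                raise PipelineError("bootstrap", str(e)) from e

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "mode": "synthetic" if config.scenario is not None else "real",
            "candidates": list(config.candidates),
            "thresholds": dataclasses.asdict(config.thresholds),
            "bootstrap_B": config.bootstrap_B,
            "return_periods": list(config.return_periods),
            "selected_mu": list(fit.mu_terms),
            "selected_sigma": list(fit.sigma_terms),
            "n_weeks": int(fit.n),
            "hqc": float(fit.hqc),
        }
        if config.scenario is not None:
            manifest["scenario"] = json.loads(
                json.dumps(dataclasses.asdict(config.scenario), default=float)
            )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results.update({"fit": fit, "table": table, "manifest": manifest})
        log.info("pipeline complete")
        return results
    finally:
        log.removeHandler(handler)
        handler.close()
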
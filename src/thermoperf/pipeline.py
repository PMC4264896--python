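"""End-to-end pipeline: inputs -> TPC fits -> acclimation contrasts ->
operative-temperature summaries and warming exceedance -> calibration report.

Each stage reads the standard CSV inputs (generated synthetically or supplied
by the user), writes its tabular outputs into the run directory, and records
its status in ``report.json``.  A missing input skips the dependent stage
(status ``skipped``); an exception marks it ``failed`` and preserves the
outputs of earlier stages.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .acclim import acclimation_contrast, fit_trait_model, mass_trend, summarize_traits
from .calibration import calibrate
from .errors import ConfigError, ThermoperfError
from .operative import (
    DEFAULT_DAYTIME_WINDOW,
    exceedance_table,
    patch_anova,
    patch_summary,
    read_logger_csv,
)
from .synth import SynthConfig, write_inputs
from .tpc import extract_parameters, fit_candidates, fit_family

__all__ = ["PipelineConfig", "run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

#: Traits taken from the tolerance table vs. the per-individual curve table.
_TOLERANCE_TRAITS = ("crt_min_c", "t_pref_c", "crt_max_c")
_CURVE_TRAITS = ("ct_min", "t_opt", "ct_max", "v_max")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``scenario_acclimation_map`` pairs each warming offset with the
    acclimation whose fitted TPC limits judge it: the default maps the current
    climate to the 20 °C acclimation and a +5 °C scenario to the 25 °C one (a
    warmer future population is assumed to carry the warmer acclimation
    phenotype).
    """

    outdir: Path = Path("thermoperf_run")
    synth: bool = True
    seed: int = 0
    inputs: dict = field(default_factory=dict)  # name -> path overrides
    epsilon: float = 0.05
    daytime_window: tuple = DEFAULT_DAYTIME_WINDOW
    delta_t: tuple = (0.0, 5.0)
    scenario_acclimation_map: dict = field(
        default_factory=lambda: {0.0: 20.0, 5.0: 25.0}
    )
    exceedance_time_base: str = "interval"
    contrast_method: str = "profile"
    synth_config: SynthConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "daytime_window":
                cfg.daytime_window = tuple(
                    time(*map(int, v.split(":"))) for v in value
                )
            elif key == "scenario_acclimation_map":
                cfg.scenario_acclimation_map = {
                    float(k): float(v) for k, v in value.items()
                }
            elif key == "outdir":
                cfg.outdir = Path(value)
            elif key == "delta_t":
                cfg.delta_t = tuple(float(v) for v in value)
            elif key == "synth_config":
                cfg.synth_config = SynthConfig(**value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ConfigError(f"unknown config key {key!r}")
        return cfg

    def validate(self) -> "PipelineConfig":
        if not 0 < self.epsilon < 1:
            raise ConfigError("epsilon must be in (0, 1)")
        for dt in self.delta_t:
            if dt not in self.scenario_acclimation_map:
                raise ConfigError(
                    f"delta_t {dt} missing from scenario_acclimation_map"
                )
        return self


def _stage_inputs(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    names = ("performance", "tolerance", "te_series", "calibration")
    if config.synth:
        synth_cfg = (config.synth_config or SynthConfig()).with_seed(config.seed)
        return write_inputs(synth_cfg, outdir / "inputs")
    return {n: Path(config.inputs[n]) for n in names if n in config.inputs}


def _stage_tpc(perf: pd.DataFrame, config: PipelineConfig, outdir: Path):
    fit_rows, param_rows = [], []
    best_by_acc = {}
    meta = perf.groupby(["individual_id", "acclimation_c"]).agg(
        order=("order", "first") if "order" in perf else ("trial_index", "size"),
        body_mass_g=("body_mass_g", "first"),
    ).reset_index()
    for acc in sorted(perf["acclimation_c"].unique()):
        fits = fit_candidates(perf, level="population", acclimation_c=acc)
        for f in fits:
            fit_rows.append({
                "acclimation_c": acc, "family": f.family,
                "params": json.dumps([round(p, 6) for p in f.params]),
                "K": f.k, "n": f.n, "rss": f.rss, "aic": f.aic,
                "lambda_i": f.lambda_i, "w_i": f.w_i, "r2": f.r2,
            })
        best = fits[0]
        best_by_acc[acc] = extract_parameters(best, config.epsilon)
        # Individual curves reuse the acclimation-level best family.
        for ind in sorted(perf["individual_id"].unique()):
            try:
                f_ind = fit_family(perf, best.family, level="individual",
                                   acclimation_c=acc, individual_id=ind)
                p_ind = extract_parameters(f_ind, config.epsilon)
            except ThermoperfError as exc:
                warnings.warn(f"individual {ind} @ {acc} °C dropped: {exc}",
                              stacklevel=2)
                continue
            param_rows.append({
                "individual_id": ind, "acclimation_c": acc,
                "t_opt": p_ind.t_opt, "v_max": p_ind.v_max,
                "ct_min": p_ind.ct_min, "ct_max": p_ind.ct_max,
                "epsilon": config.epsilon, "family": f_ind.family,
            })
    fits_df = pd.DataFrame(fit_rows)
    params_df = pd.DataFrame(param_rows).merge(
        meta, on=["individual_id", "acclimation_c"], how="left"
    )
    fits_df.to_csv(outdir / "fits.csv", index=False)
    params_df.to_csv(outdir / "params.csv", index=False)
    return fits_df, params_df, best_by_acc


def _stage_stats(tol: pd.DataFrame, params_df: pd.DataFrame,
                 config: PipelineConfig, outdir: Path):
    summary = summarize_traits(tol, params_df)
    summary.to_csv(outdir / "summary.csv", index=False)
    contrast_rows = []
    sources = [(tol, _TOLERANCE_TRAITS)]
    if params_df is not None and not params_df.empty:
        sources.append((params_df, _CURVE_TRAITS))
    for table, traits in sources:
        levels = sorted(table["acclimation_c"].unique())
        pairs = list(zip(levels[:-1], levels[1:]))
        for trait in traits:
            model = fit_trait_model(table, trait)
            for pair in pairs:
                ci = acclimation_contrast(
                    model, pair, method=config.contrast_method,
                    seed=config.seed,
                )
                contrast_rows.append({
                    "trait": ci.trait, "acclim_from": pair[0],
                    "acclim_to": pair[1], "estimate": ci.estimate,
                    "ci_low": ci.ci_low, "ci_high": ci.ci_high,
                    "scale": ci.scale, "method": ci.method,
                    "effect": ci.effect,
                })
    contrasts = pd.DataFrame(contrast_rows)
    contrasts.to_csv(outdir / "contrasts.csv", index=False)
    trend = mass_trend(tol)
    return summary, contrasts, trend


def _scenario_limits(params_df: pd.DataFrame, best_by_acc: dict,
                     config: PipelineConfig) -> dict[float, tuple]:
    """TPC limits per warming scenario.

    Limits are the across-individual means of the extracted parameters for the
    mapped acclimation (the trait-table convention); the population-curve
    limits are the fallback when no individual fits survived.  The population
    mean curve is broadened by between-individual spread in T_opt, so its
    CT_max overstates the typical individual's limit.
    """
    out = {}
    for dt in config.delta_t:
        acc = config.scenario_acclimation_map[dt]
        sel = params_df[params_df["acclimation_c"] == acc] if not params_df.empty else params_df
        if not sel.empty:
            out[dt] = (float(sel["ct_min"].mean()), float(sel["t_opt"].mean()),
                       float(sel["ct_max"].mean()))
        elif acc in best_by_acc:
            p = best_by_acc[acc]
            out[dt] = (p.ct_min, p.t_opt, p.ct_max)
        else:
            raise ConfigError(
                f"scenario {dt} maps to acclimation {acc} with no fitted TPC"
            )
    return out


def _stage_operative(series, scenario_limits, config: PipelineConfig, outdir: Path):
    summaries = [patch_summary(s, window=config.daytime_window) for s in series]
    summaries_df = pd.DataFrame([vars(s) for s in summaries])
    summaries_df.to_csv(outdir / "patch_summary.csv", index=False)
    anova_rows = []
    for response in ("mean_te", "te_max", "water_loss_rate"):
        table = patch_anova(summaries_df, response)
        table.insert(0, "response", response)
        anova_rows.append(table)
    anova_df = pd.concat(anova_rows, ignore_index=True)
    anova_df.to_csv(outdir / "anova.csv", index=False)

    exceed_df = None
    if scenario_limits:
        exceed_df = exceedance_table(
            series, scenario_limits, window=config.daytime_window,
            time_base=config.exceedance_time_base,
        )
        exceed_df.to_csv(outdir / "exceedance.csv", index=False)
    return summaries_df, anova_df, exceed_df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write ``report.json``; returns the report dict.

    The report's ``status`` is ``ok`` when every runnable stage succeeded,
    ``partial`` when inputs for some stage were missing (those stages are
    ``skipped``), and ``failed`` when a stage raised.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "epsilon": config.epsilon,
            "daytime_window": [t.isoformat() for t in config.daytime_window],
            "delta_t": list(config.delta_t),
            "scenario_acclimation_map": {
                str(k): v for k, v in config.scenario_acclimation_map.items()
            },
            "exceedance_time_base": config.exceedance_time_base,
            "contrast_method": config.contrast_method,
            "synth": config.synth,
        },
        "stages": {},
    }

    def record(name, status, **extra):
        report["stages"][name] = {"status": status, **extra}

    paths = _stage_inputs(config, outdir)
    record("inputs", "ok", files={k: str(v) for k, v in paths.items()})

    best_by_acc: dict = {}
    params_df = pd.DataFrame()
    failed = False

    if "performance" in paths and Path(paths["performance"]).exists():
        try:
            perf = pd.read_csv(paths["performance"])
            fits_df, params_df, best_by_acc = _stage_tpc(perf, config, outdir)
            record("tpc_fit", "ok",
                   best_family={
                       str(a): fits_df[fits_df["acclimation_c"] == a]
                       .sort_values("aic")["family"].iloc[0]
                       for a in fits_df["acclimation_c"].unique()
                   },
                   limits={
                       str(a): {"ct_min": p.ct_min, "t_opt": p.t_opt,
                                "ct_max": p.ct_max}
                       for a, p in best_by_acc.items()
                   })
        except Exception as exc:
            failed = True
            record("tpc_fit", "failed", error=str(exc))
    else:
        record("tpc_fit", "skipped", reason="performance input missing")

    if "tolerance" in paths and Path(paths["tolerance"]).exists():
        try:
            tol = pd.read_csv(paths["tolerance"])
            summary, contrasts, trend = _stage_stats(
                tol, params_df, config, outdir
            )
            record("acclimation_stats", "ok",
                   n_contrasts=len(contrasts),
                   mass_trend={"slope": trend.estimate,
                               "ci": [trend.ci_low, trend.ci_high]})
        except Exception as exc:
            failed = True
            record("acclimation_stats", "failed", error=str(exc))
    else:
        record("acclimation_stats", "skipped", reason="tolerance input missing")

    if "te_series" in paths and Path(paths["te_series"]).exists():
        try:
            series = read_logger_csv(paths["te_series"])
            limits = (
                _scenario_limits(params_df, best_by_acc, config)
                if (not params_df.empty or best_by_acc) else {}
            )
            _, anova_df, exceed_df = _stage_operative(
                series, limits, config, outdir
            )
            extra = {}
            if exceed_df is not None:
                extra["max_frac_above_ctmax"] = float(
                    exceed_df["frac_above_ctmax"].max()
                )
            record("operative_env", "ok", **extra)
        except Exception as exc:
            failed = True
            record("operative_env", "failed", error=str(exc))
    else:
        record("operative_env", "skipped", reason="te_series input missing")

    if "calibration" in paths and Path(paths["calibration"]).exists():
        try:
            pairs = pd.read_csv(paths["calibration"])
            cal = calibrate(pairs)
            with open(outdir / "calibration_report.json", "w") as fh:
                json.dump(cal.to_dict(), fh, indent=2)
            record("calibration", "ok", pearson_r=cal.pearson_r)
        except Exception as exc:
            failed = True
            record("calibration", "failed", error=str(exc))
    else:
        record("calibration", "skipped", reason="calibration input missing")

    statuses = {s["status"] for s in report["stages"].values()}
    report["status"] = ("failed" if failed
                        else "partial" if "skipped" in statuses else "ok")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
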
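"""Operative-temperature (T_e) series: ingestion, daytime summaries, the
patch two-way ANOVA, warming projection and exceedance of TPC limits.

T_e loggers sit inside agar frog models deployed in the four sun/shade x
wet/dry patch combinations (two replicate models per combination, one per
pond), sampling every 5 minutes.  Daytime analyses restrict to a clock window
(default 07:00-20:00).  Warming scenarios shift the whole series by a constant
offset (operative temperature scales linearly with air temperature), and
exceedance reports the fraction of daytime 30-min intervals falling in each
band of a thermal performance curve: below CT_min, CT_min..T_opt,
T_opt..CT_max, above CT_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ParseError
from .tpc import TPCParams

__all__ = [
    "TeSeries",
    "DaytimeSummary",
    "ExceedanceSummary",
    "DEFAULT_DAYTIME_WINDOW",
    "read_logger_csv",
    "write_logger_csv",
    "daytime_filter",
    "interval_average",
    "patch_summary",
    "patch_anova",
    "project_warming",
    "exceedance",
    "exceedance_table",
    "group_by_patch",
]

#: Default daytime clock window (half-open), the one attached to the headline
#: patch comparisons.  Configurable everywhere it is used.
DEFAULT_DAYTIME_WINDOW: tuple[time, time] = (time(7, 0), time(20, 0))

_EXPOSURES = ("sun", "shade")
_MOISTURES = ("wet", "dry")


@dataclass(frozen=True)
class TeSeries:
    """One logger series from one physical model in one patch."""

    model_id: str
    pond: str
    exposure: str
    moisture: str
    samples: pd.DataFrame  # columns: timestamp (datetime64), temp_c
    mass_before_g: float
    mass_after_g: float
    deployment_hours: float
    delta_t: float = 0.0  # cumulative warming offset applied
    gaps: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self):
        if self.exposure not in _EXPOSURES:
            raise ParseError(f"unknown exposure {self.exposure!r}")
        if self.moisture not in _MOISTURES:
            raise ParseError(f"unknown moisture {self.moisture!r}")
        if self.deployment_hours <= 0:
            raise ParseError("deployment_hours must be > 0")
        ts = self.samples["timestamp"]
        diffs = ts.diff().dropna()
        bad = diffs[diffs <= pd.Timedelta(0)]
        if len(bad):
            raise ParseError(
                f"model {self.model_id}: timestamps not strictly increasing "
                f"at {ts.loc[bad.index[0]]}"
            )

    @property
    def patch(self) -> tuple[str, str]:
        return (self.exposure, self.moisture)

    def temperatures(self) -> np.ndarray:
        return self.samples["temp_c"].to_numpy(float)


@dataclass(frozen=True)
class DaytimeSummary:
    """Daytime aggregate for one model: mean/max T_e and water-loss rate."""

    model_id: str
    pond: str
    exposure: str
    moisture: str
    mean_te: float
    te_max: float
    water_loss_rate: float  # g/h

    def __post_init__(self):
        if self.te_max < self.mean_te:
            raise ValueError("te_max cannot be below mean_te")


@dataclass(frozen=True)
class ExceedanceSummary:
    """Fractions of daytime intervals in each TPC band for one patch."""

    patch: tuple[str, str]
    delta_t: float
    frac_below_ctmin: float
    frac_ctmin_to_topt: float
    frac_topt_to_ctmax: float
    frac_above_ctmax: float
    n_intervals: int

    def __post_init__(self):
        fracs = (self.frac_below_ctmin, self.frac_ctmin_to_topt,
                 self.frac_topt_to_ctmax, self.frac_above_ctmax)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("band fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("band fractions must sum to 1")


# ---------------------------------------------------------------------------
# I/O

_META_COLS = ("pond", "exposure", "moisture", "mass_before_g", "mass_after_g",
              "deployment_hours")


def read_logger_csv(path: str | Path, cadence_minutes: float = 5.0) -> list[TeSeries]:
    """Parse a logger export into one :class:`TeSeries` per model.

    Expects long format with columns ``model_id, pond, exposure, moisture,
    timestamp, temp_c, mass_before_g, mass_after_g, deployment_hours``.
    Timestamps must be strictly increasing within each model; intervals longer
    than the nominal cadence are flagged as gaps (never interpolated).
    """
    df = pd.read_csv(path)
    needed = {"model_id", "timestamp", "temp_c", *_META_COLS}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = []
    for mid, g in df.groupby("model_id", sort=True):
        meta = {c: g[c].iloc[0] for c in _META_COLS}
        for c in _META_COLS:
            if g[c].nunique() > 1:
                raise ParseError(f"model {mid}: inconsistent metadata in {c}")
        samples = g[["timestamp", "temp_c"]].reset_index(drop=True)
        diffs = samples["timestamp"].diff().dropna()
        gaps = tuple(
            samples["timestamp"][diffs[diffs > pd.Timedelta(minutes=cadence_minutes)].index]
        )
        out.append(TeSeries(
            model_id=str(mid), pond=str(meta["pond"]),
            exposure=str(meta["exposure"]), moisture=str(meta["moisture"]),
            samples=samples,
            mass_before_g=float(meta["mass_before_g"]),
            mass_after_g=float(meta["mass_after_g"]),
            deployment_hours=float(meta["deployment_hours"]),
            gaps=gaps,
        ))
    if not out:
        raise ParseError(f"no logger rows in {path}")
    return out


def write_logger_csv(series: list[TeSeries], path: str | Path) -> Path:
    """Inverse of :func:`read_logger_csv` (lossless round trip)."""
    rows = []
    for s in series:
        for _, r in s.samples.iterrows():
            rows.append({
                "model_id": s.model_id, "pond": s.pond,
                "exposure": s.exposure, "moisture": s.moisture,
                "timestamp": r["timestamp"].isoformat(), "temp_c": r["temp_c"],
                "mass_before_g": s.mass_before_g,
                "mass_after_g": s.mass_after_g,
                "deployment_hours": s.deployment_hours,
            })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Windowing and aggregation


def daytime_filter(
    series: TeSeries,
    window: tuple[time, time] = DEFAULT_DAYTIME_WINDOW,
) -> TeSeries:
    """Restrict samples to the half-open clock window ``[start, end)``."""
    start, end = window
    if start >= end:
        raise ConfigError(f"degenerate daytime window {start}-{end}")
    clock = series.samples["timestamp"].dt.time
    mask = (clock >= start) & (clock < end)
    kept = series.samples[mask.to_numpy()].reset_index(drop=True)
    if kept.empty:
        raise ConfigError(
            f"model {series.model_id}: no samples in window {start}-{end}"
        )
    return replace(series, samples=kept)


def interval_average(
    series: TeSeries | list[TeSeries],
    width_minutes: int = 30,
    cadence_minutes: float = 5.0,
) -> pd.DataFrame:
    """Average temperatures over aligned fixed-width intervals.

    When several replicate series are given, samples are pooled across models
    before averaging, so each interval mean is the across-model daytime mean.
    Columns: interval_start, mean_temp_c, sd_temp_c, n_samples.
    """
    if width_minutes <= 0 or width_minutes % cadence_minutes:
        raise ConfigError(
            f"interval width {width_minutes} min must be a positive multiple "
            f"of the {cadence_minutes}-min cadence"
        )
    many = series if isinstance(series, list) else [series]
    frames = [s.samples for s in many]
    allsamp = pd.concat(frames, ignore_index=True)
    binned = allsamp["timestamp"].dt.floor(f"{width_minutes}min")
    grp = allsamp.groupby(binned)["temp_c"]
    out = grp.agg(mean_temp_c="mean", sd_temp_c="std", n_samples="count")
    out.index.name = "interval_start"
    return out.reset_index()


def patch_summary(
    series: TeSeries,
    window: tuple[time, time] | None = None,
) -> DaytimeSummary:
    """Daytime mean/max T_e and water-loss rate for one model.

    Pass ``window`` to filter here, or ``None`` if the series is already
    daytime-filtered.  Water loss = (mass before - mass after) / deployment
    hours; a mass gain is reported as a negative rate with a warning.
    """
    s = daytime_filter(series, window) if window is not None else series
    temps = s.temperatures()
    rate = (s.mass_before_g - s.mass_after_g) / s.deployment_hours
    if rate < 0:
        warnings.warn(
            f"model {s.model_id}: mass increased during deployment; "
            "water-loss rate reported negative",
            stacklevel=2,
        )
    return DaytimeSummary(
        model_id=s.model_id, pond=s.pond, exposure=s.exposure,
        moisture=s.moisture, mean_te=float(temps.mean()),
        te_max=float(temps.max()), water_loss_rate=float(rate),
    )


# ---------------------------------------------------------------------------
# Patch ANOVA


def _cell_means(df, response):
    return {
        (e, m): df[(df["exposure"] == e) & (df["moisture"] == m)][response]
        for e in _EXPOSURES for m in _MOISTURES
    }


def patch_anova(summaries, response: str) -> pd.DataFrame:
    """Two-way ANOVA of a daytime response over exposure x moisture.

    Follows the two-stage design used for the field comparison: the two main
    effects are tested in the additive model (error df = n - 3, i.e. 1 and 5
    with eight models), the interaction in the full factorial (error df =
    n - 4, i.e. 1 and 4).  Requires a balanced design with two replicate
    models per cell.

    ``summaries`` is a DataFrame (or list of :class:`DaytimeSummary`) with
    columns ``exposure``, ``moisture`` and the response.
    """
    if isinstance(summaries, list):
        summaries = pd.DataFrame([vars(s) for s in summaries])
    df = summaries
    if response not in df.columns:
        raise ConfigError(f"response {response!r} not in summaries")
    cells = _cell_means(df, response)
    counts = {k: len(v) for k, v in cells.items()}
    n_rep = next(iter(counts.values()))
    if any(c != n_rep or c == 0 for c in counts.values()):
        missing = [k for k, c in counts.items() if c != max(counts.values())]
        raise ConfigError(f"unbalanced design; short cells: {missing}")

    n = len(df)
    work = df[["exposure", "moisture", response]].rename(columns={response: "resp"})
    if float(work["resp"].var(ddof=0)) == 0.0:
        # Constant response: every effect is exactly null.
        return pd.DataFrame([
            {"factor": "exposure", "F": 0.0, "df1": 1, "df2": n - 3, "p": 1.0},
            {"factor": "moisture", "F": 0.0, "df1": 1, "df2": n - 3, "p": 1.0},
            {"factor": "exposure:moisture", "F": 0.0, "df1": 1, "df2": n - 4,
             "p": 1.0},
        ])

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        additive = anova_lm(
            smf.ols("resp ~ C(exposure) + C(moisture)", data=work).fit()
        )
        full = anova_lm(
            smf.ols("resp ~ C(exposure) * C(moisture)", data=work).fit()
        )

    ss_total = float(((work["resp"] - work["resp"].mean()) ** 2).sum())

    def frow(factor, table, row):
        f = float(table.loc[row, "F"])
        df_err = int(table.loc["Residual", "df"])
        if float(table.loc[row, "sum_sq"]) <= 1e-12 * ss_total:
            f = 0.0  # null factor; avoids 0/0 noise when residual SS is ~0
        elif not np.isfinite(f):
            f = float("inf")
        return {"factor": factor, "F": f, "df1": 1, "df2": df_err,
                "p": float(stats.f.sf(f, 1, df_err))}

    return pd.DataFrame([
        frow("exposure", additive, "C(exposure)"),
        frow("moisture", additive, "C(moisture)"),
        frow("exposure:moisture", full, "C(exposure):C(moisture)"),
    ])


# ---------------------------------------------------------------------------
# Warming projection and exceedance


def project_warming(series: TeSeries, delta_t: float) -> TeSeries:
    """Shift every temperature by ``+delta_t`` °C (uniform warming offset)."""
    if not np.isfinite(delta_t):
        raise ConfigError("delta_t must be finite")
    shifted = series.samples.copy()
    shifted["temp_c"] = shifted["temp_c"] + delta_t
    return replace(series, samples=shifted, delta_t=series.delta_t + delta_t)


def _limits(limits) -> tuple[float, float, float]:
    if isinstance(limits, TPCParams):
        trio = (limits.ct_min, limits.t_opt, limits.ct_max)
    else:
        trio = tuple(float(v) for v in limits)
        if len(trio) != 3:
            raise ConfigError("limits must be TPCParams or (ct_min, t_opt, ct_max)")
    ct_min, t_opt, ct_max = trio
    if not ct_min < ct_max:
        raise ConfigError(f"need ct_min < ct_max, got {ct_min} >= {ct_max}")
    if not ct_min <= t_opt <= ct_max:
        raise ConfigError("t_opt must lie between the critical limits")
    return trio


def exceedance(
    series: TeSeries | list[TeSeries],
    limits,
    *,
    window: tuple[time, time] = DEFAULT_DAYTIME_WINDOW,
    delta_t: float = 0.0,
    time_base: str = "interval",
    width_minutes: int = 30,
) -> ExceedanceSummary:
    """Fraction of daytime time units in each thermal band of a TPC.

    Replicate series of the same patch are pooled; temperatures are first
    shifted by ``delta_t``, restricted to the daytime ``window``, and (by
    default) averaged to ``width_minutes`` intervals across replicates, the
    time unit at which band membership is counted.  ``time_base='raw'`` counts
    the 5-min samples instead.  Bands are half-open around T_opt:
    ``(-inf, ct_min) | [ct_min, t_opt] | (t_opt, ct_max] | (ct_max, inf)``.
    """
    ct_min, t_opt, ct_max = _limits(limits)
    many = series if isinstance(series, list) else [series]
    patches = {s.patch for s in many}
    if len(patches) > 1:
        raise ConfigError(f"series from multiple patches: {sorted(patches)}")
    shifted = [daytime_filter(project_warming(s, delta_t), window) for s in many]
    if time_base == "interval":
        temps = interval_average(shifted, width_minutes)["mean_temp_c"].to_numpy()
    elif time_base == "raw":
        temps = np.concatenate([s.temperatures() for s in shifted])
    else:
        raise ConfigError(f"unknown time_base {time_base!r}")
    n = len(temps)
    below = int((temps < ct_min).sum())
    cold = int(((temps >= ct_min) & (temps <= t_opt)).sum())
    warm = int(((temps > t_opt) & (temps <= ct_max)).sum())
    above = int((temps > ct_max).sum())
    total_delta = many[0].delta_t + delta_t
    return ExceedanceSummary(
        patch=next(iter(patches)), delta_t=total_delta,
        frac_below_ctmin=below / n, frac_ctmin_to_topt=cold / n,
        frac_topt_to_ctmax=warm / n, frac_above_ctmax=above / n,
        n_intervals=n,
    )


def group_by_patch(series: list[TeSeries]) -> dict[tuple[str, str], list[TeSeries]]:
    out: dict[tuple[str, str], list[TeSeries]] = {}
    for s in series:
        out.setdefault(s.patch, []).append(s)
    return out


def exceedance_table(
    series: list[TeSeries],
    scenario_limits: dict[float, object],
    *,
    window: tuple[time, time] = DEFAULT_DAYTIME_WINDOW,
    time_base: str = "interval",
    width_minutes: int = 30,
) -> pd.DataFrame:
    """Exceedance summary for every patch under every warming scenario.

    ``scenario_limits`` maps a warming offset (°C) to the TPC limits to judge
    it against — under sustained warming the population is expected to carry
    the acclimation matching its new thermal regime, so each scenario may use
    different limits.
    """
    rows = []
    for (exposure, moisture), group in sorted(group_by_patch(series).items()):
        for delta_t, limits in sorted(scenario_limits.items()):
            s = exceedance(group, limits, window=window, delta_t=delta_t,
                           time_base=time_base, width_minutes=width_minutes)
            rows.append({
                "exposure": exposure, "moisture": moisture,
                "delta_t": delta_t,
                "frac_below_ctmin": s.frac_below_ctmin,
                "frac_ctmin_to_topt": s.frac_ctmin_to_topt,
                "frac_topt_to_ctmax": s.frac_topt_to_ctmax,
                "frac_above_ctmax": s.frac_above_ctmax,
                "n_intervals": s.n_intervals,
            })
    return pd.DataFrame(rows)
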
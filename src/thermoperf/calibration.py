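"""Validation of surrogate body-temperature measurements.

Two checks: (1) dorsal infrared readings track cloacal (true core) body
temperature — a least-squares line with Pearson correlation and its t
statistic, computed on per-chamber-temperature means; (2) agar-model operative
temperatures are statistically indistinguishable from live-animal body
temperatures — a one-way ANOVA between the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

__all__ = ["CalibrationResult", "calibrate", "validate_surrogate"]


@dataclass(frozen=True)
class CalibrationResult:
    """Dorsal-on-cloacal regression summary (per-temperature means)."""

    slope: float
    intercept: float
    pearson_r: float
    t_statistic: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return asdict(self)


def calibrate(pairs: pd.DataFrame) -> CalibrationResult:
    """Regress dorsal on cloacal body temperature.

    ``pairs`` holds columns ``chamber_t_c``, ``dorsal_tb_c``, ``cloacal_tb_c``
    (possibly several rows per chamber temperature); readings are averaged per
    chamber temperature first, so the degrees of freedom reflect the number of
    chamber settings (7 settings -> df = 5).  ``t = r sqrt((n-2)/(1-r^2))``;
    perfectly collinear data report an infinite t.
    """
    for col in ("chamber_t_c", "dorsal_tb_c", "cloacal_tb_c"):
        if col not in pairs.columns:
            raise ConfigError(f"missing column {col!r}")
    means = pairs.groupby("chamber_t_c")[["dorsal_tb_c", "cloacal_tb_c"]].mean()
    n = len(means)
    if n < 3:
        raise ConfigError(f"need >= 3 chamber temperatures, got {n}")
    x = means["cloacal_tb_c"].to_numpy(float)
    y = means["dorsal_tb_c"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ConfigError("zero variance in cloacal temperatures")
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    df = n - 2
    if abs(r) >= 1.0 - 1e-15:
        t = float("inf") if r > 0 else float("-inf")
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return CalibrationResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        pearson_r=r, t_statistic=float(t), df=df, p=p,
    )


def validate_surrogate(group_a, group_b) -> tuple[float, int, int, float]:
    """One-way ANOVA between surrogate and live-animal temperatures.

    Returns ``(F, df1, df2, p)`` with ``df = (1, n_a + n_b - 2)``; with two
    groups F equals the square of the pooled two-sample t statistic.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each group needs at least 2 values")
    df2 = len(a) + len(b) - 2
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1, df2, 1.0
    f, p = stats.f_oneway(a, b)
    return float(f), 1, df2, float(p)
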
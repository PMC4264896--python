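"""Thermal performance curve (TPC) fitting, AIC model selection and parameter
extraction.

A TPC describes how a performance trait (here maximum jumping speed, cm/s)
varies with body temperature: it rises from a lower critical temperature to an
optimum ``T_opt`` where performance is maximal (``V_max``) and falls steeply to
an upper critical temperature.  Candidate curves are unimodal peak functions
fitted by least squares; the best family per dataset is chosen by the
least-squares Akaike information criterion and relative support is quantified
with Akaike weights.

Because the candidate families used here (Gaussian, Lorentzian, logistic peak)
are strictly positive, a literal zero-performance intercept does not exist.
Critical limits ``CT_min``/``CT_max`` are therefore operationalised as the two
temperatures at which the fitted curve drops to a small fraction ``epsilon`` of
``V_max`` (default 0.05).  ``epsilon`` is exposed everywhere it is used.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares, minimize_scalar

from .errors import ExtractionError, FitError

__all__ = [
    "FAMILIES",
    "DEFAULT_CANDIDATES",
    "TPCModelFit",
    "TPCParams",
    "evaluate_family",
    "fit_family",
    "fit_candidates",
    "compute_aic",
    "akaike_weights",
    "select_best",
    "extract_parameters",
    "tpc_breadth",
    "population_curve_data",
    "individual_curve_data",
]

#: Candidate peak families and their parameter counts.
FAMILIES: dict[str, int] = {
    "gaussian": 3,
    "lorentzian": 3,
    "logistic_peak": 3,
    "weibull_peak": 4,
}

#: Families compared by default.  The four-parameter Weibull peak is available
#: but excluded from the default candidate set so that selection runs over the
#: same three-way comparison used for the population curves.
DEFAULT_CANDIDATES: tuple[str, ...] = ("gaussian", "lorentzian", "logistic_peak")

#: Fixed family order used as the final tie-break in model selection.
_FAMILY_ORDER: tuple[str, ...] = (
    "gaussian",
    "lorentzian",
    "logistic_peak",
    "weibull_peak",
)


@dataclass(frozen=True)
class TPCModelFit:
    """One candidate curve fitted to one dataset, with AIC bookkeeping.

    ``lambda_i`` (AIC difference from the best candidate) and ``w_i`` (Akaike
    weight) are relative quantities: they are ``nan`` until the fit is placed
    in a candidate set (see :func:`fit_candidates`).
    """

    family: str
    params: tuple[float, ...]
    k: int
    rss: float
    n: int
    aic: float
    r2: float
    level: str = "population"
    lambda_i: float = float("nan")
    w_i: float = float("nan")

    def __call__(self, t):
        return evaluate_family(self.family, self.params, t)


@dataclass(frozen=True)
class TPCParams:
    """Biological parameters extracted from a fitted curve.

    ``ct_min``/``ct_max`` are the temperatures at which the curve equals
    ``epsilon * v_max``; ``epsilon`` records the threshold used.
    """

    t_opt: float
    v_max: float
    ct_min: float
    ct_max: float
    epsilon: float = 0.05

    def __post_init__(self):
        if not (self.ct_min < self.t_opt < self.ct_max):
            raise ExtractionError(
                f"invalid ordering: ct_min={self.ct_min}, t_opt={self.t_opt}, "
                f"ct_max={self.ct_max}"
            )
        if not 0.0 < self.epsilon < 1.0:
            raise ExtractionError(f"epsilon must be in (0, 1), got {self.epsilon}")


def evaluate_family(family: str, params: Sequence[float], t):
    """Evaluate a peak family at temperature(s) ``t`` (°C).

    All families reach their maximum ``a`` at ``t = b``; ``c`` (> 0) sets the
    width.  The ``weibull_peak`` family adds a dimensionless shape ``d`` that
    controls asymmetry (skew), with its mode kept at ``b``.
    """
    t = np.asarray(t, dtype=float)
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}; known: {sorted(FAMILIES)}")
    if len(params) != FAMILIES[family]:
        raise ValueError(
            f"{family} expects {FAMILIES[family]} parameters, got {len(params)}"
        )
    if family == "weibull_peak":
        a, b, c, d = params
    else:
        a, b, c = params
        d = None
    if c == 0:
        raise ValueError("width parameter c must be nonzero")

    u = (t - b) / c
    if family == "gaussian":
        out = a * np.exp(-0.5 * u**2)
    elif family == "lorentzian":
        out = a / (1.0 + u**2)
    elif family == "logistic_peak":
        # 4a e^{-u} / (1 + e^{-u})^2 ; symmetric, equals a at u = 0.
        with np.errstate(over="ignore"):
            e = np.exp(-np.abs(u))  # symmetric in u; avoids overflow
        out = 4.0 * a * e / (1.0 + e) ** 2
    else:  # weibull_peak: unimodal, mode at b, peak value a, shape d > 1
        if d is None or d <= 1.0:
            raise ValueError("weibull_peak shape d must exceed 1")
        g = ((d - 1.0) / d) ** (1.0 / d)
        z = u + g
        out = np.where(
            z > 0,
            a
            * g ** (1.0 - d)
            * np.where(z > 0, z, 1.0) ** (d - 1.0)
            * np.exp(-np.where(z > 0, z, 0.0) ** d + (d - 1.0) / d),
            0.0,
        )
    return out if out.ndim else float(out)


def compute_aic(rss: float, n: int, k: int, *, corrected: bool = False) -> float:
    """Least-squares AIC: ``n ln(RSS/n) + 2K`` (plus the AICc term if asked).

    A perfect fit (``rss == 0``) has an unbounded likelihood under the
    least-squares formulation; a ``-inf`` sentinel is returned with a warning.
    """
    if n <= k:
        raise ValueError(f"need n > K, got n={n}, K={k}")
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    if rss == 0:
        warnings.warn("rss == 0: perfect fit, AIC reported as -inf", stacklevel=2)
        return float("-inf")
    aic = n * math.log(rss / n) + 2 * k
    if corrected:
        if n - k - 1 <= 0:
            raise ValueError("AICc undefined for n <= K + 1")
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def akaike_weights(aics: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """AIC differences ``lambda_i`` and Akaike weights ``w_i``.

    ``lambda_i = AIC_i - min(AIC)``; ``w_i = exp(-lambda_i/2)`` normalised to
    sum to one.  ``-inf`` AICs (perfect fits) absorb all weight.
    """
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0:
        raise ValueError("need at least one AIC")
    if np.isnan(aics).any():
        raise ValueError("AICs must not be NaN")
    best = aics.min()
    if np.isneginf(best):
        lam = np.where(np.isneginf(aics), 0.0, np.inf)
    else:
        lam = aics - best
    w = np.exp(-0.5 * lam)
    w /= w.sum()
    return lam, w


def select_best(fits: Sequence[TPCModelFit]) -> TPCModelFit:
    """Pick the fit with minimal AIC; ties broken by fewer parameters, then by
    the fixed family order."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(
        fits, key=lambda f: (f.aic, f.k, _FAMILY_ORDER.index(f.family))
    )


# ---------------------------------------------------------------------------
# Data preparation


def _average_trials(obs: pd.DataFrame) -> pd.DataFrame:
    """Per individual x acclimation x temperature: mean speed over the two
    trials (the analysis unit for individual curves)."""
    keys = ["individual_id", "acclimation_c", "test_temp_c"]
    return obs.groupby(keys, as_index=False)["speed_cm_s"].mean()


def individual_curve_data(
    obs: pd.DataFrame, individual_id, acclimation_c: float
) -> tuple[np.ndarray, np.ndarray]:
    """(temperatures, trial-averaged speeds) for one individual x acclimation."""
    avg = _average_trials(obs)
    sel = avg[
        (avg["individual_id"] == individual_id)
        & (avg["acclimation_c"] == acclimation_c)
    ]
    return sel["test_temp_c"].to_numpy(), sel["speed_cm_s"].to_numpy()


def population_curve_data(
    obs: pd.DataFrame, acclimation_c: float
) -> tuple[np.ndarray, np.ndarray]:
    """(temperatures, mean-over-individuals speeds) for one acclimation.

    Trials are first averaged within individual, then averaged across
    individuals at each test temperature — the points a population-level curve
    is fitted through.
    """
    avg = _average_trials(obs)
    sel = avg[avg["acclimation_c"] == acclimation_c]
    pop = sel.groupby("test_temp_c", as_index=False)["speed_cm_s"].mean()
    return pop["test_temp_c"].to_numpy(), pop["speed_cm_s"].to_numpy()


# ---------------------------------------------------------------------------
# Fitting

#: Multi-start perturbation factors (+/- 50%) applied to each heuristic start.
_START_FACTORS = (0.5, 1.0, 1.5)


def _starts(family: str, t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    a0 = float(y.max())
    b0 = float(t[int(np.argmax(y))])
    c0 = float((t.max() - t.min()) / 2.0) or 1.0
    base = [a0, b0, c0]
    grids = [[f * v for f in _START_FACTORS] for v in base]
    if family == "weibull_peak":
        grids.append([1.5, 3.0, 4.5])
    return [np.array(p) for p in itertools.product(*grids)]


def _bounds(family: str) -> tuple[list[float], list[float]]:
    lo, hi = [1e-9, -100.0, 1e-6], [np.inf, 200.0, 1e3]
    if family == "weibull_peak":
        lo.append(1.0 + 1e-6)
        hi.append(50.0)
    return lo, hi


def fit_family(
    obs: pd.DataFrame | tuple[np.ndarray, np.ndarray],
    family: str,
    *,
    level: str = "population",
    acclimation_c: float | None = None,
    individual_id=None,
    corrected_aic: bool = False,
) -> TPCModelFit:
    """Least-squares fit of one peak family.

    ``obs`` is either the raw trial table (``performance.csv`` layout, see
    :mod:`thermoperf.synth`) — in
    which case ``level`` selects population (per-temperature means, as plotted
    in a mean-value curve) or individual (one frog's trial-averaged speeds) —
    or a prepared ``(temperatures, speeds)`` pair.

    Optimisation is a deterministic multi-start local search: data-driven
    starting values (peak height = max speed, peak position = argmax
    temperature, width = half the temperature range) perturbed by +/-50% on a
    3x3x3 grid, each start refined by trust-region least squares; the lowest
    residual sum of squares wins, with the fixed grid order breaking ties.
    """
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}; known: {sorted(FAMILIES)}")
    if isinstance(obs, pd.DataFrame):
        if level == "population":
            if acclimation_c is None:
                accs = obs["acclimation_c"].unique()
                if len(accs) != 1:
                    raise FitError(
                        "population fit over multiple acclimations: pass acclimation_c"
                    )
                acclimation_c = accs[0]
            t, y = population_curve_data(obs, acclimation_c)
        elif level == "individual":
            if individual_id is None:
                raise FitError("individual-level fit requires individual_id")
            t, y = individual_curve_data(obs, individual_id, acclimation_c)
        else:
            raise ValueError(f"unknown level {level!r}")
    else:
        t, y = np.asarray(obs[0], float), np.asarray(obs[1], float)

    k = FAMILIES[family]
    n_temps = len(np.unique(t))
    if n_temps < k + 1:
        raise FitError(
            f"{family} has {k} parameters but only {n_temps} distinct "
            f"temperatures; need at least {k + 1}"
        )

    def resid(p):
        return evaluate_family(family, p, t) - y

    lo, hi = _bounds(family)
    best = None
    diagnostics = []
    for x0 in _starts(family, t, y):
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # pragma: no cover - scipy internal failures
            diagnostics.append(f"start {x0}: {exc}")
            continue
        if not sol.success or not np.isfinite(sol.cost):
            diagnostics.append(f"start {x0}: status {sol.status}")
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol.x)
    if best is None:
        raise FitError(
            f"all starts failed for {family}: " + "; ".join(diagnostics[:5])
        )
    rss, p = best
    n = len(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aic = compute_aic(max(rss, 0.0), n, k, corrected=corrected_aic) if rss > 0 else float("-inf")
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return TPCModelFit(
        family=family,
        params=tuple(float(v) for v in p),
        k=k,
        rss=rss,
        n=n,
        aic=aic,
        r2=max(0.0, min(1.0, r2)),
        level=level,
    )


def fit_candidates(
    obs,
    families: Iterable[str] = DEFAULT_CANDIDATES,
    **kwargs,
) -> list[TPCModelFit]:
    """Fit every candidate family and fill in ``lambda_i``/``w_i``.

    Returns fits sorted by AIC (best first).  Families whose fit fails are
    dropped with a warning; at least one must succeed.
    """
    fits = []
    for fam in families:
        try:
            fits.append(fit_family(obs, fam, **kwargs))
        except FitError as exc:
            warnings.warn(f"candidate {fam} dropped: {exc}", stacklevel=2)
    if not fits:
        raise FitError("no candidate family could be fitted")
    lam, w = akaike_weights([f.aic for f in fits])
    annotated = [
        TPCModelFit(
            family=f.family, params=f.params, k=f.k, rss=f.rss, n=f.n,
            aic=f.aic, r2=f.r2, level=f.level,
            lambda_i=float(li), w_i=float(wi),
        )
        for f, li, wi in zip(fits, lam, w)
    ]
    annotated.sort(key=lambda f: (f.aic, f.k, _FAMILY_ORDER.index(f.family)))
    return annotated


# ---------------------------------------------------------------------------
# Parameter extraction


def _t_opt(family: str, params: Sequence[float]) -> float:
    if family in ("gaussian", "lorentzian", "logistic_peak"):
        return float(params[1])
    # weibull_peak: mode is at b by construction, but locate numerically so the
    # extraction does not depend on the parameterisation detail.
    a, b, c, d = params
    res = minimize_scalar(
        lambda t: -evaluate_family(family, params, t),
        bracket=(b - abs(c), b, b + abs(c)),
        method="brent",
    )
    return float(res.x)


def extract_parameters(
    fit: TPCModelFit | tuple[str, Sequence[float]],
    epsilon: float = 0.05,
    *,
    method: str = "auto",
    max_width_factor: float = 200.0,
) -> TPCParams:
    """Extract ``T_opt``, ``V_max`` and the epsilon-level critical limits.

    ``ct_min``/``ct_max`` solve ``curve(T) = epsilon * v_max`` on either side
    of ``t_opt``.  Closed forms are used for the Gaussian
    (``b ± c·sqrt(-2 ln ε)``) and Lorentzian (``b ± c·sqrt(1/ε - 1)``) when
    ``method="auto"``; ``method="bisection"`` forces the numerical root finder
    for every family (the two agree to high precision; the numerical path
    brackets each root by stepping outward from ``t_opt`` in units of ``c`` up
    to ``max_width_factor`` widths).
    """
    if isinstance(fit, TPCModelFit):
        family, params = fit.family, fit.params
    else:
        family, params = fit
    if not 0.0 < epsilon < 1.0:
        raise ExtractionError(f"epsilon must be in (0, 1), got {epsilon}")
    if method not in ("auto", "bisection"):
        raise ValueError(f"unknown method {method!r}")

    t_opt = _t_opt(family, params)
    v_max = float(evaluate_family(family, params, t_opt))
    if v_max <= 0:
        raise ExtractionError("fitted curve has nonpositive maximum")
    c = abs(float(params[2]))

    if method == "auto" and family == "gaussian":
        half = c * math.sqrt(-2.0 * math.log(epsilon))
        return TPCParams(t_opt, v_max, t_opt - half, t_opt + half, epsilon)
    if method == "auto" and family == "lorentzian":
        half = c * math.sqrt(1.0 / epsilon - 1.0)
        return TPCParams(t_opt, v_max, t_opt - half, t_opt + half, epsilon)

    target = epsilon * v_max

    def g(t):
        return float(evaluate_family(family, params, t)) - target

    def root(direction: int) -> float:
        step = c
        t_far = t_opt + direction * step
        while g(t_far) > 0:
            step *= 2.0
            t_far = t_opt + direction * step
            if step > max_width_factor * c:
                raise ExtractionError(
                    f"no sign change within {max_width_factor} widths "
                    f"{'above' if direction > 0 else 'below'} t_opt"
                )
        lo, hi = (t_opt, t_far) if direction > 0 else (t_far, t_opt)
        return float(brentq(g, lo, hi, xtol=1e-10, rtol=1e-14))

    return TPCParams(t_opt, v_max, root(-1), root(+1), epsilon)


def tpc_breadth(params: TPCParams) -> float:
    """Thermal breadth: ``ct_max - ct_min`` (°C)."""
    return params.ct_max - params.ct_min
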
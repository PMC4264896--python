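"""Repeated-measures comparison of thermal traits across acclimation
treatments.

Each individual is measured once per acclimation temperature, so traits are
analysed with a linear mixed model: acclimation as a fixed 3-level factor,
random intercepts for individual and for measurement order, and (for traits
that scale with size) log10 body mass as a covariate.  Between-acclimation
differences are reported as 95% confidence intervals from the profile
likelihood of the contrast, with a seeded parametric bootstrap as fallback; an
"effect" is declared when the interval excludes zero.

Scale note: traits bounded away from 0 °C (T_pref, T_opt, V_max, CRT_max,
CT_max) are log10-transformed before analysis, so their contrasts are
differences of log10 means.  Cold limits (CRT_min, CT_min) cross 0 °C and are
analysed on the identity scale (an offset-log option exists).  The scale used
is recorded on every contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
import statsmodels.api as sm

from .errors import ConfigError, FitError

__all__ = [
    "ContrastCI",
    "TraitModel",
    "LOG10_TRAITS",
    "MASS_COVARIATE_TRAITS",
    "fit_trait_model",
    "acclimation_contrast",
    "summarize_traits",
    "trait_shift",
    "mass_trend",
]

#: Traits analysed on the log10 scale (strictly positive in °C or cm/s).
LOG10_TRAITS = frozenset({"t_pref", "t_opt", "v_max", "crt_max", "ct_max"})

#: Traits adjusted for log10 body mass by default.
MASS_COVARIATE_TRAITS = frozenset({"v_max", "crt_min"})

_CHI2_95_1DF = float(stats.chi2.ppf(0.95, 1))
_VAR_TOL = 1e-8


@dataclass(frozen=True)
class ContrastCI:
    """Estimated between-acclimation mean difference with its 95% interval."""

    trait: str
    pair: tuple[float, float]
    estimate: float
    ci_low: float
    ci_high: float
    scale: str
    method: str = "profile"

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("interval must bracket the estimate")

    @property
    def effect(self) -> bool:
        """True when the 95% interval excludes zero."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


def _canonical(trait: str) -> str:
    return trait.removesuffix("_c").removesuffix("_cm_s")


@dataclass
class TraitModel:
    """Handle to a fitted repeated-measures trait model.

    Holds the prepared analysis frame plus the random-effects structure that
    survived fitting (variance components estimated at zero are dropped with a
    warning, mirroring a boundary fit).
    """

    trait: str
    column: str
    scale: str
    levels: tuple[float, ...]
    y: np.ndarray
    acclimation: np.ndarray
    individual: np.ndarray
    order: np.ndarray | None
    mass_cov: np.ndarray | None
    components: tuple[str, ...]
    result: object
    llf: float
    degenerate: bool  # zero overall variance in y

    @property
    def variance_components(self) -> dict[str, float]:
        """Estimated variances for the retained random components."""
        if self.degenerate or self.result is None:
            return {c: 0.0 for c in self.components}
        out = {}
        res = self.result
        if isinstance(res.model, MixedLM):
            if self.components == ("individual",) and res.k_vc == 0:
                out["individual"] = float(np.asarray(res.cov_re)[0, 0])
            else:
                for name, v in zip(self.components, np.atleast_1d(res.vcomp)):
                    out[name] = float(v)
        return out

    @property
    def residual_variance(self) -> float:
        if self.degenerate or self.result is None:
            return 0.0
        return float(self.result.scale)


def _design(
    acclimation: np.ndarray,
    levels: tuple[float, ...],
    ref: float,
    mass_cov: np.ndarray | None,
    drop_level: float | None = None,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(acclimation))]
    names = ["intercept"]
    for lev in levels:
        if lev == ref or lev == drop_level:
            continue
        cols.append((acclimation == lev).astype(float))
        names.append(f"acclim[{lev}]")
    if mass_cov is not None:
        cols.append(mass_cov)
        names.append("log10_mass")
    return np.column_stack(cols), names


def _fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    individual: np.ndarray,
    order: np.ndarray | None,
    components: tuple[str, ...],
) -> tuple[object, float]:
    """ML fit with the requested random components; returns (result, llf)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if components == ():
            res = sm.OLS(y, X).fit()
            return res, float(res.llf)
        if components == ("individual",):
            model = MixedLM(y, X, groups=individual)
        elif components == ("order",):
            model = MixedLM(y, X, groups=order)
        else:
            mats, names = [], []
            for comp in components:
                codes = individual if comp == "individual" else order
                uniq = np.unique(codes)
                mats.append((codes[:, None] == uniq).astype(float))
                names.append([[f"{comp}{u}" for u in uniq]])
            spec = VCSpec(list(components), names, [[m] for m in mats])
            model = MixedLM(y, X, groups=np.zeros(len(y)), exog_vc=spec)
        res = model.fit(reml=False)
        return res, float(res.llf)


def fit_trait_model(
    records: pd.DataFrame,
    trait: str,
    *,
    mass_covariate: bool | None = None,
    include_order: bool = True,
    include_individual: bool = True,
    scale: str | None = None,
    log_offset: float = 0.0,
) -> TraitModel:
    """Fit the repeated-measures model for one trait.

    ``records`` needs columns ``individual_id``, ``acclimation_c``, the trait
    column, and optionally ``order`` (measurement occasion) and
    ``body_mass_g``.  ``scale`` defaults per trait (see module docstring);
    ``log_offset`` enables ``log10(x + offset)`` for cold limits if a log
    analysis is explicitly wanted.  ``mass_covariate=None`` means "by trait
    convention" (V_max and CRT_min adjusted, others not).
    """
    column = trait if trait in records.columns else f"{trait}_c"
    if column not in records.columns:
        raise ConfigError(f"trait column {trait!r} not found")
    canon = _canonical(trait)
    df = records.dropna(subset=[column]).copy()
    levels = tuple(sorted(df["acclimation_c"].unique()))
    if len(levels) < 2:
        raise ConfigError("need at least 2 acclimation levels")
    raw = df[column].to_numpy(float)
    if not np.isfinite(raw).all():
        raise ConfigError(f"non-finite values in {column}")

    if scale is None:
        scale = "log10" if canon in LOG10_TRAITS else "identity"
    if scale == "log10":
        vals = raw + log_offset
        if (vals <= 0).any():
            raise ConfigError(
                f"{trait}: log10 scale requested but values <= 0 present "
                "(use scale='identity' or a log_offset)"
            )
        y = np.log10(vals)
    elif scale == "identity":
        y = raw
    else:
        raise ConfigError(f"unknown scale {scale!r}")

    if mass_covariate is None:
        mass_covariate = canon in MASS_COVARIATE_TRAITS and "body_mass_g" in df
    mass_cov = None
    if mass_covariate:
        if "body_mass_g" not in df:
            raise ConfigError("mass covariate requested but body_mass_g missing")
        mass_cov = np.log10(df["body_mass_g"].to_numpy(float))

    individual = df["individual_id"].to_numpy()
    order = df["order"].to_numpy() if "order" in df else None
    acclimation = df["acclimation_c"].to_numpy(float)

    if np.ptp(y) < _VAR_TOL:
        return TraitModel(canon, column, scale, levels, y, acclimation,
                          individual, order, mass_cov, (), None, 0.0, True)

    components = []
    if include_individual:
        components.append("individual")
    if include_order and order is not None and len(np.unique(order)) > 1:
        components.append("order")
    components = tuple(components)

    X, _ = _design(acclimation, levels, levels[0], mass_cov)
    res, llf = _fit_lmm(y, X, individual, order, components)
    # Drop variance components estimated on the zero boundary and refit:
    # a degenerate component contributes nothing but destabilises profiles.
    if components and isinstance(res.model, MixedLM):
        var_y = float(np.var(y))
        est = dict(zip(components, np.atleast_1d(res.vcomp))) if res.k_vc else {
            components[0]: float(np.asarray(res.cov_re)[0, 0])
        }
        kept = tuple(c for c in components if est.get(c, 0.0) > _VAR_TOL * var_y)
        if kept != components:
            warnings.warn(
                f"{canon}: variance component(s) "
                f"{sorted(set(components) - set(kept))} estimated at zero; "
                "refitting without them",
                stacklevel=2,
            )
            res, llf = _fit_lmm(y, X, individual, order, kept)
            components = kept

    return TraitModel(canon, column, scale, levels, y, acclimation,
                      individual, order, mass_cov, components, res, llf, False)


def _contrast_fit(model: TraitModel, pair, theta: float | None):
    """ML fit with reference level pair[0].

    ``theta=None``: free fit, returns (llf, estimate of pair[1] coef, SE).
    Otherwise the pair[1] coefficient is fixed at ``theta`` (absorbed into the
    response) and the profiled llf is returned.
    """
    ref, to = pair
    if theta is None:
        X, names = _design(model.acclimation, model.levels, ref, model.mass_cov)
        res, llf = _fit_lmm(model.y, X, model.individual, model.order,
                            model.components)
        j = names.index(f"acclim[{to}]")
        return llf, float(res.params[j]), float(res.bse[j])
    x_to = (model.acclimation == to).astype(float)
    X, _ = _design(model.acclimation, model.levels, ref, model.mass_cov,
                   drop_level=to)
    _, llf = _fit_lmm(model.y - theta * x_to, X, model.individual, model.order,
                      model.components)
    return llf


def _bootstrap_ci(model, pair, estimate, n_boot, seed):
    """Parametric bootstrap of the contrast: simulate from the fitted model,
    refit, take percentile bounds."""
    rng = np.random.default_rng(seed)
    vc = model.variance_components
    sd_resid = np.sqrt(model.residual_variance)
    ref, to = pair
    X, names = _design(model.acclimation, model.levels, ref, model.mass_cov)
    j = names.index(f"acclim[{to}]")
    beta_res, _ = _fit_lmm(model.y, X, model.individual, model.order,
                           model.components)
    mu = X @ np.asarray(beta_res.fe_params if hasattr(beta_res, "fe_params")
                        else beta_res.params[: X.shape[1]])
    draws = []
    ind_levels = np.unique(model.individual)
    ord_levels = np.unique(model.order) if model.order is not None else None
    for _ in range(n_boot):
        y_star = mu + rng.normal(0.0, sd_resid, len(mu))
        if "individual" in vc:
            u = rng.normal(0.0, np.sqrt(vc["individual"]), len(ind_levels))
            y_star = y_star + u[np.searchsorted(ind_levels, model.individual)]
        if "order" in vc and ord_levels is not None:
            u = rng.normal(0.0, np.sqrt(vc["order"]), len(ord_levels))
            y_star = y_star + u[np.searchsorted(ord_levels, model.order)]
        try:
            boot_res, _ = _fit_lmm(y_star, X, model.individual, model.order,
                                   model.components)
            draws.append(float(boot_res.params[j]))
        except Exception:
            continue
    if len(draws) < max(50, n_boot // 4):
        raise FitError("bootstrap fallback failed to produce enough fits")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(min(lo, estimate)), float(max(hi, estimate))


def acclimation_contrast(
    model: TraitModel,
    pair: tuple[float, float],
    *,
    method: str = "profile",
    n_boot: int = 1000,
    seed: int = 0,
) -> ContrastCI:
    """Mean difference ``pair[1] - pair[0]`` on the analysis scale, with 95% CI.

    ``method='profile'`` inverts the likelihood-ratio test by profiling the
    contrast coefficient (chi-square threshold, 1 df), falling back to a
    seeded parametric bootstrap if a profile bound cannot be bracketed;
    ``'wald'`` and ``'bootstrap'`` select those intervals directly.
    """
    a, b = pair
    for lev in pair:
        if lev not in model.levels:
            raise ConfigError(f"acclimation level {lev} not in fitted model")
    if a == b:
        raise ConfigError("contrast requires two distinct levels")
    if model.degenerate:
        return ContrastCI(model.trait, pair, 0.0, 0.0, 0.0, model.scale,
                          "degenerate")

    llf_hat, estimate, se = _contrast_fit(model, pair, None)
    if model.result is not None and getattr(model.result, "scale", 1.0) < _VAR_TOL:
        return ContrastCI(model.trait, pair, estimate, estimate, estimate,
                          model.scale, "degenerate")

    if method == "wald":
        z = stats.norm.ppf(0.975)
        return ContrastCI(model.trait, pair, estimate,
                          estimate - z * se, estimate + z * se,
                          model.scale, "wald")
    if method == "bootstrap":
        lo, hi = _bootstrap_ci(model, pair, estimate, n_boot, seed)
        return ContrastCI(model.trait, pair, estimate, lo, hi, model.scale,
                          "bootstrap")
    if method != "profile":
        raise ConfigError(f"unknown CI method {method!r}")

    def deviance(theta):
        return 2.0 * (llf_hat - _contrast_fit(model, pair, theta)) - _CHI2_95_1DF

    def bound(direction: int) -> float:
        t = 2.2  # just past the Wald 1.96, in SE units
        lo_t = 0.0
        while True:
            theta = estimate + direction * t * se
            if deviance(theta) > 0:
                break
            lo_t = t
            t *= 1.7
            if t > 16.0:
                raise FitError("profile bound not bracketed")
        f = lambda tt: deviance(estimate + direction * tt * se)
        t_star = brentq(f, lo_t if lo_t > 0 else 1e-6, t, xtol=0.02)
        return estimate + direction * t_star * se

    try:
        lo, hi = bound(-1), bound(+1)
        return ContrastCI(model.trait, pair, estimate, lo, hi, model.scale,
                          "profile")
    except (FitError, ValueError) as exc:
        warnings.warn(
            f"profile CI failed for {model.trait} {pair} ({exc}); "
            "using parametric bootstrap fallback",
            stacklevel=2,
        )
        lo, hi = _bootstrap_ci(model, pair, estimate, n_boot, seed)
        return ContrastCI(model.trait, pair, estimate, lo, hi, model.scale,
                          "bootstrap")


# ---------------------------------------------------------------------------
# Summaries


_SUMMARY_ORDER = ("crt_min", "ct_min", "t_pref", "t_opt", "ct_max", "crt_max",
                  "v_max")


def summarize_traits(
    records: pd.DataFrame,
    params: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean ± SD summary per acclimation x trait.

    ``records`` is the tolerance table (CRT_min, CRT_max, T_pref);
    ``params``, if given, adds the curve-derived traits (CT_min, T_opt,
    CT_max, V_max) per individual.  SD is reported as NaN for single records
    (missing, not zero).  Output columns: trait, acclimation_c, mean, sd, n.
    """
    frames = [records] if params is None else [records, params]
    rows = []
    for df in frames:
        if df is None or df.empty:
            continue
        trait_cols = [
            c for c in df.columns
            if _canonical(c) in _SUMMARY_ORDER
        ]
        for col in trait_cols:
            grp = df.groupby("acclimation_c")[col]
            for acc, g in grp:
                rows.append({
                    "trait": _canonical(col),
                    "acclimation_c": float(acc),
                    "mean": float(g.mean()),
                    "sd": float(g.std(ddof=1)) if len(g) > 1 else float("nan"),
                    "n": int(len(g)),
                })
    if not rows:
        raise ConfigError("no recognised trait columns in input")
    out = pd.DataFrame(rows)
    out["trait"] = pd.Categorical(out["trait"], categories=_SUMMARY_ORDER,
                                  ordered=True)
    return out.sort_values(["trait", "acclimation_c"]).reset_index(drop=True)


def trait_shift(
    summary: pd.DataFrame, trait: str, acc_from: float, acc_to: float
) -> float:
    """Difference of summary means: mean(trait at acc_to) - mean(at acc_from)."""
    sel = summary[summary["trait"] == _canonical(trait)]
    means = dict(zip(sel["acclimation_c"], sel["mean"]))
    try:
        return means[acc_to] - means[acc_from]
    except KeyError as exc:
        raise ConfigError(f"acclimation {exc} missing from summary") from exc


def mass_trend(records: pd.DataFrame) -> ContrastCI:
    """Slope of log10 body mass against measurement occasion, with 95% CI.

    A health check: a healthy colony shows no systematic mass trend over the
    serial acclimations.  Fits log10(mass) ~ occasion with a random intercept
    per individual; the occasion variable is the ``order`` column.
    """
    if "order" not in records or "body_mass_g" not in records:
        raise ConfigError("mass_trend needs 'order' and 'body_mass_g' columns")
    df = records.dropna(subset=["body_mass_g"]).copy()
    counts = df.groupby("individual_id")["order"].nunique()
    if (counts < 3).all():
        raise ConfigError("need >= 3 measurement occasions per individual")
    y = np.log10(df["body_mass_g"].to_numpy(float))
    occ = df["order"].to_numpy(float)
    ind = df["individual_id"].to_numpy()

    # Exact path when mass follows a deterministic per-individual trend:
    # individual dummies + occasion explain everything.
    uniq = np.unique(ind)
    D = (ind[:, None] == uniq).astype(float)
    Xfull = np.column_stack([D, occ])
    beta, rss, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    resid = y - Xfull @ beta
    if float(resid @ resid) < 1e-16 * max(1.0, float(y @ y)):
        slope = float(beta[-1])
        return ContrastCI("log10_body_mass", (occ.min(), occ.max()),
                          slope, slope, slope, "log10", "degenerate")

    X = np.column_stack([np.ones(len(y)), occ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(y, X, groups=ind).fit(reml=False)
    slope, se = float(res.params[1]), float(res.bse[1])
    z = stats.norm.ppf(0.975)
    return ContrastCI("log10_body_mass", (occ.min(), occ.max()), slope,
                      slope - z * se, slope + z * se, "log10", "wald")
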
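"""Synthetic study-data generator.

Emulates the four data products of an acclimation study on a small desert-pond
frog population: (1) jump-speed performance trials across test temperatures
under three acclimation treatments, (2) thermal tolerance/preference records
per individual x acclimation, (3) operative-temperature (T_e) logger series
from agar frog models deployed in sun/shade x wet/dry patches at two ponds,
and (4) dorsal-vs-cloacal body-temperature calibration pairs.

Defaults reproduce the study design: 31 individuals, acclimations at
10/20/25 °C measured in series (measurement order = acclimation order), two
trials per test temperature, Gaussian population curves whose peaks and
heights sit at the reported per-acclimation T_opt and V_max, diurnal T_e
cycles in which sun patches run ~8 °C hotter in daytime mean and ~11 °C hotter
at the maximum than shade, and wet patches losing water more slowly than dry.

Every generator is a pure function of a :class:`SynthConfig`; the seed fully
determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tpc import FAMILIES, evaluate_family

__all__ = [
    "PatchParams",
    "TraitMoments",
    "SynthConfig",
    "generate_performance",
    "generate_tolerance",
    "generate_te_series",
    "generate_calibration",
    "write_inputs",
    "DEFAULT_TEST_TEMPERATURES",
    "DEFAULT_POPULATION_PARAMS",
    "DEFAULT_TOLERANCE_MOMENTS",
    "DEFAULT_PATCH_PARAMS",
]

#: Test temperatures per acclimation treatment (°C).  Warmer acclimations were
#: probed further up the scale so the descending limb is captured.
DEFAULT_TEST_TEMPERATURES: dict[float, tuple[float, ...]] = {
    10.0: (5, 10, 20, 26, 29),
    20.0: (5, 10, 20, 26, 29, 32),
    25.0: (5, 10, 20, 26, 29, 32, 36),
}

#: Gaussian population parameters (a = V_max cm/s, b = T_opt °C, c = width °C)
#: per acclimation.  a and b are the reported trait means; c is set so that the
#: 5%-of-maximum upper limit falls at the reported CT_max.
DEFAULT_POPULATION_PARAMS: dict[float, tuple[float, ...]] = {
    10.0: (8.46, 22.68, 4.0),
    20.0: (9.57, 25.98, 3.5),
    25.0: (11.41, 26.37, 4.1),
}


@dataclass(frozen=True)
class TraitMoments:
    """Mean/SD (°C) of one tolerance trait under each acclimation."""

    mean: dict[float, float]
    sd: dict[float, float]


#: Tolerance/preference trait moments per acclimation (°C): critical
#: resistance limits (loss of righting response) and preferred temperature.
DEFAULT_TOLERANCE_MOMENTS: dict[str, TraitMoments] = {
    "crt_min": TraitMoments(
        mean={10.0: 1.16, 20.0: -0.24, 25.0: 0.00},
        sd={10.0: 0.90, 20.0: 1.15, 25.0: 1.39},
    ),
    "t_pref": TraitMoments(
        mean={10.0: 20.93, 20.0: 21.17, 25.0: 23.17},
        sd={10.0: 4.62, 20.0: 5.88, 25.0: 6.03},
    ),
    "crt_max": TraitMoments(
        mean={10.0: 36.73, 20.0: 40.37, 25.0: 41.14},
        sd={10.0: 1.62, 20.0: 2.83, 25.0: 1.81},
    ),
}


@dataclass(frozen=True)
class PatchParams:
    """Clipped-sinusoid diurnal cycle for one patch (°C, h).

    Temperature sits at ``night_min`` outside the warm window and follows a
    half-cosine bump peaking at ``day_peak`` at ``peak_hour``; ``half_width``
    is the half-duration of the warm window.
    """

    night_min: float
    day_peak: float
    peak_hour: float = 14.0
    noise_sd: float = 0.3
    half_width: float = 7.0


#: Patch diurnal parameters chosen so that, over the 07:00-20:00 window, the
#: mean sun-shade gap is ~7.8 °C and the maximum gap ~11 °C.
DEFAULT_PATCH_PARAMS: dict[tuple[str, str], PatchParams] = {
    ("shade", "wet"): PatchParams(night_min=8.0, day_peak=21.6),
    ("shade", "dry"): PatchParams(night_min=8.0, day_peak=22.0),
    ("sun", "wet"): PatchParams(night_min=9.0, day_peak=32.0),
    ("sun", "dry"): PatchParams(night_min=9.0, day_peak=33.2),
}

#: Water-loss rate (g/h) = base + dry increment + sun increment, matching the
#: reported main-effect magnitudes.
_LOSS_BASE_G_H = 0.30
_LOSS_DRY_G_H = 0.686
_LOSS_SUN_G_H = 0.403

_CAL_TEMPS = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class SynthConfig:
    """Full configuration of the synthetic study.

    ``individual_sd`` is the relative SD of per-individual curve parameters
    around the population values (one latent deviate per parameter per
    individual, shared across acclimations, so repeated measures on the same
    frog are correlated).  ``noise_sd`` is the SD of multiplicative log-normal
    trial noise.  The within-individual repeatability of jump speed is not an
    observable of the emulated study, so ``individual_sd`` is a free knob.
    """

    n_individuals: int = 31
    acclimations: tuple[float, ...] = (10.0, 20.0, 25.0)
    test_temperatures: dict[float, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TEST_TEMPERATURES)
    )
    generating_family: str = "gaussian"
    population_params: dict[float, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_PARAMS)
    )
    individual_sd: float = 0.10
    noise_sd: float = 0.10
    tolerance_moments: dict[str, TraitMoments] = field(
        default_factory=lambda: dict(DEFAULT_TOLERANCE_MOMENTS)
    )
    te_patch_params: dict[tuple[str, str], PatchParams] = field(
        default_factory=lambda: dict(DEFAULT_PATCH_PARAMS)
    )
    te_date: str = "2013-10-15"
    #: SD (°C) of a constant per-model microsite offset (pond/placement
    #: differences between replicate models of the same patch); suppressed
    #: when a patch's noise_sd is zero so noiseless runs stay deterministic.
    patch_model_sd: float = 0.7
    model_mass_g: float = 50.0
    deployment_hours: float = 13.0
    calibration_noise_shared: float = 0.25
    calibration_noise_indep: float = 0.15
    calibration_bias: float = 0.0
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        for name in ("individual_sd", "noise_sd",
                     "calibration_noise_shared", "calibration_noise_indep"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.generating_family not in FAMILIES:
            raise ConfigError(
                f"unknown generating family {self.generating_family!r}"
            )
        for acc in self.acclimations:
            temps = self.test_temperatures.get(acc)
            if temps is None or len(temps) < 4:
                raise ConfigError(
                    f"acclimation {acc} needs >= 4 test temperatures"
                )
            if acc not in self.population_params:
                raise ConfigError(f"no population params for acclimation {acc}")
            if len(self.population_params[acc]) != FAMILIES[self.generating_family]:
                raise ConfigError(
                    f"population params for {acc} do not match "
                    f"{self.generating_family} arity"
                )
        for trait, mom in self.tolerance_moments.items():
            for acc in self.acclimations:
                if acc not in mom.mean or acc not in mom.sd:
                    raise ConfigError(f"{trait} moments missing acclimation {acc}")
                if mom.sd[acc] < 0:
                    raise ConfigError(f"{trait} SD must be >= 0")
        for acc in self.acclimations:
            lo = self.tolerance_moments["crt_min"].mean[acc]
            mid = self.tolerance_moments["t_pref"].mean[acc]
            hi = self.tolerance_moments["crt_max"].mean[acc]
            if not lo < mid < hi:
                raise ConfigError(
                    f"tolerance means must order crt_min < t_pref < crt_max "
                    f"at acclimation {acc}: {lo}, {mid}, {hi}"
                )
        for p in self.te_patch_params.values():
            if p.noise_sd < 0:
                raise ConfigError("patch noise_sd must be >= 0")
        return self

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # Independent stream per generator so each output depends only on the seed,
    # not on which other generators were called.
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


def _body(config: SynthConfig, rng: np.random.Generator):
    """Per-individual body length (mm) and mass (g) for a small frog."""
    length = rng.normal(42.0, 4.0, config.n_individuals).clip(min=25.0)
    mass = np.exp(rng.normal(np.log(3.2), 0.18, config.n_individuals))
    return length, mass


def generate_performance(config: SynthConfig) -> pd.DataFrame:
    """Jump-speed trials: two per individual x acclimation x test temperature.

    Each individual's curve parameters are the population parameters scaled by
    ``1 + individual_sd * z`` (one standard-normal ``z`` per parameter per
    individual, shared across acclimations); each trial speed is the
    individual's curve value times ``exp(eps)`` with
    ``eps ~ N(0, noise_sd^2)``.

    Columns: individual_id, acclimation_c, order, test_temp_c, trial_index,
    speed_cm_s, body_length_mm, body_mass_g.
    """
    config.validate()
    rng = _rng(config, 1)
    length, mass = _body(config, rng)
    n_par = FAMILIES[config.generating_family]
    z = rng.normal(0.0, 1.0, size=(config.n_individuals, n_par))
    rows = []
    for order, acc in enumerate(config.acclimations, start=1):
        pop = np.asarray(config.population_params[acc], float)
        for i in range(config.n_individuals):
            par = pop * (1.0 + config.individual_sd * z[i])
            # keep widths/heights physical if an extreme deviate flips a sign
            par[0] = max(par[0], 0.05 * pop[0])
            par[2] = max(par[2], 0.05 * pop[2])
            for t in config.test_temperatures[acc]:
                mu = float(evaluate_family(config.generating_family, par, t))
                for trial in (1, 2):
                    eps = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
                    rows.append({
                        "individual_id": f"frog{i + 1:02d}",
                        "acclimation_c": float(acc),
                        "order": order,
                        "test_temp_c": float(t),
                        "trial_index": trial,
                        "speed_cm_s": mu * np.exp(eps),
                        "body_length_mm": round(float(length[i]), 2),
                        "body_mass_g": round(float(mass[i]), 3),
                    })
    return pd.DataFrame(rows)


def generate_tolerance(config: SynthConfig, n_individuals: int | None = None) -> pd.DataFrame:
    """Tolerance records per individual x acclimation.

    CRT_min, CRT_max (ramping loss-of-righting endpoints) and T_pref are drawn
    normally around the configured per-acclimation means; draws violating
    CRT_min < T_pref < CRT_max are rejected and redrawn, so the physiological
    ordering always holds.

    Columns: individual_id, acclimation_c, order, crt_min_c, crt_max_c,
    t_pref_c, body_mass_g.
    """
    config.validate()
    n = config.n_individuals if n_individuals is None else int(n_individuals)
    rng = _rng(config, 2)
    _, mass = _body(config, rng)
    if n != config.n_individuals:
        mass = np.exp(rng.normal(np.log(3.2), 0.18, n))
    mom = config.tolerance_moments
    rows = []
    for order, acc in enumerate(config.acclimations, start=1):
        for i in range(n):
            for _attempt in range(1000):
                lo = rng.normal(mom["crt_min"].mean[acc], mom["crt_min"].sd[acc])
                pref = rng.normal(mom["t_pref"].mean[acc], mom["t_pref"].sd[acc])
                hi = rng.normal(mom["crt_max"].mean[acc], mom["crt_max"].sd[acc])
                if lo < pref < hi:
                    break
            else:  # pragma: no cover - unreachable with sane moments
                raise ConfigError("could not draw an ordered tolerance record")
            # small per-occasion fluctuation (feeding/hydration state) so the
            # colony-health mass trend is a real, noisy near-zero slope
            mass_ij = mass[i] * 10.0 ** rng.normal(0.0, 0.008)
            rows.append({
                "individual_id": f"frog{i + 1:02d}",
                "acclimation_c": float(acc),
                "order": order,
                "crt_min_c": lo,
                "crt_max_c": hi,
                "t_pref_c": pref,
                "body_mass_g": round(float(mass_ij), 3),
            })
    return pd.DataFrame(rows)


def _diurnal(p: PatchParams, hours: np.ndarray) -> np.ndarray:
    phase = np.abs(hours - p.peak_hour)
    shape = np.where(
        phase <= p.half_width,
        np.cos(np.pi * (hours - p.peak_hour) / (2.0 * p.half_width)),
        0.0,
    )
    return p.night_min + (p.day_peak - p.night_min) * shape


def generate_te_series(config: SynthConfig) -> pd.DataFrame:
    """Operative-temperature logger table: 24 h of 5-min samples per model.

    Two replicate agar models per sun/shade x wet/dry combination (one per
    pond), eight models in all.  Temperatures follow the patch's clipped
    sinusoid plus Gaussian noise.  Model masses before/after a fixed daytime
    deployment are emitted so that water loss is faster in dry and sun patches.

    Columns: model_id, pond, exposure, moisture, timestamp, temp_c,
    mass_before_g, mass_after_g, deployment_hours.
    """
    config.validate()
    required = {(e, m) for e in ("sun", "shade") for m in ("wet", "dry")}
    missing = required - set(config.te_patch_params)
    if missing:
        raise ConfigError(f"missing patch combinations: {sorted(missing)}")
    rng = _rng(config, 3)
    hours = np.arange(288) * 5.0 / 60.0
    stamps = pd.date_range(config.te_date, periods=288, freq="5min")
    rows = []
    model_no = 0
    for (exposure, moisture) in sorted(config.te_patch_params):
        p = config.te_patch_params[(exposure, moisture)]
        base = _diurnal(p, hours)
        for pond in ("pond1", "pond2"):
            model_no += 1
            if p.noise_sd:
                offset = rng.normal(0.0, config.patch_model_sd)
                noise = rng.normal(0.0, p.noise_sd, 288)
            else:
                offset = 0.0
                noise = np.zeros(288)
            temp = base + offset + noise
            rate = (
                _LOSS_BASE_G_H
                + (_LOSS_DRY_G_H if moisture == "dry" else 0.0)
                + (_LOSS_SUN_G_H if exposure == "sun" else 0.0)
                + (rng.normal(0.0, 0.05) if p.noise_sd else 0.0)
            )
            mass_before = config.model_mass_g
            mass_after = mass_before - rate * config.deployment_hours
            mid = f"model{model_no}"
            for ts, tc in zip(stamps, temp):
                rows.append({
                    "model_id": mid,
                    "pond": pond,
                    "exposure": exposure,
                    "moisture": moisture,
                    "timestamp": ts.isoformat(),
                    "temp_c": float(tc),
                    "mass_before_g": round(mass_before, 2),
                    "mass_after_g": round(float(mass_after), 2),
                    "deployment_hours": config.deployment_hours,
                })
    return pd.DataFrame(rows)


def generate_calibration(config: SynthConfig) -> pd.DataFrame:
    """Dorsal/cloacal body-temperature pairs across chamber temperatures.

    At each chamber setting both readings equal the chamber temperature plus
    correlated noise (a shared equilibration deviate plus independent
    instrument noise); ``calibration_bias`` offsets the dorsal reading.

    Columns: chamber_t_c, dorsal_tb_c, cloacal_tb_c, n_individuals.
    """
    config.validate()
    rng = _rng(config, 4)
    rows = []
    for t in _CAL_TEMPS:
        n_ind = int(rng.integers(5, 12))
        shared = rng.normal(0.0, config.calibration_noise_shared)
        cloacal = t + shared + rng.normal(0.0, config.calibration_noise_indep)
        dorsal = (
            t + config.calibration_bias + shared
            + rng.normal(0.0, config.calibration_noise_indep)
        )
        rows.append({
            "chamber_t_c": t,
            "dorsal_tb_c": dorsal,
            "cloacal_tb_c": cloacal,
            "n_individuals": n_ind,
        })
    return pd.DataFrame(rows)


def write_inputs(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the four input CSVs (performance, tolerance, te_series,
    calibration) and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "performance": generate_performance(config),
        "tolerance": generate_tolerance(config),
        "te_series": generate_te_series(config),
        "calibration": generate_calibration(config),
    }
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
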
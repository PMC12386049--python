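"""Synthetic kinetic datasets and compound tables.

No raw kinetic data ship with the study this package operationalises, so the
generator emulates the experimental design: a 2 temperature × 3 enzyme-level
ultrasound arm sampled at 8 front-loaded time points (48 runs), triplicate
measurements with replicate SDs in the 0.002–0.150 mg/g range, and
phenomenological (De, plateau-yield) maps reproducing the qualitative
structure of the fitted diffusivities — De rises with enzyme dose at fixed
temperature, falls from 40 °C to 50 °C, while the plateau yield is higher at
50 °C.  Mean curves come from the spherical-diffusion forward model, so the
generator/fitter loop closes by construction.

Compound tables mimic the 17-compound × 6-condition quantification schema
(4 categories, means spanning ~1–900 µg/g, structured missingness) with a
configurable temperature-contrast effect size so that PCA separation is
testable under both the null and a strong signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffusion import DiffusionParams, ParticleSpec, SuspensionSpec, solve_extraction, yield_curve
from .fitting import KineticDataset

__all__ = [
    "GeneratorConfig",
    "make_design",
    "default_truth",
    "simulate_kinetics",
    "simulate_compound_table",
]

#: half-extraction Fourier number for a sphere in a bath with alpha ~ 10;
#: sets the absolute time scale of the default rate maps
_TAU_HALF = 0.026

CATEGORIES = ("phenolic acid", "dihydrochalcone", "flavanol", "flavonol")


@dataclass(frozen=True)
class GeneratorConfig:
    """Design and noise settings for the kinetic generator.

    Defaults reproduce the 48-run ultrasound design: 2 temperatures × 3
    enzyme levels × 8 front-loaded sampling times, triplicates, replicate SD
    drawn uniformly from [0.002, 0.150] mg/g.  ``noise_sd`` may also be a
    single float for homoscedastic noise.
    """

    temperatures: tuple[float, ...] = (40.0, 50.0)
    enzyme_levels: tuple[float, ...] = (0.0, 0.5, 1.0)
    methods: tuple[str, ...] = ("US",)
    time_points_min: tuple[float, ...] = (2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0)
    noise_sd: float | tuple[float, float] = (0.002, 0.150)
    n_reps: int = 3
    seed: int = 0
    particle: ParticleSpec = field(default_factory=ParticleSpec)
    suspension: SuspensionSpec = field(default_factory=SuspensionSpec)
    rate_map: dict | None = None  # optional {(T, E, method): De/r² per min}
    equilibrium_map: dict | None = None  # optional {(T, E, method): plateau mg/g}

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (self.temperatures and self.enzyme_levels and self.methods and self.time_points_min):
            raise ValueError("factor lists must be nonempty")

    def sd_bounds(self) -> tuple[float, float]:
        if isinstance(self.noise_sd, (int, float)):
            return (float(self.noise_sd), float(self.noise_sd))
        lo, hi = self.noise_sd
        return (float(lo), float(hi))


def make_design(config: GeneratorConfig) -> pd.DataFrame:
    """Full-factorial condition/time grid with stable ordering."""
    rows = [
        (t, e, m, tp)
        for t in config.temperatures
        for e in config.enzyme_levels
        for m in config.methods
        for tp in config.time_points_min
    ]
    return pd.DataFrame(rows, columns=["temperature_C", "enzyme_pct", "method", "time_min"])


def _default_rate(temperature: float, enzyme: float, method: str) -> float:
    """Dimensionless diffusion rate De/r² (1/min).

    Calibrated so half-extraction falls within 2–10 min: rises with enzyme
    dose, falls with temperature, and is slower for magnetic stirring.
    """
    base = 0.008 * math.exp(-0.06 * (temperature - 40.0))
    enz = 1.0 + 0.55 * enzyme
    meth = 1.0 if method == "US" else 0.62
    return base * enz * meth


def _default_equilibrium(temperature: float, enzyme: float, method: str) -> float:
    """Plateau yield in mg GAE/g: strongly higher at 50 °C, weakly increasing
    with enzyme dose, lower without ultrasound."""
    base = 2.3 + 1.9 * (temperature - 40.0) / 10.0
    enz = 1.0 + 0.05 * enzyme
    meth = 1.0 if method == "US" else 0.85
    return base * enz * meth


def default_truth(config: GeneratorConfig) -> dict[tuple, dict[str, float]]:
    """Per-condition ground truth: diffusion rate, De, plateau yield, and the
    implied extractable content (plateau × (1+α)/α for the finite bath)."""
    alpha = config.suspension.alpha(1.0)
    truth: dict[tuple, dict[str, float]] = {}
    for t in config.temperatures:
        for e in config.enzyme_levels:
            for m in config.methods:
                key = (t, e, m)
                rate = (config.rate_map or {}).get(key, _default_rate(t, e, m))
                eq = (config.equilibrium_map or {}).get(key, _default_equilibrium(t, e, m))
                truth[key] = {
                    "rate_per_min": rate,
                    "De_m2_per_s": rate * config.particle.radius_m**2 / 60.0,
                    "equilibrium_yield_mg_per_g": eq,
                    "extractable_mg_per_g": eq * (1.0 + alpha) / alpha,
                }
    return truth


def simulate_kinetics(config: GeneratorConfig) -> tuple[KineticDataset, dict]:
    """Generate the kinetic dataset (per-point replicate mean ± SD) and the
    ground-truth record used to produce it.

    Mean curves come from the forward diffusion model at the truth
    parameters; each replicate adds Gaussian noise (truncated at zero yield)
    with a per-point SD drawn from the configured range.
    """
    rng = np.random.default_rng(config.seed)
    truth = default_truth(config)
    lo, hi = config.sd_bounds()
    times = np.concatenate(([0.0], np.asarray(config.time_points_min, dtype=float)))
    rows = []
    for t in config.temperatures:
        for e in config.enzyme_levels:
            for m in config.methods:
                info = truth[(t, e, m)]
                Cs0 = info["extractable_mg_per_g"] / 1000.0 * config.suspension.solid_density_g_cm3
                params = DiffusionParams.from_rate(info["rate_per_min"], config.particle, Cs0=Cs0)
                prof = solve_extraction(params, config.particle, config.suspension, times)
                curve = yield_curve(prof, config.suspension)[1:]
                sds = rng.uniform(lo, hi, size=curve.size)
                reps = rng.normal(curve[:, None], sds[:, None], size=(curve.size, config.n_reps))
                reps = np.clip(reps, 0.0, None)
                # the SD column reports the generating (true) per-point SD so
                # that it stays within the design's stated 0.002-0.150 range;
                # a 3-sample SD would scatter far outside it
                for tp, mean, sd in zip(config.time_points_min, reps.mean(axis=1), sds):
                    rows.append((t, e, m, tp, mean, sd, config.n_reps))
    frame = pd.DataFrame(
        rows,
        columns=["temperature_C", "enzyme_pct", "method", "time_min",
                 "yield_mg_per_g", "sd_mg_per_g", "n_reps"],
    )
    truth_record = {
        "seed": config.seed,
        "time_points_min": list(config.time_points_min),
        "noise_sd": list(config.sd_bounds()),
        "conditions": {f"{k[0]:g}C|{k[1]:g}%|{k[2]}": v for k, v in truth.items()},
    }
    return KineticDataset(frame), truth_record


# ---------------------------------------------------------------------------
# compound tables

_CONDITION_LABELS = ("40C-NE", "40C-0.5%", "40C-1%", "50C-NE", "50C-0.5%", "50C-1%")


def simulate_compound_table(
    seed: int,
    n_compounds: int = 17,
    effect_size: float = 1.0,
    n_missing: int = 2,
) -> pd.DataFrame:
    """Random compound-quantification table with the 6-condition schema.

    ``effect_size`` scales a temperature-contrast (40 °C vs 50 °C) injected
    into every compound's condition means; at 0 the conditions share one mean
    and any PCA separation is pure noise, at large values the contrast
    dominates the first principal component.  ``n_missing`` compounds are
    marked missing in all 40 °C conditions (mirroring rutin-like behaviour).

    Returns a frame in the same layout the compound-table reader accepts.
    """
    rng = np.random.default_rng(seed)
    n_cat = len(CATEGORIES)
    # category sizes echo the real table (9/2/3/3 at 17 compounds), scaled
    base_sizes = np.array([9, 2, 3, 3], dtype=float) * n_compounds / 17.0
    sizes = np.maximum(1, np.floor(base_sizes).astype(int))
    while sizes.sum() < n_compounds:
        sizes[int(rng.integers(n_cat))] += 1
    while sizes.sum() > n_compounds:
        sizes[int(sizes.argmax())] -= 1
    categories = [c for c, s in zip(CATEGORIES, sizes) for _ in range(s)]
    names = [f"compound_{i + 1:02d}" for i in range(n_compounds)]
    rt = np.sort(rng.uniform(10.0, 55.0, size=n_compounds))

    base = 10.0 ** rng.uniform(0.5, 2.8, size=n_compounds)  # ~3–630 µg/g
    direction = rng.normal(0.0, 1.0, size=n_compounds)
    group = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]) - 0.5  # 40 °C vs 50 °C
    jitter = rng.normal(0.0, 0.10, size=(n_compounds, 6))
    log_means = (np.log(base)[:, None]
                 + effect_size * direction[:, None] * group[None, :]
                 + jitter)
    means = np.exp(log_means)
    sds = means * rng.uniform(0.02, 0.08, size=means.shape)

    missing_rows = rng.choice(n_compounds, size=min(n_missing, n_compounds), replace=False)
    data = {"category": categories, "compound": names, "rt_min": np.round(rt, 2)}
    for j, label in enumerate(_CONDITION_LABELS):
        col_mean = np.round(means[:, j], 2).astype(object)
        col_sd = np.round(sds[:, j], 2).astype(object)
        if label.startswith("40C"):
            for i in missing_rows:
                col_mean[i] = np.nan
                col_sd[i] = np.nan
        data[f"mean:{label}"] = col_mean
        data[f"sd:{label}"] = col_sd
    return pd.DataFrame(data)
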
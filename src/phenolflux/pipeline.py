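"""End-to-end orchestration: De fitting → ANFIS → compositional analytics.

One validated configuration drives the whole analysis.  A single top-level
seed deterministically derives per-stage seeds, every defaulted field is
echoed into ``manifest.json``, stages communicate only through files in the
output directory, and all figures are regenerable from the persisted CSVs.
"""

from __future__ import annotations

import json
import logging
import platform
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .anfis import evaluate, grid_partition_init, response_surface, split_dataset, train_hybrid
from .composition import (
    category_summary,
    expand_replicates,
    pca_autoscaled,
    read_compound_table,
)
from .diffusion import DiffusionParams, ParticleSpec, SuspensionSpec, solve_extraction, yield_curve
from .fitting import KineticDataset, fit_all_conditions
from .synthetic import GeneratorConfig, default_truth, simulate_kinetics
from . import plotting

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("phenolflux")

ANFIS_FEATURES = ["temperature_C", "time_min", "enzyme_pct"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


class ParticleConfig(BaseModel):
    radius_um: float = 24.50


class SuspensionConfig(BaseModel):
    solid_mass_g: float = 6.0
    liquid_volume_ml: float = 60.0
    solid_density_g_cm3: float = 1.0


class FittingConfig(BaseModel):
    total_content_mg_per_g: float = 7.90
    use_truth_content: bool = True  # synthetic runs: take content from the truth sidecar
    K: float = 1.0
    bounds_decades: float = 3.0
    n_nodes: int = 101


class AnfisConfig(BaseModel):
    ratio: float = 0.6
    epochs: int = 30
    n_mf: int = 2
    mf_kind: Literal["dsigmf", "gaussmf"] = "dsigmf"
    order: Literal[0, 1] = 1
    lr: float = 0.01
    surfaces: list[tuple[str, str]] = Field(
        default=[("temperature_C", "enzyme_pct"), ("time_min", "enzyme_pct")]
    )


class PcaConfig(BaseModel):
    mode: Literal["autoscaled", "covariance"] = "autoscaled"
    n_reps: int = 3


class RunConfig(BaseModel):
    """Validated run configuration; unknown fields are rejected."""

    model_config = {"extra": "forbid"}

    kinetics: str = "synthetic:default"  # CSV path or synthetic: directive
    compounds: str | None = "fixture:table2"  # CSV path, fixture:table2, or None
    particle: ParticleConfig = Field(default_factory=ParticleConfig)
    suspension: SuspensionConfig = Field(default_factory=SuspensionConfig)
    fitting: FittingConfig = Field(default_factory=FittingConfig)
    anfis: AnfisConfig = Field(default_factory=AnfisConfig)
    pca: PcaConfig = Field(default_factory=PcaConfig)
    heatmap_times_min: list[float] = Field(default=[2.5, 10.0, 30.0])
    outdir: str = "phenolflux_run"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)


def _stage_seeds(seed: int) -> dict[str, int]:
    """Derive independent per-stage seeds (< 2^31) from the master seed."""
    ss = np.random.SeedSequence(seed)
    names = ["kinetics", "anfis_split", "pca"]
    states = ss.generate_state(len(names)) % (2**31)
    return dict(zip(names, map(int, states)))


def run_pipeline(config: RunConfig, strict: bool = True) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the manifest dict.  With ``strict`` a stage failure raises
    :class:`PipelineError` after the manifest (including the failure record)
    is written; partial outputs are always retained.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    particle = ParticleSpec(radius_um=config.particle.radius_um)
    suspension = SuspensionSpec(
        solid_mass_g=config.suspension.solid_mass_g,
        liquid_volume_ml=config.suspension.liquid_volume_ml,
        solid_density_g_cm3=config.suspension.solid_density_g_cm3,
    )
    manifest: dict = {
        "phenolflux_version": __version__,
        "python": platform.python_version(),
        "config": json.loads(config.model_dump_json()),
        "stage_seeds": seeds,
        "stages": {},
        "design_notes": [
            "dimensionless diffusion core: tau = De*t/r^2, alpha = VL/(K*Vs)",
            "De search over log10(De/r^2), bounded scalar minimisation of RMSE",
            "ANFIS inputs min-max scaled; hybrid LSE + normalised gradient steps",
            "PCA replicates simulated from printed mean±SD, truncated at zero",
        ],
    }
    failures: list[str] = []

    # ---- kinetics + De fitting -------------------------------------------
    truth = None
    try:
        if config.kinetics.startswith("synthetic:"):
            gen = GeneratorConfig(seed=seeds["kinetics"], noise_sd=0.05,
                                  particle=particle, suspension=suspension)
            dataset, truth = simulate_kinetics(gen)
            dataset.to_csv(out / "kinetics.csv")
            with open(out / "kinetics.truth.json", "w") as fh:
                json.dump(truth, fh, indent=2)
        else:
            dataset = KineticDataset.from_csv(config.kinetics)
            dataset.to_csv(out / "kinetics.csv")

        if truth is not None and config.fitting.use_truth_content:
            gen_truth = default_truth(gen)
            tc = {k: v["extractable_mg_per_g"] for k, v in gen_truth.items()}
        else:
            tc = config.fitting.total_content_mg_per_g
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = fit_all_conditions(
                dataset, particle=particle, suspension=suspension,
                total_content_mg_per_g=tc, K=config.fitting.K,
                bounds_decades=config.fitting.bounds_decades,
                n_nodes=config.fitting.n_nodes,
            )
        fits.to_csv(out / "fits.csv", index=False)
        manifest["stages"]["fitting"] = {
            "status": "ok",
            "n_conditions": int(len(fits)),
            "all_converged": bool(fits["converged"].fillna(False).all()),
        }

        # simulated overlay curves + radial heatmaps from the fitted De
        sims = []
        tmax = dataset.frame["time_min"].max()
        tgrid = np.linspace(0.0, tmax, 61)
        for _, row in fits.iterrows():
            if row["error"]:
                continue
            cs0 = (tc[(row.temperature_C, row.enzyme_pct, row.method)]
                   if isinstance(tc, dict) else tc) / 1000.0 * suspension.solid_density_g_cm3
            params = DiffusionParams.from_rate(row.rate_per_min, particle, Cs0=cs0,
                                               K=config.fitting.K)
            prof = solve_extraction(params, particle, suspension, tgrid,
                                    n_nodes=config.fitting.n_nodes)
            sims.append(pd.DataFrame({
                "temperature_C": row.temperature_C, "enzyme_pct": row.enzyme_pct,
                "method": row.method, "time_min": tgrid,
                "yield_mg_per_g": yield_curve(prof, suspension),
            }))
        if sims:
            sim_frame = pd.concat(sims, ignore_index=True)
            sim_frame.to_csv(out / "simulated_curves.csv", index=False)
            plotting.kinetic_overlay(dataset.frame, sim_frame, out / "kinetic_overlay.png")
            # heatmap for the first condition
            r0 = fits.iloc[0]
            cs0 = (tc[(r0.temperature_C, r0.enzyme_pct, r0.method)]
                   if isinstance(tc, dict) else tc) / 1000.0 * suspension.solid_density_g_cm3
            params = DiffusionParams.from_rate(r0.rate_per_min, particle, Cs0=cs0,
                                               K=config.fitting.K)
            times = np.unique(np.concatenate(([0.0], config.heatmap_times_min)))
            prof = solve_extraction(params, particle, suspension, times,
                                    n_nodes=config.fitting.n_nodes)
            prof.to_frame().to_csv(out / "profile.csv", index=False)
            plotting.radial_heatmap(prof.to_frame(), out / "radial_heatmap.png")
    except Exception as exc:  # noqa: BLE001
        log.exception("fitting stage failed")
        manifest["stages"]["fitting"] = {"status": "failed", "error": str(exc)}
        failures.append(f"fitting: {exc}")
        dataset = None

    # ---- ANFIS ------------------------------------------------------------
    if dataset is not None:
        try:
            frame = dataset.frame[dataset.frame["method"] == "US"].reset_index(drop=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train, test = split_dataset(frame, ratio=config.anfis.ratio,
                                            seed=seeds["anfis_split"])
                model = grid_partition_init(train[ANFIS_FEATURES],
                                            n_mf=config.anfis.n_mf,
                                            mf_kind=config.anfis.mf_kind,
                                            order=config.anfis.order)
                report = train_hybrid(model, train, test, epochs=config.anfis.epochs,
                                      lr=config.anfis.lr, seed=seeds["anfis_split"])
            model.to_json(out / "anfis_model.json")
            with open(out / "anfis_report.json", "w") as fh:
                json.dump(report.__dict__, fh, indent=2)
            plotting.parity_plot(
                train["yield_mg_per_g"], model.forward(train[ANFIS_FEATURES].to_numpy()),
                test["yield_mg_per_g"], model.forward(test[ANFIS_FEATURES].to_numpy()),
                out / "anfis_parity.png",
            )
            for pair in config.anfis.surfaces:
                fixed_name = next(n for n in ANFIS_FEATURES if n not in pair)
                mid = float(model.domains[ANFIS_FEATURES.index(fixed_name)].mean())
                ax1, ax2, Z = response_surface(model, tuple(pair), {fixed_name: mid})
                tag = f"{pair[0]}-{pair[1]}"
                pd.DataFrame(Z, index=ax1, columns=ax2).to_csv(out / f"surface_{tag}.csv")
                plotting.surface_plot(ax1, ax2, Z, tuple(pair), out / f"surface_{tag}.png")
            manifest["stages"]["anfis"] = {
                "status": "ok",
                "train_rmse": report.final_train_rmse,
                "test_rmse": report.final_test_rmse,
                "train_r2": report.final_train_r2,
                "test_r2": report.final_test_r2,
                "best_epoch": report.best_epoch,
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("anfis stage failed")
            manifest["stages"]["anfis"] = {"status": "failed", "error": str(exc)}
            failures.append(f"anfis: {exc}")

    # ---- composition ------------------------------------------------------
    if config.compounds is None:
        log.warning("no compound table configured; composition stage skipped")
        manifest["stages"]["composition"] = {"status": "skipped"}
    else:
        try:
            path = None if config.compounds == "fixture:table2" else config.compounds
            table = read_compound_table(path)
            counts, props = category_summary(table)
            summary = props.copy()
            summary.insert(0, "n_compounds", counts)
            summary.to_csv(out / "category_summary.csv")
            plotting.category_bars(props, out / "category_proportions.png")
            reps = expand_replicates(table, n_reps=config.pca.n_reps, seed=seeds["pca"])
            res = pca_autoscaled(reps, scale=config.pca.mode == "autoscaled")
            res.scores.to_csv(out / "pca_scores.csv")
            res.loadings.to_csv(out / "pca_loadings.csv")
            plotting.pca_biplot(res.scores, res.loadings, res.explained_variance_pct,
                                out / "pca_biplot.png")
            manifest["stages"]["composition"] = {
                "status": "ok",
                "n_compounds": len(table.compounds),
                "pc1_pct": float(res.explained_variance_pct[0]),
                "pc2_pct": float(res.explained_variance_pct[1]),
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("composition stage failed")
            manifest["stages"]["composition"] = {"status": "failed", "error": str(exc)}
            failures.append(f"composition: {exc}")

    manifest["ok"] = not failures
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if failures and strict:
        raise PipelineError("; ".join(failures))
    return manifest
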
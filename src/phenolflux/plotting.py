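"""Figure rendering for the extraction-analysis pipeline.

Figures are views over persisted CSV/JSON outputs, never sources of numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "kinetic_overlay",
    "radial_heatmap",
    "parity_plot",
    "surface_plot",
    "category_bars",
    "pca_biplot",
]


def kinetic_overlay(observed: pd.DataFrame, simulated: pd.DataFrame, path) -> None:
    """Observed points (± SD when present) with simulated yield curves, one
    panel per condition."""
    keys = observed[["temperature_C", "enzyme_pct", "method"]].drop_duplicates()
    n = len(keys)
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False, sharex=True)
    for ax, (_, key) in zip(axes.ravel(), keys.iterrows()):
        sel = (observed[key.index] == key.values).all(axis=1)
        obs = observed[sel].sort_values("time_min")
        simsel = (simulated[key.index] == key.values).all(axis=1)
        sim = simulated[simsel].sort_values("time_min")
        yerr = obs["sd_mg_per_g"] if "sd_mg_per_g" in obs else None
        ax.errorbar(obs["time_min"], obs["yield_mg_per_g"], yerr=yerr,
                    fmt="o", ms=4, capsize=2, label="observed")
        ax.plot(sim["time_min"], sim["yield_mg_per_g"], "-", label="model")
        ax.set_title(f"{key.temperature_C:g} °C, {key.enzyme_pct:g}% ({key.method})",
                     fontsize=9)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("yield (mg GAE/g)")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    axes.ravel()[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def radial_heatmap(profile_frame: pd.DataFrame, path) -> None:
    """Solid-phase concentration Cs(ξ, t) as a time × radius heatmap."""
    pivot = profile_frame.pivot(index="time_min", columns="xi", values="Cs_g_per_cm3")
    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(pivot.columns, pivot.index, pivot.to_numpy(), shading="auto")
    fig.colorbar(mesh, ax=ax, label="Cs (g/cm³)")
    ax.set_xlabel("dimensionless radius ξ")
    ax.set_ylabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def parity_plot(train_obs, train_pred, test_obs, test_pred, path) -> None:
    """Predicted vs experimental yield for the train and test subsets."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, obs, pred, label in ((axes[0], train_obs, train_pred, "training"),
                                 (axes[1], test_obs, test_pred, "testing")):
        obs = np.asarray(obs)
        pred = np.asarray(pred)
        ax.scatter(obs, pred, s=18)
        lims = [min(obs.min(), pred.min()), max(obs.max(), pred.max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("experimental yield (mg/g)")
        ax.set_ylabel("predicted yield (mg/g)")
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def surface_plot(ax1, ax2, Z, names: tuple[str, str], path) -> None:
    """2D contour + 3D surface of a model response over two inputs."""
    fig = plt.figure(figsize=(9, 4))
    a = fig.add_subplot(1, 2, 1)
    c = a.contourf(ax1, ax2, Z.T, levels=20)
    fig.colorbar(c, ax=a, label="yield (mg/g)")
    a.set_xlabel(names[0])
    a.set_ylabel(names[1])
    b = fig.add_subplot(1, 2, 2, projection="3d")
    G1, G2 = np.meshgrid(ax1, ax2, indexing="ij")
    b.plot_surface(G1, G2, Z, cmap="viridis", linewidth=0)
    b.set_xlabel(names[0])
    b.set_ylabel(names[1])
    b.set_zlabel("yield (mg/g)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def category_bars(proportions: pd.DataFrame, path) -> None:
    """Stacked bars of category concentration shares per condition."""
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(proportions.shape[1])
    for cat, row in proportions.iterrows():
        ax.bar(proportions.columns, row.to_numpy(), bottom=bottom, label=cat)
        bottom += row.to_numpy()
    ax.set_ylabel("share of total phenolic mass")
    ax.legend(fontsize=8)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _confidence_ellipse(ax, xy: np.ndarray, color, n_std: float = 2.447) -> None:
    # 95% normal ellipse (sqrt of chi2_2 0.95 quantile ≈ 2.447); cosmetic only
    from matplotlib.patches import Ellipse

    if xy.shape[0] < 3:
        return
    cov = np.cov(xy.T)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, 0.0)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    ell = Ellipse(xy.mean(axis=0), 2 * n_std * np.sqrt(vals[-1]),
                  2 * n_std * np.sqrt(vals[0]), angle=angle,
                  facecolor="none", edgecolor=color, alpha=0.6)
    ax.add_patch(ell)


def pca_biplot(scores: pd.DataFrame, loadings: pd.DataFrame,
               explained_pct, path, group_sep: str = "/") -> None:
    """Score scatter grouped by condition (95% ellipses) with loading arrows."""
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    groups = [idx.split(group_sep)[0] for idx in scores.index]
    cmap = plt.get_cmap("tab10")
    for i, g in enumerate(dict.fromkeys(groups)):
        pts = scores.to_numpy()[[j for j, gg in enumerate(groups) if gg == g], :2]
        ax.scatter(pts[:, 0], pts[:, 1], color=cmap(i % 10), label=g, s=25)
        _confidence_ellipse(ax, pts, cmap(i % 10))
    span = np.abs(scores.to_numpy()[:, :2]).max()
    arrows = loadings.to_numpy()[:, :2] * span
    for name, (x, y) in zip(loadings.index, arrows):
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="grey", lw=0.8))
        ax.text(x * 1.05, y * 1.05, name, fontsize=6, color="grey")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel(f"PC1 ({explained_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({explained_pct[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
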
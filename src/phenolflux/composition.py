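"""Compound-level analytics: category profiling and PCA of phenolic tables.

A compound table holds, for each identified phenolic compound, its category
(phenolic acid, dihydrochalcone, flavanol or flavonol), HPLC retention time
and a mean ± SD concentration (µg per g of solid) under each of six
extraction conditions ({40, 50} °C × {no enzyme, 0.5 %, 1 % cellulase}).
A packaged fixture transcribes the published 17-compound quantification
table; "-" entries mean the compound was not detected under that condition.

Because the underlying triplicate measurements are not published, PCA
samples are simulated by drawing replicates from Normal(mean, SD) truncated
at zero — an explicit approximation.  PCA is autoscaled (correlation-matrix
PCA) by default since compound abundances span three orders of magnitude;
covariance-mode is available.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "CompoundTable",
    "PcaResult",
    "read_compound_table",
    "packaged_table_path",
    "category_summary",
    "condition_query",
    "expand_replicates",
    "pca_autoscaled",
]

VALID_CATEGORIES = {"phenolic acid", "dihydrochalcone", "flavanol", "flavonol"}


@dataclass
class CompoundTable:
    """Compound × condition quantification matrix.

    ``means``/``sds``: DataFrames indexed by compound with one column per
    condition (NaN = not detected); ``categories``/``retention_times``:
    per-compound Series aligned to the same index.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    categories: pd.Series
    retention_times: pd.Series

    @property
    def compounds(self) -> list[str]:
        return list(self.means.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.means.columns)

    def missingness(self) -> pd.Series:
        """Number of conditions in which each compound was not detected."""
        return self.means.isna().sum(axis=1)


def packaged_table_path():
    """Path to the packaged 17-compound quantification fixture."""
    return importlib.resources.files("phenolflux.data") / "table2_phenolics.csv"


def read_compound_table(path=None) -> CompoundTable:
    """Read and validate a compound table CSV.

    Layout: ``category, compound, rt_min`` then ``mean:<cond>, sd:<cond>``
    column pairs; "-" or empty cells mark a compound as not detected.  With
    no ``path`` the packaged fixture is loaded.
    """
    if path is None:
        path = packaged_table_path()
    raw = pd.read_csv(path, na_values=["-", ""])
    for col in ("category", "compound", "rt_min"):
        if col not in raw.columns:
            raise ValueError(f"compound table missing column {col!r}")
    mean_cols = [c for c in raw.columns if c.startswith("mean:")]
    conditions = [c.split(":", 1)[1] for c in mean_cols]
    if not conditions:
        raise ValueError("no 'mean:<condition>' columns found")
    missing_sd = [c for c in conditions if f"sd:{c}" not in raw.columns]
    if missing_sd:
        raise ValueError(f"missing sd columns for conditions: {missing_sd}")

    problems = []
    dup = raw["compound"][raw["compound"].duplicated()]
    if not dup.empty:
        problems.append(f"duplicate compound names: {sorted(set(dup))}")
    bad_cat = sorted(set(raw["category"]) - VALID_CATEGORIES)
    if bad_cat:
        problems.append(f"unknown categories: {bad_cat}")
    means = raw[mean_cols].set_axis(conditions, axis=1).astype(float)
    sds = raw[[f"sd:{c}" for c in conditions]].set_axis(conditions, axis=1).astype(float)
    if (means < 0).any().any() or (sds < 0).any().any():
        problems.append("negative concentrations or SDs")
    if (means.isna() != sds.isna()).any().any():
        problems.append("mean/sd missingness inconsistent")
    if problems:
        raise ValueError("invalid compound table: " + "; ".join(problems))

    idx = raw["compound"]
    return CompoundTable(
        means=means.set_axis(idx, axis=0),
        sds=sds.set_axis(idx, axis=0),
        categories=raw.set_index("compound")["category"],
        retention_times=raw.set_index("compound")["rt_min"],
    )


def category_summary(table: CompoundTable) -> tuple[pd.Series, pd.DataFrame]:
    """Compound counts per category and per-condition concentration shares.

    Shares treat a non-detected compound as contributing zero mass, so each
    condition's category proportions sum to one.
    """
    counts = table.categories.value_counts().sort_index()
    mass = table.means.fillna(0.0).groupby(table.categories).sum()
    proportions = mass / mass.sum(axis=0)
    return counts, proportions


def condition_query(table: CompoundTable, statistic: str, compound: str,
                    ) -> tuple[float, str]:
    """Max/min concentration of a compound over non-missing conditions.

    Returns (value, condition label); ``statistic`` ∈ {"max", "min",
    "argmax-condition"}.
    """
    if compound not in table.means.index:
        raise KeyError(f"unknown compound {compound!r}")
    row = table.means.loc[compound].dropna()
    if row.empty:
        raise ValueError(f"compound {compound!r} missing in all conditions")
    if statistic in ("max", "argmax-condition"):
        cond = row.idxmax()
    elif statistic == "min":
        cond = row.idxmin()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return float(row[cond]), str(cond)


def expand_replicates(table: CompoundTable, n_reps: int = 3, seed: int = 0,
                      ) -> pd.DataFrame:
    """Simulate replicate samples from the printed mean ± SD values.

    Each replicate of each condition draws every compound independently from
    Normal(mean, SD) truncated at zero; non-detected compounds contribute 0.
    Returns an (n_conditions·n_reps) × n_compounds frame whose row labels
    carry the condition identity (``<condition>/rep<k>``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    means = table.means.fillna(0.0).to_numpy().T  # (cond, compound)
    sds = table.sds.fillna(0.0).to_numpy().T
    n_cond, n_comp = means.shape
    draws = rng.normal(
        np.repeat(means, n_reps, axis=0),
        np.repeat(sds, n_reps, axis=0),
        size=(n_cond * n_reps, n_comp),
    )
    draws = np.clip(draws, 0.0, None)
    index = [f"{cond}/rep{k + 1}" for cond in table.conditions for k in range(n_reps)]
    return pd.DataFrame(draws, index=index, columns=table.compounds)


@dataclass
class PcaResult:
    """Principal-component decomposition of a sample × variable matrix."""

    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # variables × components
    explained_variance_pct: np.ndarray
    preprocessing: str
    dropped_columns: list[str]

    def reconstruct(self) -> np.ndarray:
        """Scores · loadingsᵀ — the preprocessed data matrix."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def pca_autoscaled(matrix: pd.DataFrame, n_components: int | None = None,
                   scale: bool = True) -> PcaResult:
    """PCA of an autoscaled (centred, unit-variance) sample matrix.

    Constant columns are dropped with a warning; with ``scale=False`` only
    centring is applied (covariance-mode PCA).  All ``min(n−1, p)``
    components are kept by default so the explained-variance percentages sum
    to 100 and the scores/loadings reproduce the preprocessed matrix.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for PCA")
    std = X.std(axis=0, ddof=1)
    keep = std > 0
    dropped = [c for c, k in zip(matrix.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
        X = X[:, keep]
        std = std[keep]
    Xp = X - X.mean(axis=0)
    if scale:
        Xp = Xp / std

    max_rank = min(Xp.shape[0] - 1, Xp.shape[1])
    if n_components is None:
        n_components = max_rank
    elif n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components > rank bound {max_rank}; truncated",
            stacklevel=2,
        )
        n_components = max_rank
    pca = PCA(n_components=max_rank, svd_solver="full")
    scores = pca.fit_transform(Xp)[:, :n_components]
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    kept_cols = [c for c, k in zip(matrix.columns, keep) if k]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_[:n_components].T,
                              index=kept_cols, columns=comp_names),
        explained_variance_pct=pca.explained_variance_ratio_[:n_components] * 100.0,
        preprocessing="autoscaled" if scale else "centred",
        dropped_columns=dropped,
    )
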
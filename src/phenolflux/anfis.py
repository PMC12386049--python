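"""Five-layer Takagi–Sugeno adaptive neuro-fuzzy inference system (ANFIS).

Predicts total phenolic yield (mg GAE/g) from extraction temperature (°C),
sonication time (min) and enzyme concentration (% w/v).  The architecture is
the classical one:

  I   fuzzification — each input passes through its membership functions
      (difference-of-sigmoids ``dsigmf`` by default, Gaussian optional);
  II  rule layer — firing strength of every premise combination (grid
      partition: all Π nᵢ combinations) via the product t-norm;
  III normalisation — firing strengths scaled to sum to one;
  IV  defuzzification — per-rule first-order consequents ŷᵢ = pᵢᵀx + sᵢ
      weighted by normalised firings;
  V   output — the weighted sum.

Training is the hybrid scheme: each epoch solves the consequent coefficients
exactly by linear least squares (premises fixed), then nudges the premise
parameters down the squared-error gradient with a normalised step.  The model
snapshot at the epoch with minimum test RMSE is retained.

Inputs are min–max scaled to [0, 1] internally; all user-facing values are in
raw units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import r_squared, rmse

__all__ = [
    "MembershipFunction",
    "AnfisModel",
    "TrainReport",
    "split_dataset",
    "grid_partition_init",
    "predict",
    "train_hybrid",
    "evaluate",
    "response_surface",
]

_SCHEMA_VERSION = 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


@dataclass
class MembershipFunction:
    """A fuzzy set on one (scaled) input.

    ``dsigmf`` params (a1, c1, a2, c2): σ(a1(x−c1)) − σ(a2(x−c2)), an
    interval-shaped set; ``gaussmf`` params (sigma, c).
    """

    kind: str
    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.kind not in ("dsigmf", "gaussmf"):
            raise ValueError(f"unknown membership kind {self.kind!r}")
        n = 4 if self.kind == "dsigmf" else 2
        if self.params.shape != (n,) or not np.all(np.isfinite(self.params)):
            raise ValueError(f"{self.kind} needs {n} finite params")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "dsigmf":
            a1, c1, a2, c2 = self.params
            return _sigmoid(a1 * (x - c1)) - _sigmoid(a2 * (x - c2))
        sigma, c = self.params
        return np.exp(-0.5 * ((x - c) / sigma) ** 2)

    def grad(self, x: np.ndarray) -> np.ndarray:
        """∂μ/∂params, shape (len(params), len(x))."""
        x = np.asarray(x, dtype=float)
        if self.kind == "dsigmf":
            a1, c1, a2, c2 = self.params
            s1 = _sigmoid(a1 * (x - c1))
            s2 = _sigmoid(a2 * (x - c2))
            d1 = s1 * (1.0 - s1)
            d2 = s2 * (1.0 - s2)
            return np.stack([d1 * (x - c1), -a1 * d1, -d2 * (x - c2), a2 * d2])
        sigma, c = self.params
        mu = self(x)
        return np.stack([mu * (x - c) ** 2 / sigma**3, mu * (x - c) / sigma**2])


@dataclass
class AnfisModel:
    """Sugeno fuzzy model: input domains, per-input MFs, the full rule grid
    and first-order consequent coefficients (one row per rule: the input
    weights followed by the constant)."""

    input_names: list[str]
    domains: np.ndarray  # (n_inputs, 2) raw-unit (lo, hi)
    mfs: list[list[MembershipFunction]]  # per input, on the [0,1] scale
    rules: np.ndarray  # (n_rules, n_inputs) MF index per input
    consequents: np.ndarray  # (n_rules, n_inputs + 1)
    order: int = 1  # 1 = first-order Sugeno, 0 = constant consequents
    meta: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_rules(self) -> int:
        return self.rules.shape[0]

    def scale(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.domains[:, 0], self.domains[:, 1]
        return (np.asarray(X, dtype=float) - lo) / (hi - lo)

    # -- layers ------------------------------------------------------------
    def memberships(self, Xs: np.ndarray) -> list[np.ndarray]:
        """Layer I on scaled inputs: per input an (n_samples, n_mf) array."""
        return [np.stack([mf(Xs[:, j]) for mf in self.mfs[j]], axis=1)
                for j in range(self.n_inputs)]

    def firing(self, mu: list[np.ndarray]) -> np.ndarray:
        """Layer II: product t-norm over each rule's premise, (n, n_rules)."""
        w = np.ones((mu[0].shape[0], self.n_rules))
        for j in range(self.n_inputs):
            w *= mu[j][:, self.rules[:, j]]
        return w

    def forward(self, X: np.ndarray, trace: bool = False):
        """Full five-layer pass on raw-unit inputs (n_samples, n_inputs)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite input")
        Xs = self.scale(X)
        mu = self.memberships(Xs)
        w = self.firing(mu)
        wsum = w.sum(axis=1)
        if np.any(wsum <= 0.0):
            raise ValueError("input outside fuzzy support: all firing strengths zero")
        wbar = w / wsum[:, None]
        if self.order == 1:
            f = Xs @ self.consequents[:, :-1].T + self.consequents[:, -1]
        else:
            f = np.broadcast_to(self.consequents[:, -1], wbar.shape)
        y = np.sum(wbar * f, axis=1)
        if trace:
            return y, {"scaled": Xs, "memberships": mu, "firing": w,
                       "normalized": wbar, "consequent": f}
        return y

    def design_matrix(self, X: np.ndarray) -> np.ndarray:
        """LSE design: per sample, normalised firings times [x, 1] blocks."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = self.scale(X)
        wbar = self.firing(self.memberships(Xs))
        wbar = wbar / wbar.sum(axis=1, keepdims=True)
        if self.order == 1:
            blocks = np.concatenate([Xs, np.ones((Xs.shape[0], 1))], axis=1)
            return np.einsum("nr,nc->nrc", wbar, blocks).reshape(Xs.shape[0], -1)
        return wbar

    # -- serialisation -----------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "schema_version": _SCHEMA_VERSION,
            "input_names": self.input_names,
            "domains": self.domains.tolist(),
            "mfs": [[{"kind": m.kind, "params": m.params.tolist()} for m in row]
                    for row in self.mfs],
            "rules": self.rules.tolist(),
            "consequents": self.consequents.tolist(),
            "order": self.order,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AnfisModel":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {obj.get('schema_version')!r}")
        return cls(
            input_names=obj["input_names"],
            domains=np.asarray(obj["domains"], dtype=float),
            mfs=[[MembershipFunction(m["kind"], np.asarray(m["params"]))
                  for m in row] for row in obj["mfs"]],
            rules=np.asarray(obj["rules"], dtype=int),
            consequents=np.asarray(obj["consequents"], dtype=float),
            order=int(obj["order"]),
            meta=obj.get("meta", {}),
        )

    def copy(self) -> "AnfisModel":
        return AnfisModel(
            input_names=list(self.input_names),
            domains=self.domains.copy(),
            mfs=[[MembershipFunction(m.kind, m.params.copy()) for m in row]
                 for row in self.mfs],
            rules=self.rules.copy(),
            consequents=self.consequents.copy(),
            order=self.order,
            meta=dict(self.meta),
        )


@dataclass
class TrainReport:
    """Per-epoch training trajectory and the retained model's final metrics."""

    train_rmse: list[float]
    test_rmse: list[float]
    best_epoch: int
    final_train_rmse: float
    final_test_rmse: float
    final_train_r2: float
    final_test_r2: float
    epochs: int
    seed: int | None
    train_index: list[int]
    test_index: list[int]
    algorithm: str = "hybrid"


def split_dataset(samples: pd.DataFrame, ratio: float = 0.6, seed: int = 0,
                  strata_cols: tuple[str, ...] = ("temperature_C", "enzyme_pct"),
                  balance_col: str = "time_min",
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test split, stratified over condition cells.

    The train size is ``round(ratio·n)`` overall, allocated across strata by
    largest remainder so that every cell with ≥ 2 samples contributes to both
    subsets.  Within a stratum the test picks are spread systematically over
    ``balance_col`` (one random draw per quantile block), so that — as in the
    source experiment — both subsets cover the full kinetic range instead of,
    say, all early steep-phase points landing in one subset.  A singleton
    stratum goes to the train set with a warning.
    """
    n = len(samples)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0,1), got {ratio}")
    rng = np.random.default_rng(seed)
    n_train_target = int(round(ratio * n))

    strata_cols = [c for c in strata_cols if c in samples.columns]
    if strata_cols:
        groups = list(samples.groupby(strata_cols, sort=True).groups.items())
    else:
        groups = [("all", samples.index)]

    quotas, fracs, singles = [], [], []
    for key, idx in groups:
        if len(idx) == 1:
            warnings.warn(f"stratum {key} has a single sample; assigned to train",
                          stacklevel=2)
            singles.append(idx[0])
            quotas.append(None)
            fracs.append(-1.0)
            continue
        q = ratio * len(idx)
        quotas.append(int(np.floor(q)))
        fracs.append(q - np.floor(q))
    remaining = n_train_target - len(singles) - sum(q for q in quotas if q is not None)
    order = np.argsort(-np.asarray(fracs), kind="stable")
    for g in order:
        if remaining <= 0:
            break
        if quotas[g] is None or quotas[g] >= len(groups[g][1]) - 1:
            continue  # keep at least one test sample per stratum
        quotas[g] += 1
        remaining -= 1

    train_idx: list = list(singles)
    test_idx: list = []
    for (key, idx), q in zip(groups, quotas):
        if q is None:
            continue
        idx = np.asarray(idx)
        n_test = len(idx) - q
        if balance_col in samples.columns:
            order = idx[np.argsort(samples.loc[idx, balance_col].to_numpy(),
                                   kind="stable")]
        else:
            order = rng.permutation(idx)
        # one test pick per quantile block of the balance column
        blocks = np.array_split(order, n_test)
        for b in blocks:
            j = int(rng.integers(len(b)))
            test_idx.append(b[j])
            train_idx.extend(np.delete(b, j))
    train_idx.sort()
    test_idx.sort()
    return samples.loc[train_idx], samples.loc[test_idx]


def grid_partition_init(train_X: pd.DataFrame | np.ndarray, n_mf: int = 2,
                        mf_kind: str = "dsigmf", order: int = 1,
                        input_names: list[str] | None = None) -> AnfisModel:
    """Initial model by grid partitioning.

    Per input, ``n_mf`` membership functions with centres at equal quantiles
    of the (scaled) domain and widths chosen so adjacent sets cross near 0.5;
    the rule base is the full factorial; consequents start at zero.
    """
    if isinstance(train_X, pd.DataFrame):
        names = input_names or list(train_X.columns)
        X = train_X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(train_X, dtype=float))
        names = input_names or [f"x{j+1}" for j in range(X.shape[1])]
    if n_mf < 1:
        raise ValueError("n_mf must be >= 1")
    lo, hi = X.min(axis=0), X.max(axis=0)
    for j, name in enumerate(names):
        if hi[j] - lo[j] <= 0:
            raise ValueError(f"input {name!r} is constant in the training data")
    domains = np.stack([lo, hi], axis=1)

    # on the scaled [0,1] axis: centres at k/(n_mf-1), half-width = step/2;
    # the slope gives substantially overlapping sets (membership decays over
    # ~step/3) while adjacent sets still cross within 1e-3 of 0.5 — heavily
    # overlapped partitions share data across rules and generalise far better
    # than near-crisp ones when samples are scarce relative to consequents
    step = 1.0 / (n_mf - 1) if n_mf > 1 else 2.0
    half = step / 2.0
    slope = 7.0 / step
    mfs: list[list[MembershipFunction]] = []
    for _ in names:
        row = []
        for k in range(n_mf):
            c = k * step if n_mf > 1 else 0.5
            if mf_kind == "dsigmf":
                row.append(MembershipFunction("dsigmf",
                                              [slope, c - half, slope, c + half]))
            else:
                sigma = half / np.sqrt(2.0 * np.log(2.0))
                row.append(MembershipFunction("gaussmf", [sigma, c]))
        mfs.append(row)

    grids = np.meshgrid(*[np.arange(n_mf)] * len(names), indexing="ij")
    rules = np.stack([g.ravel() for g in grids], axis=1)
    consequents = np.zeros((rules.shape[0], len(names) + 1))
    return AnfisModel(input_names=names, domains=domains, mfs=mfs, rules=rules,
                      consequents=consequents, order=order,
                      meta={"n_mf": n_mf, "mf_kind": mf_kind})


def predict(model: AnfisModel, x, trace: bool = False):
    """Predict yield for one input triple or a batch; with ``trace`` the
    per-layer intermediates are returned as well."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = model.forward(np.atleast_2d(x), trace=trace)
    if trace:
        y, tr = out
        return (float(y[0]), tr) if single else (y, tr)
    return float(out[0]) if single else out


def _solve_consequents(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> None:
    A = model.design_matrix(X)
    n_coef = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    if rank < n_coef:
        warnings.warn(
            f"LSE system rank-deficient ({rank}/{n_coef}); ridge fallback",
            stacklevel=3,
        )
        theta = np.linalg.solve(A.T @ A + 1e-8 * np.eye(n_coef), A.T @ y)
    else:
        theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    if model.order == 1:
        model.consequents = theta.reshape(model.n_rules, model.n_inputs + 1)
    else:
        model.consequents[:, -1] = theta


def _premise_gradient(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> list[list[np.ndarray]]:
    """∂SSE/∂(MF params) with consequents fixed, via the chain rule through
    the product t-norm and the normalisation layer."""
    X = np.atleast_2d(X)
    Xs = model.scale(X)
    mu = model.memberships(Xs)
    w = model.firing(mu)
    wsum = w.sum(axis=1)
    wbar = w / wsum[:, None]
    if model.order == 1:
        f = Xs @ model.consequents[:, :-1].T + model.consequents[:, -1]
    else:
        f = np.broadcast_to(model.consequents[:, -1], wbar.shape)
    yhat = np.sum(wbar * f, axis=1)
    resid = yhat - y  # dE/dyhat = 2·resid; the 2 is absorbed in the step size
    # dyhat/dw_k = (f_k - yhat)/wsum
    dy_dw = (f - yhat[:, None]) / wsum[:, None]
    grads: list[list[np.ndarray]] = []
    eps = 1e-12
    for j in range(model.n_inputs):
        rows = []
        for m, mf in enumerate(model.mfs[j]):
            uses = model.rules[:, j] == m  # rules whose premise uses this MF
            # dw_k/dmu = w_k/mu for those rules
            dmu = np.sum(dy_dw[:, uses] * w[:, uses], axis=1) / np.maximum(mu[j][:, m], eps)
            dmu_dp = mf.grad(Xs[:, j])  # (n_params, n)
            rows.append(dmu_dp @ (resid * dmu))
        grads.append(rows)
    return grads


def train_hybrid(model: AnfisModel, train: pd.DataFrame, test: pd.DataFrame | None = None,
                 target: str = "yield_mg_per_g", epochs: int = 30, lr: float = 0.01,
                 seed: int | None = None) -> TrainReport:
    """Hybrid LSE + gradient-descent training (in place).

    Each epoch: (1) forward pass solves the consequents by least squares on
    the normalised-firing design matrix and records train/test RMSE; (2) the
    backward pass takes a normalised gradient step (length ``lr``) on the
    premise parameters.  The learning rate halves whenever train RMSE rises.
    The model state at the best-test-RMSE epoch is restored at the end.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if len(train) == 0:
        raise ValueError("empty training set")
    feats = model.input_names
    Xtr = train[feats].to_numpy(dtype=float)
    ytr = train[target].to_numpy(dtype=float)
    have_test = test is not None and len(test) > 0
    if have_test:
        Xte = test[feats].to_numpy(dtype=float)
        yte = test[target].to_numpy(dtype=float)

    tr_hist: list[float] = []
    te_hist: list[float] = []
    best = (np.inf, 0, None)  # (test RMSE, epoch, snapshot)
    cur_lr = lr
    for epoch in range(epochs):
        _solve_consequents(model, Xtr, ytr)
        tr_rmse = rmse(model.forward(Xtr), ytr)
        te_rmse = rmse(model.forward(Xte), yte) if have_test else tr_rmse
        tr_hist.append(tr_rmse)
        te_hist.append(te_rmse)
        if te_rmse < best[0]:
            best = (te_rmse, epoch, model.copy())
        if epoch > 0 and tr_rmse > tr_hist[-2]:
            cur_lr /= 2.0
        if epoch < epochs - 1:  # no premise update after the last forward pass
            grads = _premise_gradient(model, Xtr, ytr)
            norm = np.sqrt(sum(float(g @ g) for rows in grads for g in rows))
            if norm > 0:
                for j, rows in enumerate(grads):
                    for m, g in enumerate(rows):
                        model.mfs[j][m].params -= cur_lr * g / norm

    if best[2] is not None:
        snap = best[2]
        model.mfs = snap.mfs
        model.consequents = snap.consequents

    pred_tr = model.forward(Xtr)
    final = TrainReport(
        train_rmse=tr_hist,
        test_rmse=te_hist,
        best_epoch=best[1],
        final_train_rmse=rmse(pred_tr, ytr),
        final_test_rmse=rmse(model.forward(Xte), yte) if have_test else float("nan"),
        final_train_r2=r_squared(pred_tr, ytr),
        final_test_r2=r_squared(model.forward(Xte), yte) if have_test else float("nan"),
        epochs=epochs,
        seed=seed,
        train_index=list(map(int, train.index)),
        test_index=list(map(int, test.index)) if have_test else [],
    )
    model.meta.update({"epochs": epochs, "best_epoch": best[1], "algorithm": "hybrid"})
    return final


def evaluate(model: AnfisModel, data: pd.DataFrame, target: str = "yield_mg_per_g") -> dict:
    """RMSE and R² of the model on a labelled dataset (shared metric code
    with the diffusivity-fitting module)."""
    y = data[target].to_numpy(dtype=float)
    pred = model.forward(data[model.input_names].to_numpy(dtype=float))
    return {"rmse": rmse(pred, y), "r_squared": r_squared(pred, y)}


def response_surface(model: AnfisModel, var_pair: tuple[str, str],
                     fixed: dict[str, float], grid: int = 40,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted-yield surface over a grid of two inputs with the remaining
    input(s) held fixed.  Returns (axis1, axis2, surface[i, j]) with axis1
    varying along rows."""
    v1, v2 = var_pair
    if v1 == v2:
        raise ValueError("var_pair must name two distinct inputs")
    for v in var_pair:
        if v not in model.input_names:
            raise ValueError(f"unknown input {v!r}")
    if grid < 10:
        raise ValueError("grid must be >= 10")
    dom = {n: model.domains[i] for i, n in enumerate(model.input_names)}
    for name, val in fixed.items():
        lo, hi = dom[name]
        if not lo <= val <= hi:
            raise ValueError(f"fixed value {name}={val} outside domain [{lo}, {hi}]")
    ax1 = np.linspace(*dom[v1], grid)
    ax2 = np.linspace(*dom[v2], grid)
    G1, G2 = np.meshgrid(ax1, ax2, indexing="ij")
    X = np.zeros((grid * grid, model.n_inputs))
    for i, name in enumerate(model.input_names):
        if name == v1:
            X[:, i] = G1.ravel()
        elif name == v2:
            X[:, i] = G2.ravel()
        else:
            X[:, i] = fixed[name]
    Z = model.forward(X).reshape(grid, grid)
    return ax1, ax2, Z
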
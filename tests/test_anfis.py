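"""Takagi–Sugeno ANFIS: layers, initialisation, hybrid training."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenolflux.anfis import (
    AnfisModel,
    MembershipFunction,
    evaluate,
    grid_partition_init,
    predict,
    response_surface,
    split_dataset,
    train_hybrid,
)
from phenolflux.fitting import rmse
from phenolflux.synthetic import GeneratorConfig, simulate_kinetics

FEATS = ["temperature_C", "time_min", "enzyme_pct"]


def _dataset(seed=0, noise=0.05):
    ds, _ = simulate_kinetics(GeneratorConfig(seed=seed, noise_sd=noise))
    return ds.frame


class TestSplit:
    def test_sizes_follow_rounding_rule(self):
        df = _dataset()
        train, test = split_dataset(df, ratio=0.6, seed=0)
        assert len(train) == round(0.6 * 48) == 29
        assert len(test) == 48 - 29
        assert set(train.index).isdisjoint(test.index)
        assert len(train) + len(test) == 48

    def test_every_cell_in_both_subsets(self):
        df = _dataset()
        train, test = split_dataset(df, ratio=0.6, seed=3)
        for part in (train, test):
            cells = part.groupby(["temperature_C", "enzyme_pct"]).size()
            assert len(cells) == 6

    def test_deterministic_per_seed(self):
        df = _dataset()
        a1, b1 = split_dataset(df, 0.6, seed=11)
        a2, b2 = split_dataset(df, 0.6, seed=11)
        assert list(a1.index) == list(a2.index)
        assert list(b1.index) == list(b2.index)

    def test_degenerate_ratios_rejected(self):
        df = _dataset()
        with pytest.raises(ValueError):
            split_dataset(df, ratio=1.0)
        with pytest.raises(ValueError):
            split_dataset(df.head(5), ratio=0.6)

    def test_singleton_stratum_goes_to_train(self):
        df = _dataset()
        single = df[(df.temperature_C == 40.0) & (df.enzyme_pct == 0.0)].head(1)
        rest = df[(df.enzyme_pct != 0.0) | (df.temperature_C != 40.0)]
        both = pd.concat([single, rest])
        with pytest.warns(UserWarning, match="single sample"):
            train, test = split_dataset(both, 0.6, seed=0)
        assert single.index[0] in train.index


class TestInit:
    def test_two_mfs_cross_near_half_at_midpoint(self):
        X = np.column_stack([np.linspace(0, 1, 20)] * 3)
        m = grid_partition_init(X, n_mf=2)
        for j in range(3):
            mid = m.domains[j].mean()
            vals = [float(mf(m.scale(np.array([[mid] * 3]))[0, j:j + 1])[0])
                    for mf in m.mfs[j]]
            for v in vals:
                assert abs(v - 0.5) < 0.1

    def test_membership_bounded_on_domain_scan(self):
        X = np.column_stack([np.linspace(0, 1, 20)] * 2)
        m = grid_partition_init(X, n_mf=3)
        scan = np.linspace(0, 1, 101)
        for row in m.mfs:
            for mf in row:
                mu = mf(scan)
                assert np.all(mu >= 0) and np.all(mu <= 1.0)

    @pytest.mark.parametrize("n_mf, n_inputs, n_rules", [(2, 3, 8), (3, 3, 27), (1, 3, 1)])
    def test_rule_count_is_full_factorial(self, n_mf, n_inputs, n_rules):
        X = np.random.default_rng(0).uniform(size=(20, n_inputs))
        m = grid_partition_init(X, n_mf=n_mf)
        assert m.n_rules == n_rules

    def test_constant_column_rejected_by_name(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="'b'"):
            grid_partition_init(X, n_mf=2)


class TestForwardPass:
    def test_single_rule_constant_model(self):
        X = np.random.default_rng(1).uniform(size=(20, 3))
        m = grid_partition_init(X, n_mf=1)
        m.consequents[:] = 0.0
        m.consequents[0, -1] = 4.2
        for x in X[:5]:
            assert predict(m, x) == pytest.approx(4.2, abs=1e-12)

    def test_normalisation_layer_sums_to_one(self):
        X = np.random.default_rng(2).uniform(size=(30, 3))
        m = grid_partition_init(X, n_mf=2)
        _, trace = predict(m, X, trace=True)
        np.testing.assert_allclose(trace["normalized"].sum(axis=1), 1.0, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_normalisation_property_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(8, 3))
        m = grid_partition_init(np.column_stack([np.linspace(0, 1, 10)] * 3), n_mf=2)
        _, trace = predict(m, X, trace=True)
        np.testing.assert_allclose(trace["normalized"].sum(axis=1), 1.0, atol=1e-12)

    def test_two_rule_one_input_hand_computed(self):
        """Forward pass reproduces hand arithmetic for a 1-input, 2-rule
        model evaluated at the domain midpoint."""
        mf1 = MembershipFunction("dsigmf", [7.0, -0.5, 7.0, 0.5])
        mf2 = MembershipFunction("dsigmf", [7.0, 0.5, 7.0, 1.5])
        m = AnfisModel(
            input_names=["x"], domains=np.array([[0.0, 1.0]]),
            mfs=[[mf1, mf2]], rules=np.array([[0], [1]]),
            consequents=np.array([[2.0, 1.0], [-1.0, 3.0]]),
        )
        x = 0.5
        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        mu1 = sig(7.0 * (x + 0.5)) - sig(7.0 * (x - 0.5))
        mu2 = sig(7.0 * (x - 0.5)) - sig(7.0 * (x - 1.5))
        f1, f2 = 2.0 * x + 1.0, -1.0 * x + 3.0
        expected = (mu1 * f1 + mu2 * f2) / (mu1 + mu2)
        assert predict(m, np.array([x])) == pytest.approx(expected, abs=1e-12)

    def test_zero_support_raises(self):
        mf = MembershipFunction("gaussmf", [0.01, 0.5])
        m = AnfisModel(["x"], np.array([[0.0, 1.0]]), [[mf]],
                       np.array([[0]]), np.zeros((1, 2)))
        with pytest.raises(ValueError, match="fuzzy support"):
            predict(m, np.array([100.0]))


class TestTraining:
    def test_linear_target_solved_by_first_lse(self):
        """One MF per input → a single global linear consequent; plain least
        squares reproduces an exactly linear target to machine precision."""
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(40, 3))
        y = 1.5 * X[:, 0] - 2.0 * X[:, 1] + 0.5 * X[:, 2] + 3.0
        df = pd.DataFrame(X, columns=FEATS)
        df["yield_mg_per_g"] = y
        m = grid_partition_init(df[FEATS], n_mf=1)
        rep = train_hybrid(m, df, epochs=1)
        assert rep.final_train_rmse < 1e-8

    def test_epochs_must_be_positive(self):
        df = _dataset()
        m = grid_partition_init(df[FEATS], n_mf=2)
        with pytest.raises(ValueError):
            train_hybrid(m, df, epochs=0)

    def test_held_out_r2_on_synthetic_design(self):
        """Seeded 48-run dataset, 6:4 split, 2 dsigmf MFs per input, hybrid,
        30 epochs → held-out R² ≥ 0.96."""
        df = _dataset(seed=0)
        train, test = split_dataset(df, 0.6, seed=0)
        m = grid_partition_init(train[FEATS], n_mf=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = train_hybrid(m, train, test, epochs=30, seed=0)
        assert rep.final_test_r2 >= 0.96

    def test_reproducible_bitwise(self):
        df = _dataset(seed=4)
        reports = []
        for _ in range(2):
            train, test = split_dataset(df, 0.6, seed=4)
            m = grid_partition_init(train[FEATS], n_mf=2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reports.append(train_hybrid(m, train, test, epochs=10, seed=4))
        assert reports[0].train_rmse == reports[1].train_rmse
        assert reports[0].test_rmse == reports[1].test_rmse

    def test_forward_pass_consequents_are_sse_optimal(self):
        """Perturbing any consequent coefficient by ±1e-3 never lowers the
        training SSE below the LSE solution's."""
        df = _dataset(seed=6)
        train, test = split_dataset(df, 0.6, seed=6)
        m = grid_partition_init(train[FEATS], n_mf=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train_hybrid(m, train, test, epochs=5, seed=6)
        X = train[FEATS].to_numpy()
        y = train["yield_mg_per_g"].to_numpy()
        sse0 = np.sum((m.forward(X) - y) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i = rng.integers(m.consequents.shape[0])
            j = rng.integers(m.consequents.shape[1])
            for delta in (1e-3, -1e-3):
                m2 = m.copy()
                m2.consequents[i, j] += delta
                sse = np.sum((m2.forward(X) - y) ** 2)
                assert sse >= sse0 - 1e-9

    def test_capacity_recovers_own_architecture(self):
        """Noiseless targets generated by an ANFIS of identical architecture
        are recovered to test RMSE < 1e-3 (predictions, not parameters)."""
        df = _dataset(seed=8, noise=0.0)
        teacher = grid_partition_init(df[FEATS], n_mf=2)
        rng = np.random.default_rng(8)
        teacher.consequents = rng.normal(0, 1, teacher.consequents.shape)
        data = df.copy()
        data["yield_mg_per_g"] = teacher.forward(df[FEATS].to_numpy())
        train, test = split_dataset(data, 0.6, seed=8)
        student = grid_partition_init(train[FEATS], n_mf=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = train_hybrid(student, train, test, epochs=30, seed=8)
        assert rep.final_test_rmse < 1e-3


class TestEvaluateAndSurface:
    def test_evaluate_matches_shared_metrics(self):
        df = _dataset(seed=3)
        m = grid_partition_init(df[FEATS], n_mf=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train_hybrid(m, df, epochs=3)
        res = evaluate(m, df)
        pred = m.forward(df[FEATS].to_numpy())
        assert res["rmse"] == pytest.approx(rmse(pred, df["yield_mg_per_g"]), abs=1e-12)

    def test_evaluate_on_exact_outputs(self):
        df = _dataset(seed=3)
        m = grid_partition_init(df[FEATS], n_mf=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train_hybrid(m, df, epochs=1)
        data = df.copy()
        data["yield_mg_per_g"] = m.forward(df[FEATS].to_numpy())
        res = evaluate(m, data)
        assert res["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_model_r2_can_be_negative(self):
        df = _dataset(seed=3)
        m = grid_partition_init(df[FEATS], n_mf=1)
        m.consequents[:] = 0.0
        m.consequents[0, -1] = 100.0
        assert evaluate(m, df)["r_squared"] < 0

    def test_surface_consistent_with_predict(self):
        df = _dataset(seed=2)
        m = grid_partition_init(df[FEATS], n_mf=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train_hybrid(m, df, epochs=3)
        ax1, ax2, Z = response_surface(m, ("temperature_C", "enzyme_pct"),
                                       {"time_min": 10.0}, grid=10)
        i, j = 4, 7
        direct = predict(m, np.array([ax1[i], 10.0, ax2[j]]))
        assert Z[i, j] == pytest.approx(direct, abs=1e-12)

    def test_surface_validation(self):
        df = _dataset(seed=2)
        m = grid_partition_init(df[FEATS], n_mf=2)
        with pytest.raises(ValueError):
            response_surface(m, ("time_min", "time_min"), {"enzyme_pct": 0.5})
        with pytest.raises(ValueError):
            response_surface(m, ("temperature_C", "enzyme_pct"), {"time_min": 10.0},
                             grid=5)


class TestSerialisation:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        df = _dataset(seed=1)
        m = grid_partition_init(df[FEATS], n_mf=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train_hybrid(m, df, epochs=3)
        path = tmp_path / "m.json"
        m.to_json(path)
        m2 = AnfisModel.from_json(path)
        X = df[FEATS].to_numpy()
        np.testing.assert_array_equal(m.forward(X), m2.forward(X))
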
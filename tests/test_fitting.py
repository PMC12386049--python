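"""Goodness-of-fit metrics and effective-diffusivity estimation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenolflux.fitting import (
    KineticDataset,
    aad,
    fit_all_conditions,
    fit_de,
    r_squared,
    rmse,
)
from phenolflux.synthetic import GeneratorConfig, default_truth, simulate_kinetics


def brute_rmse(p, o):
    s = 0.0
    for a, b in zip(p, o):
        s += (a - b) ** 2
    return math.sqrt(s / len(p))


def brute_r2(p, o):
    mean = sum(o) / len(o)
    ss_res = sum((b - a) ** 2 for a, b in zip(p, o))
    ss_tot = sum((b - mean) ** 2 for b in o)
    return 1.0 - ss_res / ss_tot


def brute_aad(p, o):
    return 100.0 * sum(abs(b - a) / b for a, b in zip(p, o)) / len(p)


class TestMetrics:
    @pytest.mark.parametrize("pred, obs, expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2], [1, 4], math.sqrt(2)),
        ([0], [3], 3.0),
    ])
    def test_rmse_examples(self, pred, obs, expected):
        assert rmse(pred, obs) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pred, obs, expected", [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([2, 2, 2], [1, 2, 3], 0.0),  # predicting the mean everywhere
        ([1, 2, 4], [1, 2, 3], 0.5),
    ])
    def test_r_squared_examples(self, pred, obs, expected):
        assert r_squared(pred, obs) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pred, obs, expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1], [2], 50.0),
        ([2, 2], [1, 4], 75.0),
    ])
    def test_aad_examples(self, pred, obs, expected):
        assert aad(pred, obs) == pytest.approx(expected, abs=1e-12)

    def test_cross_validated_against_brute_force(self):
        """Vectorised metrics agree with element-wise loops to 1e-12 on 100
        random vectors."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            o = rng.uniform(0.1, 10.0, n)
            p = o + rng.normal(0, 1.0, n)
            assert rmse(p, o) == pytest.approx(brute_rmse(p, o), abs=1e-12)
            assert r_squared(p, o) == pytest.approx(brute_r2(p, o), abs=1e-12)
            assert aad(p, o) == pytest.approx(brute_aad(p, o), abs=1e-12)

    @given(st.lists(st.floats(0.1, 100.0), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rmse_nonnegative_and_zero_iff_equal(self, obs):
        assert rmse(obs, obs) == 0.0
        shifted = [x + 1.0 for x in obs]
        assert rmse(shifted, obs) == pytest.approx(1.0, abs=1e-12)

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])
        with pytest.raises(ValueError):
            r_squared([1, 2], [3, 3])
        with pytest.raises(ValueError):
            aad([1], [0])


def _single_condition_dataset(rate, eq_yield, times, noise_sd=0.0, seed=0,
                              temperature=40.0, enzyme=0.5):
    cfg = GeneratorConfig(
        temperatures=(temperature,), enzyme_levels=(enzyme,),
        time_points_min=tuple(times), noise_sd=noise_sd, n_reps=1, seed=seed,
        rate_map={(temperature, enzyme, "US"): rate},
        equilibrium_map={(temperature, enzyme, "US"): eq_yield},
    )
    ds, _ = simulate_kinetics(cfg)
    tc = default_truth(cfg)[(temperature, enzyme, "US")]["extractable_mg_per_g"]
    return ds, tc


class TestFitDe:
    def test_noiseless_recovery_within_one_percent(self):
        times = (2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0)
        for rate_true in (0.003, 0.01, 0.02):
            ds, tc = _single_condition_dataset(rate_true, 2.4, times)
            res = fit_de(ds.frame, total_content_mg_per_g=tc)
            assert res.converged
            assert abs(res.rate_per_min - rate_true) / rate_true < 0.01
            assert res.rmse_mg_per_g < 1e-3

    def test_noisy_recovery_coverage(self):
        """SD 0.05 mg/g, 8 points: De within 15% in ≥ 90% of 20 seeds and
        R² > 0.95 throughout."""
        times = (2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0)
        hits, r2s = 0, []
        for seed in range(20):
            ds, tc = _single_condition_dataset(0.01, 2.4, times, noise_sd=0.05,
                                               seed=seed)
            res = fit_de(ds.frame, total_content_mg_per_g=tc)
            hits += abs(res.rate_per_min - 0.01) / 0.01 < 0.15
            r2s.append(res.r_squared)
        assert hits >= 18
        assert min(r2s) > 0.95

    def test_optimizer_beats_bound_scan(self):
        """The optimum RMSE is no worse than the best of a 20-point scan of
        the objective over the search bounds."""
        times = (2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0, 30.0)
        ds, tc = _single_condition_dataset(0.01, 2.4, times, noise_sd=0.05, seed=3)
        res = fit_de(ds.frame, total_content_mg_per_g=tc)
        from phenolflux.fitting import _model_yield
        from phenolflux.diffusion import ParticleSpec, SuspensionSpec

        data = ds.frame[ds.frame.time_min > 0]
        t, y = data.time_min.to_numpy(), data.yield_mg_per_g.to_numpy()
        cs0 = tc / 1000.0
        scan = np.linspace(*res.log10_rate_bounds, 20)
        vals = [rmse(_model_yield(10**g, t, ParticleSpec(), SuspensionSpec(),
                                  cs0, 1.0, 101), y) for g in scan]
        assert res.rmse_mg_per_g <= min(vals) + 1e-12

    def test_flat_data_hits_upper_bound(self):
        """Observations already at equilibrium for all t>0 imply infinitely
        fast diffusion: the optimum lands on the upper bound, flagged."""
        eq = 2.4
        frame = pd.DataFrame({
            "temperature_C": 40.0, "enzyme_pct": 0.5, "method": "US",
            "time_min": [2.5, 5.0, 10.0, 20.0, 30.0],
            "yield_mg_per_g": [eq] * 5,
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_de(frame, total_content_mg_per_g=eq * 11 / 10)
        assert not res.converged
        assert np.log10(res.rate_per_min) == pytest.approx(
            res.log10_rate_bounds[1], abs=0.01)

    def test_too_few_points_rejected(self):
        frame = pd.DataFrame({
            "temperature_C": 40.0, "enzyme_pct": 0.5, "method": "US",
            "time_min": [2.5, 5.0, 10.0],
            "yield_mg_per_g": [1.0, 1.5, 1.8],
        })
        with pytest.raises(ValueError):
            fit_de(frame)


class TestFitAllConditions:
    def test_synthetic_conditions_all_converge_and_order_preserved(self):
        """Noiseless 6-condition fit: every row converges and the fitted De
        preserves the generator's orderings (rising with enzyme dose at fixed
        temperature, falling from 40 to 50 °C)."""
        cfg = GeneratorConfig(seed=5, noise_sd=0.0)
        ds, _ = simulate_kinetics(cfg)
        tc = {k: v["extractable_mg_per_g"] for k, v in default_truth(cfg).items()}
        fits = fit_all_conditions(ds, total_content_mg_per_g=tc)
        assert len(fits) == 6
        assert fits["converged"].all()
        by_key = fits.set_index(["temperature_C", "enzyme_pct"])["rate_per_min"]
        for temp in (40.0, 50.0):
            assert by_key[(temp, 0.0)] < by_key[(temp, 0.5)] < by_key[(temp, 1.0)]
        for enz in (0.0, 0.5, 1.0):
            assert by_key[(40.0, enz)] > by_key[(50.0, enz)]

    def test_empty_dataset_warns_and_returns_empty(self):
        empty = KineticDataset(pd.DataFrame(columns=[
            "temperature_C", "enzyme_pct", "method", "time_min", "yield_mg_per_g"]))
        with pytest.warns(UserWarning):
            fits = fit_all_conditions(empty)
        assert len(fits) == 0

    def test_per_condition_failure_isolated(self):
        cfg = GeneratorConfig(seed=2, noise_sd=0.0, temperatures=(40.0,),
                              enzyme_levels=(0.0, 0.5))
        ds, _ = simulate_kinetics(cfg)
        # cripple one condition: keep only 2 points
        f = ds.frame
        keep = ~((f.enzyme_pct == 0.0) & (f.time_min > 7.5))
        ds2 = KineticDataset(f[keep])
        tc = {k: v["extractable_mg_per_g"] for k, v in default_truth(cfg).items()}
        fits = fit_all_conditions(ds2, total_content_mg_per_g=tc)
        assert len(fits) == 2
        failed = fits[fits.enzyme_pct == 0.0].iloc[0]
        good = fits[fits.enzyme_pct == 0.5].iloc[0]
        assert failed["error"] != "" and not failed["converged"]
        assert good["error"] == "" and good["converged"]


class TestKineticDataset:
    def test_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=9)
        ds, _ = simulate_kinetics(cfg)
        path = tmp_path / "k.csv"
        ds.to_csv(path)
        back = KineticDataset.from_csv(path)
        pd.testing.assert_frame_equal(ds.frame, back.frame)

    def test_validation(self):
        with pytest.raises(ValueError):
            KineticDataset(pd.DataFrame({"time_min": [1.0]}))
        bad = pd.DataFrame({
            "temperature_C": [40.0, 40.0], "enzyme_pct": [0.5, 0.5],
            "method": ["US", "US"], "time_min": [5.0, 5.0],
            "yield_mg_per_g": [1.0, 1.1],
        })
        with pytest.raises(ValueError):
            KineticDataset(bad)
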
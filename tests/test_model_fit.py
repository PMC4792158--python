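"""Linear and sigmoid least-squares fitting, grids, block-wise trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srtlearn.model_fit import (
    blockwise_sigmoid,
    compare_predictors_sessionwise,
    compare_predictors_trialwise,
    fit_linear,
    fit_sigmoid,
    median_rt,
)
from srtlearn.rt_synth import SigmoidParams, sigmoid_rt


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = fit_linear(x, 2 * x + 1)
        assert res.params["slope"] == pytest.approx(2.0, abs=1e-12)
        assert res.params["intercept"] == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_covariance_gives_zero_slope(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = x ** 2  # even function: orthogonal to x
        res = fit_linear(x, y)
        assert res.params["slope"] == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_normal_equations(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 3.0 * x - 2.0 + rng.normal(size=200)
        res = fit_linear(x, y)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.params["slope"] == pytest.approx(beta[0], abs=1e-10)
        assert res.params["intercept"] == pytest.approx(beta[1], abs=1e-10)

    def test_noisy_line_estimates_within_3se(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 1000)
        y = 2.0 * x + 1.0 + rng.normal(0, 2.0, 1000)
        res = fit_linear(x, y)
        assert abs(res.params["slope"] - 2.0) < 3 * res.param_se["slope"]
        assert abs(res.params["intercept"] - 1.0) < 3 * res.param_se["intercept"]

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_linear(np.ones(5), np.arange(5.0))


TRUE = SigmoidParams(xhalf=3.0, ymax=480.0, ymin=250.0, slope=1.0)


class TestFitSigmoid:
    def test_noise_free_exact_recovery(self):
        x = np.linspace(0, 7, 60)
        y = sigmoid_rt(x, TRUE)
        res = fit_sigmoid(x, y)
        assert res.converged
        for name in ("xhalf", "ymax", "ymin", "slope"):
            assert res.params[name] == pytest.approx(getattr(TRUE, name), abs=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_fixed_slope_recovery_within_3se(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0.5, 6.5, 48)
        y = sigmoid_rt(x, TRUE) * np.exp(rng.normal(0, 0.03, x.size))
        res = fit_sigmoid(x, y, fixed={"slope": 1.0})
        assert res.converged and res.params["slope"] == 1.0
        for name in ("xhalf", "ymax", "ymin"):
            assert abs(res.params[name] - getattr(TRUE, name)) < \
                3 * res.param_se[name]

    def test_decreasing_orientation_recovery(self):
        x = np.linspace(0, 1, 50)
        p = SigmoidParams(xhalf=0.3, ymax=480.0, ymin=280.0, slope=0.08)
        y = sigmoid_rt(x, p, "decreasing")
        res = fit_sigmoid(x, y, orientation="decreasing")
        assert res.converged
        assert res.params["xhalf"] == pytest.approx(0.3, abs=1e-5)

    def test_constant_y_degenerate_flagged(self):
        res = fit_sigmoid(np.linspace(0, 5, 20), np.full(20, 300.0))
        assert not res.converged

    def test_deterministic_restarts(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 7, 48)
        y = sigmoid_rt(x, TRUE) + rng.normal(0, 10, 48)
        a, b = fit_sigmoid(x, y), fit_sigmoid(x, y)
        assert a.params == b.params and a.rss == b.rss

    def test_mean_r2_sigmoid_exceeds_linear_on_sigmoid_data(self):
        """Over replicates of noisy sigmoid data the sigmoid explains more
        variance than the line on average."""
        rng = np.random.default_rng(4)
        x = np.linspace(0.5, 6.5, 48)
        diffs = []
        for _ in range(50):
            y = sigmoid_rt(x, TRUE) * np.exp(rng.normal(0, 0.05, x.size))
            diffs.append(fit_sigmoid(x, y).r_squared - fit_linear(x, y).r_squared)
        assert np.mean(diffs) > 0


class TestMedianRT:
    def test_odd_count_middle_value(self):
        t = pd.DataFrame({"g": ["a"] * 3, "rt_ms": [200.0, 300.0, 400.0],
                          "correct": True})
        assert median_rt(t, "g")["median_rt"].iloc[0] == 300.0

    def test_robust_to_tail_outlier(self):
        t = pd.DataFrame({"g": ["a"] * 5, "rt_ms": [200, 250, 300, 350, 2900.0],
                          "correct": True})
        assert median_rt(t, "g")["median_rt"].iloc[0] == 300.0

    def test_incorrect_trials_excluded(self):
        t = pd.DataFrame({"g": ["a"] * 4, "rt_ms": [100.0, 300.0, 300.0, 300.0],
                          "correct": [False, True, True, True]})
        assert median_rt(t, "g")["median_rt"].iloc[0] == 300.0

    def test_agrees_with_sort_based_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            vals = rng.uniform(100, 900, n)
            t = pd.DataFrame({"g": ["u"] * n, "rt_ms": vals, "correct": True})
            got = median_rt(t, "g")["median_rt"].iloc[0]
            s = np.sort(vals)
            oracle = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
            assert got == pytest.approx(oracle, abs=1e-12)


def _session_units(rng, n=48, sigma=0.03):
    je3 = np.linspace(1.0, 6.7, n)
    y = sigmoid_rt(je3, TRUE) * np.exp(rng.normal(0, sigma, n))
    return pd.DataFrame({
        "unit": [str(i) for i in range(n)], "median_rt": y,
        "je_1": je3 / 2, "ce_1": je3 / 3, "je_3": je3, "ce_3": je3 / 2,
    })


class TestComparisonGrids:
    def test_sessionwise_best_cell_matches_generator(self):
        units = _session_units(np.random.default_rng(6))
        grid = compare_predictors_sessionwise(units, n_prev_range=(1, 3))
        best = grid.loc[grid["r_squared"].idxmax()]
        assert (best["predictor"], best["function"]) == ("JE", "sigmoid")

    def test_sessionwise_too_few_units_rejected(self):
        units = _session_units(np.random.default_rng(7)).head(3)
        with pytest.raises(ValueError):
            compare_predictors_sessionwise(units, n_prev_range=(1,))

    def test_degenerate_constant_predictor_flagged_not_raised(self):
        units = _session_units(np.random.default_rng(8))
        units["ce_1"] = 0.0  # all-deterministic sequence set
        grid = compare_predictors_sessionwise(units, n_prev_range=(1,))
        ce_cells = grid[grid["predictor"] == "CE"]["r_squared"]
        assert ce_cells.isna().all()

    def test_trialwise_grid_deterministic(self, exp1_sim):
        from srtlearn.pipeline import attach_trial_predictors
        from srtlearn.sequence_gen import preset_spec
        sub = exp1_sim[exp1_sim["subject_id"].isin(["s01", "s09"])]
        specs = {s: preset_spec(g) for s, g in
                 sub.groupby("subject_id")["group"].first().items()}
        t = attach_trial_predictors(sub, specs, (1,))
        g1 = compare_predictors_trialwise(t, n_prev_range=(1,))
        g2 = compare_predictors_trialwise(t, n_prev_range=(1,))
        pd.testing.assert_frame_equal(g1, g2)

    def test_trialwise_empty_window_rejected(self, exp1_sim):
        with pytest.raises(ValueError, match="empty"):
            compare_predictors_trialwise(exp1_sim.head(10), n_prev_range=(1,))


class TestBlockwise:
    def _trials(self, rng, drift=True, n_units=48, sigma=0.25):
        from srtlearn.rt_synth import DEFAULT_START, learning_trajectory
        je = np.linspace(1.0, 6.7, n_units)
        rows = []
        for b in range(5, 23):
            p = learning_trajectory(b) if drift else DEFAULT_START
            m = sigmoid_rt(je, p)
            for u in range(n_units):
                rts = m[u] * np.exp(rng.normal(0, sigma, 49))
                rows.append(pd.DataFrame({
                    "unit": str(u), "block": b, "rt_ms": rts, "correct": True}))
        return pd.concat(rows), pd.Series(je, index=[str(u) for u in range(n_units)])

    def test_drifting_xhalf_recovered_monotone(self):
        trials, je = self._trials(np.random.default_rng(9))
        traj = blockwise_sigmoid(trials, je)
        ok = traj[traj["converged"]]
        assert len(ok) >= 16
        assert stats.spearmanr(ok["block"], ok["xhalf"]).statistic > 0.9
        assert stats.spearmanr(ok["block"], ok["ymin"]).statistic < -0.9

    def test_flat_params_recovered_flat_within_se(self):
        trials, je = self._trials(np.random.default_rng(10), drift=False,
                                  sigma=0.05)
        traj = blockwise_sigmoid(trials, je)
        ok = traj[traj["converged"]]
        from srtlearn.rt_synth import DEFAULT_START
        inside = np.abs(ok["xhalf"] - DEFAULT_START.xhalf) < 3 * ok["xhalf_se"]
        assert inside.mean() > 0.9

    def test_too_few_entropy_values_rejected(self):
        trials, _ = self._trials(np.random.default_rng(11), n_units=4)
        with pytest.raises(ValueError):
            blockwise_sigmoid(trials, pd.Series([1.0, 1.0, 2.0, 2.0],
                                                index=list("0123")))
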
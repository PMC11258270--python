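"""SEM preprocessing, the weighted cost, chi-square gating, annealing
search and envelope prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaincinv

from gluchip.calibration import (
    FitConfig,
    GTTDataset,
    chi2_threshold,
    cost,
    fit,
    predict_envelope,
    preprocess_sem,
)
from gluchip.protocol import gtt_study_protocol, simulate
from gluchip.studies import STUDY_SOLVER


def make_dataset(rows, condition="c", nominal=None):
    return GTTDataset(condition, pd.DataFrame(rows, columns=["signal", "time_h", "mean", "sem", "n", "gtt_window"]),
                      nominal or {})


class TestPreprocessSem:
    def test_small_sems_floored_to_scope_maximum(self):
        ds = make_dataset(
            [("glucose", 0.0, 10.0, 0.4, 3, ""), ("glucose", 8.0, 20.0, 3.0, 3, "")]
        )
        out = preprocess_sem(ds)
        assert out.table["sem"].tolist() == [3.0, 3.0]  # 0.4 < 0.5 is unrealistic

    def test_realistic_sems_untouched_without_offsets(self):
        rows = [("glucose", 0.0, 10.0, 0.9, 3, ""), ("glucose", 8.0, 20.0, 3.0, 3, "")]
        out = preprocess_sem(make_dataset(rows))
        assert out.table["sem"].tolist() == [0.9, 3.0]

    def test_measured_start_offset_added_to_window_sems(self):
        rows = [
            ("glucose", 0.0, 12.0, 1.0, 3, "day1"),
            ("glucose", 8.0, 9.0, 1.0, 3, "day1"),
            ("glucose", 24.0, 7.0, 1.0, 3, "day1"),
        ]
        out = preprocess_sem(make_dataset(rows, nominal={("day1", "glucose"): 11.0}))
        # measured 12 vs dosed 11 -> +1 on every SEM of the window
        assert out.table["sem"].tolist() == [2.0, 2.0, 2.0]

    def test_all_zero_sems_rejected(self):
        ds = make_dataset([("glucose", 0.0, 10.0, 0.0, 3, ""), ("glucose", 8.0, 5.0, 0.0, 3, "")])
        with pytest.raises(ValueError, match="floor undefined"):
            preprocess_sem(ds)

    def test_dataset_scope_pools_signals(self):
        rows = [("glucose", 0.0, 10.0, 0.1, 3, ""), ("insulin", 0.0, 100.0, 9.0, 3, "")]
        per_signal = preprocess_sem(make_dataset(rows), scope="signal")
        pooled = preprocess_sem(make_dataset(rows), scope="dataset")
        assert per_signal.table["sem"].tolist() == [0.1, 9.0]
        assert pooled.table["sem"].tolist() == [9.0, 9.0]


@pytest.fixture(scope="module")
def sim_setup(params_h2):
    proto = gtt_study_protocol(11.0, gtt_days=(1, 7))
    r = simulate(params_h2, proto, STUDY_SOLVER)
    rows = []
    for sig, vals in (("glucose", r.pooled_glucose), ("insulin", r.pooled_insulin)):
        for t, w, v in zip(r.times, r.windows, vals):
            rows.append((sig, float(t), float(v), 1.0, 3, w))
    return proto, make_dataset(rows)


@pytest.fixture(scope="module")
def tiny_problem(params_h1):
    """Noiseless single-window dataset with two free parameters."""
    proto = gtt_study_protocol(11.0, gtt_days=(1,), duration_days=3)
    truth = params_h1.set({"fast.S_I0": 0.05, "fast.sigma_max": 1.5e6})
    r = simulate(truth, proto, STUDY_SOLVER)
    rows = []
    for sig, vals in (("glucose", r.pooled_glucose), ("insulin", r.pooled_insulin)):
        for t, w, v in zip(r.times, r.windows, vals):
            rows.append((sig, float(t), float(v), 1.0, 3, w))
    free = {"fast.S_I0": (1e-3, 1.0), "fast.sigma_max": (1e5, 4e7)}
    return make_dataset(rows), proto, truth, free


class TestCost:
    def test_zero_for_noiseless_data(self, params_h2, sim_setup):
        proto, ds = sim_setup
        assert cost(params_h2, [ds], [proto], STUDY_SOLVER) == pytest.approx(0.0, abs=1e-8)

    def test_one_sem_residual_per_point_counts_points(self, params_h2, sim_setup):
        proto, ds = sim_setup
        tab = ds.table.copy()
        tab["mean"] = tab["mean"] + tab["sem"]
        shifted = GTTDataset(ds.condition, tab, {})
        assert cost(params_h2, [shifted], [proto], STUDY_SOLVER) == pytest.approx(ds.n_points, rel=1e-6)

    def test_matches_naive_resummation(self, params_h2, sim_setup):
        proto, ds = sim_setup
        rng = np.random.default_rng(3)
        tab = ds.table.copy()
        tab["mean"] = tab["mean"] * (1 + 0.1 * rng.standard_normal(len(tab)))
        tab["sem"] = rng.uniform(0.5, 2.0, len(tab))
        noisy = GTTDataset(ds.condition, tab, {})
        got = cost(params_h2, [noisy], [proto], STUDY_SOLVER)
        # naive independent re-summation straight off the simulation output
        r = simulate(params_h2, proto, STUDY_SOLVER)
        sim_vals = {("glucose", t): v for t, v in zip(r.times, r.pooled_glucose)}
        sim_vals |= {("insulin", t): v for t, v in zip(r.times, r.pooled_insulin)}
        expected = sum(
            (row["mean"] - sim_vals[(row["signal"], row["time_h"])]) ** 2 / row["sem"] ** 2
            for _, row in tab.iterrows()
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_row_reordering(self, params_h2, sim_setup):
        proto, ds = sim_setup
        tab = ds.table.copy()
        tab["mean"] += 0.5
        shuffled = GTTDataset(ds.condition, tab.sample(frac=1, random_state=1).reset_index(drop=True), {})
        plain = GTTDataset(ds.condition, tab, {})
        assert cost(params_h2, [shuffled], [proto], STUDY_SOLVER) == pytest.approx(
            cost(params_h2, [plain], [proto], STUDY_SOLVER), rel=1e-12
        )

    def test_sem_scaling_rescales_cost(self, params_h2, sim_setup):
        proto, ds = sim_setup
        tab = ds.table.copy()
        tab["mean"] += 1.0
        base = cost(params_h2, [GTTDataset("c", tab, {})], [proto], STUDY_SOLVER)
        tab2 = tab.copy()
        tab2["sem"] *= 2.0
        halved = cost(params_h2, [GTTDataset("c", tab2, {})], [proto], STUDY_SOLVER)
        assert halved == pytest.approx(base / 4.0, rel=1e-9)

    def test_unmatched_time_point_rejected(self, params_h2, sim_setup):
        proto, ds = sim_setup
        tab = ds.table.copy()
        tab.loc[0, "time_h"] = 3.21
        with pytest.raises(ValueError, match="no simulated value"):
            cost(params_h2, [GTTDataset("c", tab, {})], [proto], STUDY_SOLVER)


class TestChi2Threshold:
    def test_printed_rejection_thresholds(self):
        assert chi2_threshold(25, 0.05) == pytest.approx(37.65, abs=5e-3)
        assert chi2_threshold(6, 0.05) == pytest.approx(12.59, abs=5e-3)

    def test_monotone_in_df_and_alpha(self):
        assert chi2_threshold(10) > chi2_threshold(5)
        assert chi2_threshold(10, 0.01) > chi2_threshold(10, 0.10)

    def test_quantile_vanishes_as_alpha_approaches_one(self):
        assert chi2_threshold(1, 1 - 1e-12) < 1e-10

    def test_agrees_with_incomplete_gamma_inverse(self):
        for df in (1, 3, 6, 25, 100):
            expected = 2.0 * gammaincinv(df / 2.0, 0.95)
            assert chi2_threshold(df, 0.05) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("df,alpha", [(0, 0.05), (-1, 0.05), (5, 0.0), (5, 1.0), (2.5, 0.05)])
    def test_invalid_inputs_rejected(self, df, alpha):
        with pytest.raises(ValueError):
            chi2_threshold(df, alpha)


class TestFit:
    def test_recovers_truth_from_noiseless_data(self, params_h1, tiny_problem):
        ds, proto, truth, free = tiny_problem
        cfg = FitConfig(free=free, n_restarts=2, n_iter=120, seed=0, solver_cfg=STUDY_SOLVER)
        ens = fit([ds], [proto], params_h1, cfg)
        assert ens.acceptable
        assert ens.optimum_params.fast.S_I0 == pytest.approx(truth.fast.S_I0, rel=0.05)
        assert ens.optimum_params.fast.sigma_max == pytest.approx(truth.fast.sigma_max, rel=0.05)

    def test_infinite_threshold_accepts_every_evaluation(self, params_h1, tiny_problem, monkeypatch):
        import gluchip.calibration as cal

        ds, proto, _, free = tiny_problem
        cfg = FitConfig(free=free, n_restarts=1, n_iter=30, seed=1,
                        solver_cfg=STUDY_SOLVER, polish=False)
        monkeypatch.setattr(cal, "chi2_threshold", lambda df, alpha=0.05: np.inf)
        ens = fit([ds], [proto], params_h1, cfg)
        assert len(ens.costs) == ens.n_evaluations

    def test_same_seed_reproduces_ensemble(self, params_h1, tiny_problem):
        ds, proto, _, free = tiny_problem
        cfg = FitConfig(free=free, n_restarts=1, n_iter=40, seed=7, solver_cfg=STUDY_SOLVER)
        e1 = fit([ds], [proto], params_h1, cfg)
        e2 = fit([ds], [proto], params_h1, cfg)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)
        np.testing.assert_array_equal(e1.costs, e2.costs)

    def test_bounds_and_threshold_respected(self, params_h1, tiny_problem):
        ds, proto, _, free = tiny_problem
        cfg = FitConfig(free=free, n_restarts=2, n_iter=60, seed=3, solver_cfg=STUDY_SOLVER)
        ens = fit([ds], [proto], params_h1, cfg)
        assert np.all(ens.costs <= ens.threshold)
        for j, name in enumerate(ens.names):
            lo, hi = free[name]
            assert np.all(ens.vectors[:, j] >= lo) and np.all(ens.vectors[:, j] <= hi)


class TestPredictEnvelope:
    def test_singleton_ensemble_collapses_band(self, params_h1, gtt_protocol):
        from gluchip.studies import _singleton_ensemble

        ens = _singleton_ensemble(params_h1)
        env = predict_envelope(ens, gtt_protocol, STUDY_SOLVER)
        np.testing.assert_allclose(env.glucose_lower, env.glucose_upper)
        np.testing.assert_allclose(env.glucose_lower, env.glucose_central)

    def test_band_contains_central_trajectory(self, params_h1, gtt_protocol, tiny_ensemble):
        env = predict_envelope(tiny_ensemble, gtt_protocol, STUDY_SOLVER)
        assert np.all(env.glucose_lower <= env.glucose_central + 1e-12)
        assert np.all(env.glucose_central <= env.glucose_upper + 1e-12)
        assert np.all(env.insulin_lower <= env.insulin_upper + 1e-12)

    def test_per_parameter_extremes_match_exhaustive_band(self, params_h1, gtt_protocol, tiny_ensemble):
        """When the members attaining per-parameter extremes exhaust the
        ensemble, the shortcut equals brute-force simulation of all."""
        short = predict_envelope(tiny_ensemble, gtt_protocol, STUDY_SOLVER, full=False)
        full = predict_envelope(tiny_ensemble, gtt_protocol, STUDY_SOLVER, full=True)
        np.testing.assert_allclose(short.glucose_lower, full.glucose_lower)
        np.testing.assert_allclose(short.glucose_upper, full.glucose_upper)

    def test_empty_acceptable_set_rejected(self, params_h1, gtt_protocol):
        from gluchip.calibration import ParameterEnsemble

        empty = ParameterEnsemble(
            names=["fast.S_I0"], vectors=np.empty((0, 1)), costs=np.array([]),
            threshold=1.0, base_params=params_h1, best_vector=np.array([0.05]),
            best_cost=99.0, seed=0, n_evaluations=10,
        )
        with pytest.raises(ValueError, match="empty"):
            predict_envelope(empty, gtt_protocol)


@pytest.fixture(scope="module")
def tiny_ensemble(params_h1):
    """Two-member toy ensemble whose members are the per-parameter
    extremes (each member attains one min and one max)."""
    from gluchip.calibration import ParameterEnsemble

    names = ["fast.S_I0", "fast.sigma_max"]
    vectors = np.array([[0.02, 2.5e6], [0.05, 1.5e6]])
    return ParameterEnsemble(
        names=names, vectors=vectors, costs=np.array([1.0, 2.0]), threshold=10.0,
        base_params=params_h1, best_vector=vectors[0], best_cost=1.0, seed=0,
        n_evaluations=2,
    )
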
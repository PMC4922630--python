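import numpy as np
import pandas as pd
import pytest

from nettrans.calibration import (
    calibrate_costs,
    empirical_net_from_longitudinal,
    empirical_net_table,
    project_surface,
    validate_longitudinal,
    validate_stability,
)
from nettrans.prevalence import fit_prevalence
from nettrans.synthetic import make_truth, sample_cross_section, simulate_trajectories
from nettrans.transport import nets_from_prevalence


def toy_trajectories(moves_up=10, moves_down=3, n_normal=100, n_over=40, n_obese=20):
    rows = []
    for i in range(n_normal):
        rows += [("n%d" % i, 18, 1), ("n%d" % i, 19, 2 if i < moves_up else 1)]
    for i in range(n_over):
        rows += [("o%d" % i, 18, 2), ("o%d" % i, 19, 1 if i < moves_down else 2)]
    for i in range(n_obese):
        rows += [("b%d" % i, 18, 3), ("b%d" % i, 19, 3)]
    return pd.DataFrame(rows, columns=["id", "age", "category"])


class TestEmpiricalNets:
    def test_worked_example_seven_percent(self):
        table = empirical_net_from_longitudinal(toy_trajectories(), 18)
        probs = table.set_index(["boundary", "direction"])["net_prob"]
        assert probs[("normal_overweight", "up")] == pytest.approx(0.07, abs=1e-12)
        assert probs[("normal_overweight", "down")] == 0.0
        assert table["net_count"].max() == pytest.approx(7.0)

    def test_static_cohort_all_zero(self):
        table = empirical_net_from_longitudinal(toy_trajectories(0, 0), 18)
        assert (table["net_prob"] == 0).all()

    def test_hand_count_two_step_moves_cross_both_boundaries(self):
        df = pd.DataFrame(
            [("a", 10, 1), ("a", 11, 3), ("b", 10, 2), ("b", 11, 2), ("c", 10, 3), ("c", 11, 3)],
            columns=["id", "age", "category"],
        )
        table = empirical_net_from_longitudinal(df, 10)
        probs = table.set_index(["boundary", "direction"])["net_prob"]
        assert probs[("normal_overweight", "up")] == pytest.approx(1.0)  # 1 of 1 normal
        assert probs[("overweight_obese", "up")] == pytest.approx(1.0)  # net 1 / 1 overweight

    def test_no_paired_observations_empty(self):
        df = pd.DataFrame([("a", 10, 1), ("a", 15, 2)], columns=["id", "age", "category"])
        assert empirical_net_from_longitudinal(df, 10).empty

    def test_simulated_markov_within_binomial_noise(self, truth_early):
        n = 30_000
        traj = simulate_trajectories(truth_early, n, seed=21, start_age=2, end_age=40)
        true = truth_early.true_net_probs()
        P = truth_early.prevalence()
        origin = {("normal_overweight", "up"): 0, ("normal_overweight", "down"): 1,
                  ("overweight_obese", "up"): 1, ("overweight_obese", "down"): 2}
        table = empirical_net_table(traj, ages=[5, 20, 30])
        for row in table.itertuples():
            b = 0 if row.boundary == "normal_overweight" else 1
            d = 0 if row.direction == "up" else 1
            tv = true[row.age - 2, b, d]
            n_origin = row.n_pairs * P[row.age - 2, origin[(row.boundary, row.direction)]]
            se = np.sqrt(max(tv * (1 - tv), 1e-4) / n_origin)
            assert abs(row.net_prob - tv) < 3 * se + 1e-3

    def test_rejects_nonincreasing_ages(self):
        df = pd.DataFrame([("a", 11, 1), ("a", 10, 1)], columns=["id", "age", "category"])
        with pytest.raises(ValueError, match="strictly increasing"):
            validate_longitudinal(df.sort_values("age", ascending=False))


@pytest.fixture(scope="module")
def calib_inputs(truth_early):
    traj = simulate_trajectories(truth_early, 3000, seed=8)
    emp = empirical_net_table(traj)
    return emp, truth_early.ages, truth_early.prevalence()


class TestCalibrateCosts:

    def test_valid_candidates_tie_and_first_wins(self, calib_inputs):
        emp, ages, P = calib_inputs
        res = calibrate_costs(emp, ages, P, [(1, 3), (6, 17), (10, 25)])
        valid = res.profile[res.profile.valid]
        assert valid["mse"].max() - valid["mse"].min() < 1e-9
        assert res.best_constants == (0.0, 1.0, 3.0)  # documented tie-break: grid order

    def test_invalid_candidate_flagged_not_fitted(self, calib_inputs):
        emp, ages, P = calib_inputs
        res = calibrate_costs(emp, ages, P, [(6, 11), (6, 17)])
        row = res.profile[(res.profile.c1 == 6) & (res.profile.c2 == 11)].iloc[0]
        assert not row["valid"] and np.isnan(row["mse"])
        assert res.best_constants == (0.0, 6.0, 17.0)

    def test_default_cost_triple_accepted(self, calib_inputs):
        emp, ages, P = calib_inputs
        res = calibrate_costs(emp, ages, P, [(6, 17)])
        assert res.profile["valid"].all()

    def test_empty_valid_grid_errors(self, calib_inputs):
        emp, ages, P = calib_inputs
        with pytest.raises(ValueError, match="no valid"):
            calibrate_costs(emp, ages, P, [(6, 11)])


class TestStability:
    def test_horizon_zero_predicts_observed(self, fitted_curve):
        P = fitted_curve.P
        assert np.allclose(project_surface(P, nets_from_prevalence(P), 0), P)

    def test_projection_shifts_by_horizon(self, fitted_curve):
        # self-projection: predicting age a+h from age a reproduces the curve at a+h
        P = fitted_curve.P
        pred = project_surface(P, nets_from_prevalence(P), 3)
        assert np.allclose(pred, P[3:], atol=1e-12)

    def test_null_passes_and_drift_flagged(self, truth_early):
        drift = truth_early.with_drift(1.5)
        early = fit_prevalence(
            sample_cross_section(truth_early, n=7000, seed=1, emit_anthropometry=False), stratum="e"
        )
        late_null = fit_prevalence(
            sample_cross_section(truth_early, n=7000, seed=2, emit_anthropometry=False), stratum="l0"
        )
        late_drift = fit_prevalence(
            sample_cross_section(drift, n=7000, seed=3, emit_anthropometry=False), stratum="l1"
        )
        rep = validate_stability(early, {"null": late_null, "drift": late_drift}, horizon=2, seed=4)
        s = rep.summary.set_index("cycle")
        assert bool(s.loc["null", "stable"])
        assert not bool(s.loc["drift", "stable"])
        assert s.loc["drift", "mean_abs_error"] > s.loc["null", "mean_abs_error"]

    def test_discrepancies_within_bounds(self, truth_early):
        early = fit_prevalence(
            sample_cross_section(truth_early, n=5000, seed=11, emit_anthropometry=False), stratum="e"
        )
        later = fit_prevalence(
            sample_cross_section(truth_early, n=5000, seed=12, emit_anthropometry=False), stratum="l"
        )
        rep = validate_stability(early, {"later": later}, horizon=2, seed=13)
        assert rep.details["discrepancy"].between(-1, 1).all()

    def test_grid_mismatch_errors(self, truth_early, fitted_curve):
        import copy

        other = copy.copy(fitted_curve)
        other.ages = fitted_curve.ages[:-1]
        other.P = fitted_curve.P[:-1]
        with pytest.raises(ValueError, match="age grid"):
            validate_stability(fitted_curve, {"bad": other}, horizon=1)
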
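import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linprog

from nettrans.transport import (
    BOUNDARIES,
    CostMatrix,
    InfeasibleMarginals,
    closed_form_net,
    monotone_plan,
    net_prob_array,
    net_probabilities,
    net_table_from_curve,
    nets_from_prevalence,
    project_forward,
    solve_transport,
)


def brute_force_nets(p, q, constants=(0.0, 6.0, 17.0)):
    """Independent 9-variable LP oracle, assembled from scratch in the test."""
    k = 3
    idx = np.arange(k)
    c = np.asarray(constants)[np.abs(idx[:, None] - idx[None, :])].ravel()
    a_eq, b_eq = [], []
    for i in range(k):
        row = np.zeros(9)
        row[i * k : (i + 1) * k] = 1
        a_eq.append(row)
        b_eq.append(p[i])
    for j in range(k):
        row = np.zeros(9)
        row[j::k] = 1
        a_eq.append(row)
        b_eq.append(q[j])
    res = linprog(c, A_eq=np.array(a_eq), b_eq=np.array(b_eq), bounds=(0, None), method="highs")
    assert res.success
    x = res.x.reshape(3, 3)
    return np.array(
        [x[0, 1:].sum() - x[1:, 0].sum(), x[:2, 2].sum() - x[2, :2].sum()]
    ), float(res.fun)


class TestCostMatrix:
    def test_default_constants_valid(self):
        cm = CostMatrix()
        assert cm.constants == (0.0, 6.0, 17.0)
        assert cm.matrix[0, 2] == 17.0

    @pytest.mark.parametrize("constants", [(0, 6, 11), (0, 6, 12), (6, 6, 17), (0, 0, 1)])
    def test_invalid_economy_of_movement(self, constants):
        with pytest.raises(ValueError, match="economy-of-movement"):
            CostMatrix(constants=constants)

    def test_cost_depends_only_on_step_distance(self):
        m = CostMatrix(constants=(0, 1, 3)).matrix
        assert m[0, 1] == m[1, 0] == m[1, 2] == m[2, 1] == 1


class TestSolveTransport:
    def test_identity_when_marginals_equal(self):
        p = np.array([0.4, 0.35, 0.25])
        plan = solve_transport(p, p)
        assert np.allclose(plan.flows, np.diag(p), atol=1e-12)
        assert plan.cost == pytest.approx(0.0, abs=1e-12)

    def test_small_upward_shift(self):
        p, q = [0.6, 0.3, 0.1], [0.55, 0.32, 0.13]
        plan = solve_transport(p, q)
        expected = np.array([[0.55, 0.05, 0], [0, 0.27, 0.03], [0, 0, 0.1]])
        assert np.allclose(plan.flows, expected, atol=1e-9)
        assert plan.cost == pytest.approx(0.48, abs=1e-9)

    def test_downward_shift(self):
        p, q = [0.2, 0.3, 0.5], [0.3, 0.3, 0.4]
        plan = solve_transport(p, q)
        assert plan.flows[1, 0] == pytest.approx(0.10, abs=1e-9)
        assert plan.flows[2, 1] == pytest.approx(0.10, abs=1e-9)
        assert np.allclose(plan.net_flows(), [-0.10, -0.10], atol=1e-9)

    def test_cascade_through_middle_category(self):
        # all mass moves one boundary up; no direct two-step assignment needed
        plan = solve_transport([0.5, 0.5, 0.0], [0.0, 0.5, 0.5])
        assert np.allclose(plan.net_flows(), [0.5, 0.5], atol=1e-12)
        assert plan.flows[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_mass_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p, q = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
            plan = solve_transport(p, q)
            assert np.allclose(plan.flows.sum(axis=1), plan.p, atol=1e-9)
            assert np.allclose(plan.flows.sum(axis=0), plan.q, atol=1e-9)

    def test_infeasible_marginals_error(self):
        with pytest.raises(InfeasibleMarginals):
            solve_transport([0.5, 0.3, 0.2], [0.6, 0.3, 0.2])

    def test_small_mismatch_renormalized(self):
        plan = solve_transport([0.5, 0.3, 0.2 + 5e-7], [0.5, 0.3, 0.2])
        assert plan.flows.sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_lp(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p, q = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
            nets_bf, cost_bf = brute_force_nets(p, q)
            plan = solve_transport(p, q)
            assert np.allclose(plan.net_flows(), nets_bf, atol=1e-9)
            assert plan.cost == pytest.approx(cost_bf, abs=1e-9)

    def test_general_k_supported(self):
        cm = CostMatrix(constants=(0.0, 1.0, 3.0, 7.0), k=4)
        p = np.array([0.4, 0.3, 0.2, 0.1])
        q = np.array([0.35, 0.3, 0.2, 0.15])
        plan = solve_transport(p, q, cm)
        assert np.allclose(plan.flows.sum(axis=1), p, atol=1e-9)


class TestClosedForm:
    def test_equal_marginals_zero(self):
        p = np.array([0.3, 0.4, 0.3])
        assert np.allclose(closed_form_net(p, p), 0.0)

    def test_derived_example(self):
        assert np.allclose(closed_form_net([0.6, 0.3, 0.1], [0.55, 0.32, 0.13]), [0.05, 0.03], atol=1e-12)

    def test_cascade(self):
        assert np.allclose(closed_form_net([0.5, 0.5, 0], [0, 0.5, 0.5]), [0.5, 0.5], atol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_oracle_equivalence_random(self, s):
        rng = np.random.default_rng(s)
        p, q = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
        for constants in [(0, 6, 17), (0, 1, 3), (0, 10, 25)]:
            plan = solve_transport(p, q, CostMatrix(constants=constants))
            assert np.allclose(plan.net_flows(), closed_form_net(p, q), atol=1e-9)


class TestNetProbabilities:
    def test_worked_example_counts(self):
        # 100 normal at age 18, net 7 moving up across boundary 1
        p = np.array([100, 40, 20]) / 160
        table = net_probabilities([7 / 160, 0.0], p, age=18)
        up = table[(table.boundary == "normal_overweight") & (table.direction == "up")]
        assert up["net_prob"].iloc[0] == pytest.approx(0.07, abs=1e-12)
        down = table[(table.boundary == "normal_overweight") & (table.direction == "down")]
        assert down["net_prob"].iloc[0] == 0.0

    def test_derived_example_probabilities(self):
        p = np.array([0.6, 0.3, 0.1])
        table = net_probabilities([0.05, 0.03], p)
        probs = table.set_index(["boundary", "direction"])["net_prob"]
        assert probs[("normal_overweight", "up")] == pytest.approx(0.05 / 0.6)
        assert probs[("overweight_obese", "up")] == pytest.approx(0.10)

    def test_zero_over_zero_flagged(self):
        table = net_probabilities([0.0, 0.0], [1.0, 0.0, 0.0])
        assert table.loc[table.direction == "up", "zero_over_zero"].any()

    @given(st.integers(0, 2**32 - 1))
    def test_one_direction_at_a_time_and_scale(self, s):
        rng = np.random.default_rng(s)
        p, q = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
        table = net_probabilities(closed_form_net(p, q), p)
        for b in BOUNDARIES:
            sub = table[table.boundary == b]
            assert sub["net_prob"].min() == 0.0
        assert ((table["net_prob"] >= 0) & (table["net_prob"] <= 1)).all()


class TestProjection:
    def test_exact_inverse(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p, q = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
            nets = closed_form_net(p, q)
            assert np.allclose(project_forward(p, nets), q, atol=1e-12)

    def test_zero_nets_identity(self):
        p = np.array([0.2, 0.5, 0.3])
        assert np.allclose(project_forward(p, [0, 0]), p)

    def test_chained_projection_reproduces_surface(self, fitted_curve):
        P = fitted_curve.P
        nets = nets_from_prevalence(P)
        cur = P[0]
        for t in range(len(P) - 1):
            cur = project_forward(cur, nets[t])
            assert np.allclose(cur, P[t + 1], atol=1e-12)


def test_net_prob_array_matches_table(fitted_curve):
    """Vectorized nets agree with the row-by-row LP table."""
    table = net_table_from_curve(fitted_curve.ages, fitted_curve.P)
    arr = net_prob_array(fitted_curve.P)
    for row in table.itertuples():
        t = int(row.age) - 2
        b = BOUNDARIES.index(row.boundary)
        d = 0 if row.direction == "up" else 1
        assert arr[t, b, d] == pytest.approx(row.net_prob, abs=1e-9)


def test_monotone_plan_is_nw_corner():
    x = monotone_plan([0.5, 0.3, 0.2], [0.2, 0.3, 0.5])
    assert x[0, 0] == pytest.approx(0.2)
    assert x.sum() == pytest.approx(1.0)
    # no crossing flows: x[i,j]>0 and x[k,l]>0 with i<k implies j<=l
    nz = np.argwhere(x > 1e-15)
    for i, j in nz:
        for k, l in nz:
            if i < k:
                assert j <= l
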
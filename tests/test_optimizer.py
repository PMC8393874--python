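"""Assignment solver: exactness, decomposition, feasibility frontier."""

import numpy as np
import pytest
from scipy.optimize import Bounds, LinearConstraint, milp

import carestrat as cs
from carestrat.mckp import solve_mckp
from carestrat.optimizer import (
    _milp_choice,
    brute_force_oracle,
    compute_thresholds,
    solve_condition_scenario,
)
from conftest import manual_scenario_set


class TestSolveConditionScenario:
    def test_single_patient_must_upgrade(self):
        # cheap plan busts the cap; the expensive effective plan is forced
        r = solve_condition_scenario(
            np.array([[10.0, 5.0]]), np.array([[0.1, 0.3]]), mu_star=0.2
        )
        assert r.assignment == (0,)
        assert r.total_cost == 10.0

    def test_two_patients_split_between_plan_types(self):
        costs = np.array([[10.0, 4.0], [10.0, 4.0]])
        mu = np.array([[0.1, 0.25], [0.1, 0.25]])
        r = solve_condition_scenario(costs, mu, mu_star=0.40)
        # (4,4) busts the cap at 0.5; (10,10) costs 20; optimum mixes
        assert r.total_cost == 14.0
        assert r.total_mu == pytest.approx(0.35)

    def test_slack_cap_reduces_to_cheapest_plans(self):
        rng = np.random.default_rng(0)
        costs = rng.uniform(10, 100, (6, 4))
        mu = rng.uniform(0.05, 0.2, (6, 4))
        r = solve_condition_scenario(costs, mu, mu_star=mu.max(axis=1).sum() + 1)
        assert r.total_cost == pytest.approx(costs.min(axis=1).sum())

    def test_infeasible_reports_margin(self):
        r = solve_condition_scenario(
            np.array([[1.0, 2.0]]), np.array([[0.4, 0.3]]), mu_star=0.1
        )
        assert not r.feasible
        assert r.status == "infeasible"
        assert r.infeasibility_margin == pytest.approx(0.2)

    def test_constraint_respected_at_tolerance(self, scenarios_a, hospital_a):
        beta = cs.BetaVector.uniform(hospital_a, 0.85)
        th = compute_thresholds(hospital_a, beta)
        for cid in ("AMI", "CABG"):
            for w in range(5):
                r = solve_condition_scenario(
                    scenarios_a.costs[cid][w],
                    scenarios_a.mu_hat[cid][w],
                    th[cid].mu_star,
                )
                assert r.feasible
                assert r.total_mu <= th[cid].mu_star + 1e-9

    def test_equal_cost_ties_break_toward_low_plan_index(self):
        # both assignments cost 10; plan indices decide
        costs = np.array([[5.0, 5.0], [5.0, 5.0]])
        mu = np.array([[0.10, 0.12], [0.10, 0.12]])
        r = solve_condition_scenario(costs, mu, mu_star=1.0)
        assert r.assignment == (0, 0)
        b = brute_force_oracle(costs, mu, mu_star=1.0)
        assert b.assignment == r.assignment


class TestBruteForceOracle:
    def test_refuses_oversized_instances(self):
        with pytest.raises(ValueError, match="too large"):
            brute_force_oracle(np.ones((30, 10)), np.ones((30, 10)) * 0.01, 5.0)

    def test_random_instances_match_solver(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            P, K = rng.integers(1, 5), rng.integers(2, 4)
            costs = np.round(rng.uniform(1, 20, (P, K)), 1)
            mu = rng.uniform(0.01, 0.4, (P, K))
            cap = rng.uniform(0, mu.min(axis=1).sum() * 2)
            a = solve_condition_scenario(costs, mu, cap)
            b = brute_force_oracle(costs, mu, cap)
            assert a.feasible == b.feasible
            if a.feasible:
                assert a.total_cost == pytest.approx(b.total_cost, abs=1e-9)

    def test_medium_instances_match_exact_milp(self):
        # independent backend: HiGHS run to proven optimality
        rng = np.random.default_rng(7)
        for _ in range(8):
            P, K = int(rng.integers(5, 30)), int(rng.integers(3, 11))
            costs = rng.uniform(1e3, 2e4, (P, K))
            mu = rng.uniform(0.01, 0.5, (P, K))
            cap = rng.uniform(mu.min(axis=1).sum() * 1.001, mu.max(axis=1).sum())
            s = solve_mckp(costs, mu, cap)
            choice = _milp_choice(costs, mu, cap)
            milp_cost = float(costs[np.arange(P), choice].sum())
            assert s.status == "solved"
            assert s.total_cost == pytest.approx(milp_cost, rel=1e-9)


class TestSolveDem:
    def _one_condition_spec(self):
        return cs.HospitalSpec(
            hospital_id="t",
            annual_penalty=0.0,
            conditions=(
                cs.ConditionSpec(
                    condition_id="C",
                    target_rate=0.2,
                    hospital_mean_rate=0.2,
                    n_patients=2,
                    cost_triangular=(1.0, 5.0, 20.0),
                    n_plans=2,
                    tier_sizes=(1, 1),
                ),
            ),
        )

    def test_two_identical_scenarios_equal_single_scenario_cost(self):
        spec = self._one_condition_spec()
        costs = np.array([[10.0, 4.0], [10.0, 4.0]])
        mu = np.array([[0.1, 0.25], [0.1, 0.25]])
        scen = manual_scenario_set(
            {"C": np.stack([mu, mu])}, {"C": np.stack([costs, costs])}, {"C": (1, 3)}
        )
        # beta chosen so mu* = 0.40: root of 0.4 - m = sqrt(0.25 m) z
        from scipy.stats import norm

        beta = float(norm.cdf((0.2 * 2 - 0.40) / np.sqrt(0.25 * 0.40)))
        sol = cs.solve_dem(scen, cs.BetaVector({"C": beta}), spec)
        assert sol.feasible
        assert sol.objective == pytest.approx(14.0)
        assert sol.expected_penalty == 0.0

    def test_infeasible_cells_are_listed(self):
        spec = self._one_condition_spec()
        mu = np.array([[0.9, 0.8], [0.9, 0.8]])
        costs = np.ones((2, 2))
        scen = manual_scenario_set(
            {"C": np.stack([mu])}, {"C": np.stack([costs])}, {"C": (1, 3)}
        )
        sol = cs.solve_dem(scen, cs.BetaVector({"C": 0.9}), spec)
        assert not sol.feasible
        assert sol.failing_cells == (("C", 0),)
        assert sol.objective is None

    def test_objective_is_cost_plus_penalty_identity(self, hospital_a, scenarios_a):
        sol = cs.solve_dem(scenarios_a, cs.BetaVector.uniform(hospital_a, 0.7), hospital_a)
        assert sol.objective == sol.expected_treatment_cost + sol.expected_penalty

    def test_near_one_confidence_drives_penalty_to_zero(self, tiny_spec):
        scen = cs.generate_scenarios(tiny_spec, 3, cs.GeneratorSettings(seed=2))
        beta = cs.BetaVector.uniform(tiny_spec, 1 - 1e-12)
        model = cs.cost_shares(tiny_spec)
        assert cs.expected_penalty(beta, model) == pytest.approx(0.0, abs=1e-6)

    def test_decomposition_matches_monolithic_milp(self, tiny_spec):
        # one MILP over every (condition, scenario) cell jointly must agree
        # with the cell-by-cell solve
        scen = cs.generate_scenarios(tiny_spec, 2, cs.GeneratorSettings(seed=4))
        beta = cs.BetaVector.uniform(tiny_spec, 0.6)
        sol = cs.solve_dem(scen, beta, tiny_spec)
        assert sol.feasible
        th = compute_thresholds(tiny_spec, beta)
        blocks, mu_rows, caps = [], [], []
        p_w = scen.probabilities
        obj = []
        for cid in tiny_spec.condition_ids:
            for w in range(scen.n_scenarios):
                c = scen.costs[cid][w]
                m = scen.mu_hat[cid][w]
                blocks.append((cid, w, c.shape))
                obj.append((p_w[w] * c).ravel())
                mu_rows.append(m.ravel())
                caps.append(th[cid].mu_star)
        sizes = [b[2][0] * b[2][1] for b in blocks]
        offs = np.concatenate(([0], np.cumsum(sizes)))
        n = offs[-1]
        cons = []
        row = 0
        a_rows, a_cols = [], []
        for bi, (cid, w, (P, K)) in enumerate(blocks):
            for p in range(P):
                a_rows.extend([row] * K)
                a_cols.extend(range(offs[bi] + p * K, offs[bi] + (p + 1) * K))
                row += 1
        from scipy import sparse

        a_eq = sparse.csr_matrix((np.ones(len(a_rows)), (a_rows, a_cols)), shape=(row, n))
        cons.append(LinearConstraint(a_eq, 1.0, 1.0))
        for bi, cap in enumerate(caps):
            v = np.zeros(n)
            v[offs[bi] : offs[bi + 1]] = mu_rows[bi]
            cons.append(LinearConstraint(v, -np.inf, cap + 1e-9))
        res = milp(
            np.concatenate(obj),
            constraints=cons,
            integrality=np.ones(n),
            bounds=Bounds(0, 1),
            options={"mip_rel_gap": 0.0},
        )
        assert res.success
        assert sol.expected_treatment_cost == pytest.approx(res.fun, rel=1e-9)


class TestMaxFeasibleBeta:
    def test_reference_screening_example(self):
        # |P|=2, theta=0.2, lam=0.25: mu*(0.5)=0.4, mu*(0.6)~0.3275,
        # mu*(0.7)~0.2650; a floor of 0.3 passes 0.6 but not 0.7
        spec = cs.HospitalSpec(
            hospital_id="t",
            annual_penalty=0.0,
            conditions=(
                cs.ConditionSpec(
                    condition_id="C",
                    target_rate=0.2,
                    hospital_mean_rate=0.2,
                    n_patients=2,
                    cost_triangular=(1.0, 2.0, 3.0),
                    n_plans=2,
                    tier_sizes=(1, 1),
                ),
            ),
        )
        mu = np.array([[0.15, 0.2], [0.15, 0.25]])
        scen = manual_scenario_set(
            {"C": np.stack([mu])}, {"C": np.ones((1, 2, 2))}, {"C": (1, 3)}
        )
        per_cond, overall = cs.max_feasible_beta(scen, spec, [0.5, 0.6, 0.7, 0.8])
        assert per_cond["C"] == 0.6
        assert overall == 0.6

    def test_floor_above_target_mass_is_never_feasible(self):
        spec = cs.HospitalSpec(
            hospital_id="t",
            annual_penalty=0.0,
            conditions=(
                cs.ConditionSpec(
                    condition_id="C",
                    target_rate=0.1,
                    hospital_mean_rate=0.2,
                    n_patients=2,
                    cost_triangular=(1.0, 2.0, 3.0),
                    n_plans=2,
                    tier_sizes=(1, 1),
                ),
            ),
        )
        mu = np.array([[0.3, 0.4], [0.3, 0.4]])  # floor 0.6 > theta|P| = 0.2
        scen = manual_scenario_set(
            {"C": np.stack([mu])}, {"C": np.ones((1, 2, 2))}, {"C": (1, 3)}
        )
        per_cond, overall = cs.max_feasible_beta(scen, spec, [0.5, 0.7, 0.9])
        assert per_cond["C"] is None
        assert overall is None

    def test_feasibility_frontier_is_downward_closed(self, hospital_a, scenarios_a):
        grid = list(cs.DEFAULT_BETA_GRID)
        per_cond, overall = cs.max_feasible_beta(scenarios_a, hospital_a, grid)
        for cid, beta_star in per_cond.items():
            if beta_star is None:
                continue
            cond = hospital_a.condition(cid)
            worst = max(
                scenarios_a.mu_hat[cid][w].min(axis=1).sum()
                for w in range(scenarios_a.n_scenarios)
            )
            for b in grid:
                star = cs.deterministic_threshold(
                    cond.target_rate, cond.n_patients, cond.variance_coefficient, b
                ).mu_star
                assert (b <= beta_star) == (worst <= star + 1e-9)

    def test_empty_or_unordered_grid_rejected(self, hospital_a, scenarios_a):
        with pytest.raises(ValueError):
            cs.max_feasible_beta(scenarios_a, hospital_a, [])
        with pytest.raises(ValueError):
            cs.max_feasible_beta(scenarios_a, hospital_a, [0.8, 0.6])
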
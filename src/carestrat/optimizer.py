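"""Exact solution of the deterministic-equivalent assignment problem.

Per condition c and scenario ω the model is a multiple-choice knapsack:
pick exactly one treatment plan per patient, minimizing total cost,
subject to the chance-constraint cap Σ μ̂ ≤ μ*_c.  The full model over
scenarios and conditions decomposes into these independent cells because
the objective is separable and no constraint couples cells; the overall
objective is the scenario-probability-weighted treatment cost plus the
expected penalty EP(β).

Cells are solved exactly by a specialized multiple-choice-knapsack
branch and bound (see :mod:`carestrat.mckp`), with two shortcuts that
settle most cells without a search: if the per-patient cheapest plans
already satisfy the cap the cell is unconstrained, and if even the
per-patient smallest μ̂ sum exceeds the cap the cell is infeasible.  A
MILP backend (HiGHS via scipy.optimize.milp, run to proven optimality)
serves as fallback for the rare search that exceeds its node budget and
as an independent cross-check in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .chance import ChanceThreshold, deterministic_threshold
from .domain import BetaVector, HospitalSpec
from .economics import cost_shares, expected_penalty
from .mckp import solve_mckp
from .scenarios import ScenarioSet

__all__ = [
    "AssignmentResult",
    "CareStrategySolution",
    "solve_condition_scenario",
    "brute_force_oracle",
    "solve_dem",
    "max_feasible_beta",
]

#: Absolute tolerance on the knapsack constraint Σ μ̂ ≤ μ*.
MU_TOL = 1e-9

#: HiGHS is run to proven optimality: the default relative MIP gap would
#: accept near-optimal incumbents and break exact agreement with the
#: enumeration oracle.
_MILP_OPTIONS = {"mip_rel_gap": 0.0}

#: Tie-break refinement (second, cost-capped solve minimizing the total
#: plan index) is only run on instances at most this large, or when a
#: patient has exactly duplicated costs; larger instances draw costs from
#: continuous distributions, where cost ties have probability zero.
TIE_BREAK_MAX_VARS = 120


@dataclass(frozen=True)
class AssignmentResult:
    """One solved (condition, scenario) cell."""

    condition_id: str
    scenario: int
    assignment: tuple[int, ...] | None  # chosen plan index per patient
    total_cost: float
    total_mu: float
    feasible: bool
    status: str  # "solved" | "infeasible"
    infeasibility_margin: float = 0.0  # Σ min μ̂ − μ* when infeasible


@dataclass(frozen=True)
class CareStrategySolution:
    """A full DEM solve: every (condition, scenario) cell plus aggregates.

    ``objective = expected_treatment_cost + expected_penalty`` holds as
    an exact arithmetic identity when feasible.  When any cell is
    infeasible, ``feasible`` is False, ``failing_cells`` lists the
    (condition, scenario) pairs, and the cost aggregates are None.
    """

    spec: HospitalSpec
    scenarios: ScenarioSet
    beta: BetaVector
    thresholds: Mapping[str, ChanceThreshold]
    results: Mapping[tuple[str, int], AssignmentResult]
    feasible: bool
    failing_cells: tuple[tuple[str, int], ...]
    expected_treatment_cost: float | None
    expected_penalty: float | None
    objective: float | None

    def condition_results(self, condition_id: str) -> list[AssignmentResult]:
        return [
            self.results[(condition_id, w)]
            for w in range(self.scenarios.n_scenarios)
        ]


def _cheapest_assignment(costs: np.ndarray) -> np.ndarray:
    # argmin returns the first (lowest-index) minimizer, matching the
    # lowest-plan-index tie-break.
    return costs.argmin(axis=1)


def _min_mu_sum(mu_hat: np.ndarray) -> float:
    return float(mu_hat.min(axis=1).sum())


def _result_from_assignment(
    costs: np.ndarray,
    mu_hat: np.ndarray,
    choice: np.ndarray,
    condition_id: str,
    scenario: int,
) -> AssignmentResult:
    rows = np.arange(costs.shape[0])
    return AssignmentResult(
        condition_id=condition_id,
        scenario=scenario,
        assignment=tuple(int(k) for k in choice),
        total_cost=float(costs[rows, choice].sum()),
        total_mu=float(mu_hat[rows, choice].sum()),
        feasible=True,
        status="solved",
    )


def _milp_choice(
    objective: np.ndarray,
    mu_hat: np.ndarray,
    mu_star: float,
    extra: LinearConstraint | None = None,
) -> np.ndarray | None:
    P, K = mu_hat.shape
    n = P * K
    rows = np.repeat(np.arange(P), K)
    a_eq = sparse.csr_matrix((np.ones(n), (rows, np.arange(n))), shape=(P, n))
    constraints = [
        LinearConstraint(a_eq, 1.0, 1.0),
        LinearConstraint(mu_hat.ravel(), -np.inf, mu_star + MU_TOL),
    ]
    if extra is not None:
        constraints.append(extra)
    res = milp(
        objective.ravel(),
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(0.0, 1.0),
        options=_MILP_OPTIONS,
    )
    if not res.success:
        return None
    x = res.x.reshape(P, K)
    return x.argmax(axis=1)


def solve_condition_scenario(
    costs: np.ndarray,
    mu_hat: np.ndarray,
    mu_star: float,
    condition_id: str = "",
    scenario: int = 0,
) -> AssignmentResult:
    """Cost-minimal one-plan-per-patient assignment with Σ μ̂ ≤ μ*.

    Solved exactly (branch and bound with MILP fallback); among
    cost-optimal assignments, ties are broken toward low plan indices.
    Returns an infeasible result (with the violating margin) when even
    the per-patient minimum μ̂ sum exceeds the cap.
    """
    costs = np.asarray(costs, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    if costs.shape != mu_hat.shape or costs.ndim != 2:
        raise ValueError("costs and mu_hat must be matrices of identical shape")
    if mu_star < 0:
        raise ValueError(f"mu_star must be >= 0, got {mu_star}")
    P, K = costs.shape
    rows = np.arange(P)

    floor_mu = _min_mu_sum(mu_hat)
    if floor_mu > mu_star + MU_TOL:
        return AssignmentResult(
            condition_id,
            scenario,
            None,
            float("nan"),
            floor_mu,
            False,
            "infeasible",
            infeasibility_margin=floor_mu - mu_star,
        )

    cheap = _cheapest_assignment(costs)
    if float(mu_hat[rows, cheap].sum()) <= mu_star + MU_TOL:
        return _result_from_assignment(costs, mu_hat, cheap, condition_id, scenario)

    sol = solve_mckp(costs, mu_hat, mu_star + MU_TOL)
    if sol.status == "solved":
        choice = sol.assignment
    else:  # node-limit safeguard tripped: fall back to the MILP backend
        choice = _milp_choice(costs, mu_hat, mu_star)
        if choice is None:  # numerically tight cap: take the μ̂-floor plan
            choice = mu_hat.argmin(axis=1)
    best_cost = float(costs[rows, choice].sum())

    has_dup = any(len(np.unique(costs[p])) < K for p in range(P))
    if P * K <= TIE_BREAK_MAX_VARS or has_dup:
        cap = LinearConstraint(
            costs.ravel(), -np.inf, best_cost + 1e-7 * max(1.0, abs(best_cost))
        )
        idx = np.tile(np.arange(K, dtype=float), (P, 1))
        refined = _milp_choice(idx, mu_hat, mu_star, extra=cap)
        if refined is not None:
            choice = refined
    return _result_from_assignment(costs, mu_hat, choice, condition_id, scenario)


def brute_force_oracle(
    costs: np.ndarray,
    mu_hat: np.ndarray,
    mu_star: float,
    condition_id: str = "",
    scenario: int = 0,
    max_assignments: int = 10**6,
) -> AssignmentResult:
    """Exhaustive enumeration of all K^P assignments (testing oracle).

    Enumerates plan tuples in lexicographic order and keeps the first
    strict cost improvement, so the returned assignment is the
    lexicographically smallest cost optimum.  Refuses instances with
    more than ``max_assignments`` assignments.
    """
    costs = np.asarray(costs, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    P, K = costs.shape
    if K**P > max_assignments:
        raise ValueError(f"instance too large for enumeration: {K}^{P} assignments")
    rows = np.arange(P)
    best: tuple[float, tuple[int, ...]] | None = None
    for combo in itertools.product(range(K), repeat=P):
        idx = np.asarray(combo)
        if float(mu_hat[rows, idx].sum()) > mu_star + MU_TOL:
            continue
        cost = float(costs[rows, idx].sum())
        if best is None or cost < best[0]:
            best = (cost, combo)
    if best is None:
        floor_mu = _min_mu_sum(mu_hat)
        return AssignmentResult(
            condition_id,
            scenario,
            None,
            float("nan"),
            floor_mu,
            False,
            "infeasible",
            infeasibility_margin=floor_mu - mu_star,
        )
    return _result_from_assignment(
        costs, mu_hat, np.asarray(best[1]), condition_id, scenario
    )


def compute_thresholds(
    spec: HospitalSpec, beta: BetaVector
) -> dict[str, ChanceThreshold]:
    """μ*_c per condition; θ, |P|, λ are scenario-invariant, so one
    threshold serves every scenario of a condition."""
    beta.validate_for(spec)
    return {
        c.condition_id: deterministic_threshold(
            c.target_rate,
            c.n_patients,
            c.variance_coefficient,
            beta[c.condition_id],
            condition_id=c.condition_id,
        )
        for c in spec.conditions
    }


def solve_dem(
    scenarios: ScenarioSet,
    beta: BetaVector,
    spec: HospitalSpec,
) -> CareStrategySolution:
    """Solve every (condition, scenario) cell and assemble the objective.

    objective = Σ_ω p(ω) Σ_c cost_cω + EP(β), with EP computed from the
    analytic penalty model (condition cost shares of the annual penalty).
    """
    thresholds = compute_thresholds(spec, beta)
    results: dict[tuple[str, int], AssignmentResult] = {}
    failing: list[tuple[str, int]] = []
    for cid in spec.condition_ids:
        mu_star = thresholds[cid].mu_star
        for w in range(scenarios.n_scenarios):
            r = solve_condition_scenario(
                scenarios.costs[cid][w], scenarios.mu_hat[cid][w], mu_star, cid, w
            )
            results[(cid, w)] = r
            if not r.feasible:
                failing.append((cid, w))
    if failing:
        return CareStrategySolution(
            spec, scenarios, beta, thresholds, results, False, tuple(failing),
            None, None, None,
        )
    p = scenarios.probabilities
    expected_cost = float(
        sum(
            p[w] * results[(cid, w)].total_cost
            for cid in spec.condition_ids
            for w in range(scenarios.n_scenarios)
        )
    )
    ep = expected_penalty(beta, cost_shares(spec))
    return CareStrategySolution(
        spec, scenarios, beta, thresholds, results, True, (),
        expected_cost, ep, expected_cost + ep,
    )


def max_feasible_beta(
    scenarios: ScenarioSet,
    spec: HospitalSpec,
    beta_grid: Sequence[float],
) -> tuple[dict[str, float | None], float | None]:
    """Highest grid β feasible in every scenario, per condition and overall.

    Feasibility of a cell depends only on whether the per-patient minimum
    μ̂ sum fits under μ*_c(β) — a necessary and sufficient screen for the
    knapsack constraint — so no solves are needed.  Returns ``None``
    markers where even the smallest grid value fails.
    """
    grid = list(beta_grid)
    if not grid or any(b >= b2 for b, b2 in zip(grid, grid[1:])):
        raise ValueError("beta_grid must be a non-empty strictly increasing sequence")
    per_condition: dict[str, float | None] = {}
    for cond in spec.conditions:
        cid = cond.condition_id
        worst = max(
            _min_mu_sum(scenarios.mu_hat[cid][w])
            for w in range(scenarios.n_scenarios)
        )
        best: float | None = None
        for b in grid:
            t = deterministic_threshold(
                cond.target_rate, cond.n_patients, cond.variance_coefficient, b
            )
            if worst <= t.mu_star + MU_TOL:
                best = b
            else:
                break  # μ*(β) decreases in β: later grid points also fail
        per_condition[cid] = best
    feasible_values = [v for v in per_condition.values()]
    overall = None if any(v is None for v in feasible_values) else min(feasible_values)
    return per_condition, overall
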
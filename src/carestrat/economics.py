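"""Expected-penalty model, cost baselines, and solution summaries.

The annual readmission penalty is apportioned to conditions by their
share of the hospital's expected treatment spend, R_c = |P_c|·ā_c / Σ,
with ā_c the analytic mean of the condition's triangular cost law.  The
expected penalty at confidence vector β is then
EP(β) = Σ_c (1 − β_c)·R_c·Penalty: each condition contributes its share
of the penalty weighted by the probability (1 − β_c) of missing its
target.  The two cost baselines bracket the hospital's current position:
Σ|P_c|ā_c without the policy, plus the full penalty with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import BetaVector, ConditionSpec, HospitalSpec
from .scenarios import ScenarioSet

if TYPE_CHECKING:  # only for annotations; avoids a circular import
    from .optimizer import CareStrategySolution

__all__ = [
    "PenaltyModel",
    "SweepResult",
    "mean_plan_cost",
    "cost_shares",
    "expected_penalty",
    "baseline_costs",
    "mean_readmission_summary",
    "tier_shares",
    "beta_sweep",
]

DEFAULT_BETA_GRID = tuple(round(0.50 + 0.05 * i, 2) for i in range(10)) + (0.98,)


@dataclass(frozen=True)
class PenaltyModel:
    """Condition shares R_c of the annual penalty (Σ R_c = 1)."""

    annual_penalty: float
    shares: Mapping[str, float]
    mean_costs: Mapping[str, float]


@dataclass(frozen=True)
class SweepResult:
    """Tabular β sweep: one row per (mode, β) with all summary metrics."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")


def mean_plan_cost(condition: ConditionSpec) -> float:
    """Analytic triangular mean ā_c = (min + mode + max)/3, USD."""
    lo, mode, hi = condition.cost_triangular
    return (lo + mode + hi) / 3.0


def cost_shares(spec: HospitalSpec) -> PenaltyModel:
    """R_c = |P_c|·ā_c / Σ_ĉ |P_ĉ|·ā_ĉ."""
    means = {c.condition_id: mean_plan_cost(c) for c in spec.conditions}
    weights = {c.condition_id: c.n_patients * means[c.condition_id] for c in spec.conditions}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("cost shares undefined: all |P_c|·ā_c are zero")
    return PenaltyModel(
        annual_penalty=spec.annual_penalty,
        shares={cid: w / total for cid, w in weights.items()},
        mean_costs=means,
    )


def expected_penalty(beta: BetaVector, model: PenaltyModel) -> float:
    """EP(β) = Σ_c (1 − β_c)·R_c·Penalty, USD."""
    return sum(
        (1.0 - beta[cid]) * share * model.annual_penalty
        for cid, share in model.shares.items()
    )


def baseline_costs(spec: HospitalSpec) -> tuple[float, float]:
    """(no-penalty, with-penalty) cost baselines.

    no_penalty = Σ_c |P_c|·ā_c is the hospital's expected treatment spend
    absent the policy; with_penalty adds the full annual penalty.
    """
    no_penalty = sum(c.n_patients * mean_plan_cost(c) for c in spec.conditions)
    return no_penalty, no_penalty + spec.annual_penalty


def _require_solved(solution: "CareStrategySolution") -> None:
    if not solution.feasible:
        raise ValueError(
            f"solution is infeasible (failing cells: {solution.failing_cells[:5]}...)"
        )


def mean_readmission_summary(
    solution: "CareStrategySolution", spec: HospitalSpec
) -> dict[str, float]:
    """Scenario-averaged per-patient mean readmission rate per condition.

    μ̄_c = Σ_ω p(ω)·(Σ_p μ̂ of chosen plans)/|P_c|, on the same scale as
    the target θ_c.  The un-normalized sum is available via
    ``raw_readmission_mass``.
    """
    _require_solved(solution)
    mass = raw_readmission_mass(solution)
    return {
        c.condition_id: mass[c.condition_id] / c.n_patients for c in spec.conditions
    }


def raw_readmission_mass(solution: "CareStrategySolution") -> dict[str, float]:
    """Σ_ω p(ω)·Σ_p μ̂ of chosen plans (not divided by |P_c|)."""
    _require_solved(solution)
    p = solution.scenarios.probabilities
    return {
        cid: float(
            sum(
                p[w] * solution.results[(cid, w)].total_mu
                for w in range(solution.scenarios.n_scenarios)
            )
        )
        for cid in solution.spec.condition_ids
    }


def tier_shares(
    solution: "CareStrategySolution", spec: HospitalSpec
) -> pd.DataFrame:
    """Expected percentage of patients per tier, per condition.

    Rows sum to 100; the expectation is scenario-probability weighted.
    """
    _require_solved(solution)
    p = solution.scenarios.probabilities
    n_tiers = max(len(c.tier_sizes) for c in spec.conditions)
    rows = []
    for c in spec.conditions:
        cid = c.condition_id
        tiers = np.asarray(solution.scenarios.plan_tiers[cid])
        shares = np.zeros(n_tiers)
        for w in range(solution.scenarios.n_scenarios):
            choice = np.asarray(solution.results[(cid, w)].assignment)
            counts = np.bincount(tiers[choice], minlength=n_tiers + 1)[1:]
            shares += p[w] * counts / c.n_patients
        rows.append(
            {"condition": cid, **{f"tier{t + 1}_pct": 100.0 * shares[t] for t in range(n_tiers)}}
        )
    return pd.DataFrame(rows)


def beta_sweep(
    spec: HospitalSpec,
    scenarios: ScenarioSet,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    mode: str = "all_conditions",
    fixed_beta: Mapping[str, float] | None = None,
) -> SweepResult:
    """One DEM solve per grid point, tabulating the cost/readmission trade-off.

    ``mode="all_conditions"`` moves every β_c together along the grid;
    ``mode="condition:<id>"`` varies only that condition while the others
    stay at ``fixed_beta`` (default: their highest feasible grid level).
    Infeasible grid points are flagged rows without solution fields.
    """
    from .optimizer import max_feasible_beta, solve_dem

    no_pen, with_pen = baseline_costs(spec)
    single = None
    if mode != "all_conditions":
        if not mode.startswith("condition:"):
            raise ValueError(f"mode must be 'all_conditions' or 'condition:<id>', got {mode}")
        single = mode.split(":", 1)[1]
        spec.condition(single)  # KeyError on unknown id
        if fixed_beta is None:
            per_cond, _ = max_feasible_beta(scenarios, spec, beta_grid)
            if any(v is None for v in per_cond.values()):
                bad = [cid for cid, v in per_cond.items() if v is None]
                raise ValueError(
                    f"no feasible grid level for conditions {bad}; pass fixed_beta"
                )
            fixed_beta = per_cond

    rows = []
    for b in beta_grid:
        if single is None:
            beta = BetaVector.uniform(spec, b)
        else:
            beta = BetaVector(dict(fixed_beta)).with_level(single, b)
        sol = solve_dem(scenarios, beta, spec)
        row = {
            "mode": mode,
            "beta": b,
            "feasible": sol.feasible,
            "baseline_no_penalty": no_pen,
            "baseline_with_penalty": with_pen,
        }
        if sol.feasible:
            row.update(
                expected_cost=sol.expected_treatment_cost,
                expected_penalty=sol.expected_penalty,
                objective=sol.objective,
            )
            readm = mean_readmission_summary(sol, spec)
            shares = tier_shares(sol, spec).set_index("condition")
            for c in spec.conditions:
                cid = c.condition_id
                row[f"{cid}_mean_readmission"] = readm[cid]
                for col in shares.columns:
                    row[f"{cid}_{col}"] = shares.loc[cid, col]
        rows.append(row)
    return SweepResult(pd.DataFrame(rows))
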
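"""Exact multiple-choice knapsack solver for the per-cell assignment.

Each (condition, scenario) cell of the deterministic-equivalent model
asks for a cost-minimal choice of one plan per patient subject to a
single cap on the sum of chosen readmission means.  This is the
multiple-choice knapsack problem (MCKP) in minimization form, solved
exactly in three stages:

1. *Dominance pruning* — per patient, any plan with another plan at both
   lower-or-equal cost and weight is discarded.
2. *Lagrangian core reduction* — bisection on the multiplier λ of the
   weight constraint gives a dual bound LB and, at the feasible end, an
   integer incumbent that a greedy slack-filling pass improves to UB.
   Writing δ_pk for a plan's reduced-cost excess over the patient's best
   reduced cost at λ, every feasible solution satisfies
   cost ≥ LB + Σ_p δ_p(chosen), so plans with δ_pk > UB − LB can never
   occur in a solution better than the incumbent.  Patients left with a
   single candidate are fixed; the rest form a small core.
3. *Branch and bound on the core* — depth-first search with the greedy
   LP-relaxation bound over each patient's convex hull of (weight, cost)
   Pareto plans, branching on the single fractional patient of the LP
   optimum.

Instances here are small (<= ~132 patients, <= 10 plans) and the core is
typically a handful of patients, so the search stays tiny; a node-limit
safeguard reports failure so the caller can fall back to a MILP solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MckpSolution", "solve_mckp"]

_FEAS_TOL = 1e-9


@dataclass(frozen=True)
class MckpSolution:
    status: str  # "solved" | "infeasible" | "node_limit"
    assignment: np.ndarray | None  # original plan index per patient
    total_cost: float
    total_mu: float


def _pareto(cost_row: np.ndarray, mu_row: np.ndarray) -> np.ndarray:
    """Indices of Pareto-minimal plans, by increasing cost / decreasing weight."""
    order = np.lexsort((np.arange(len(cost_row)), mu_row, cost_row))
    keep: list[int] = []
    best_mu = np.inf
    for k in order:
        if mu_row[k] < best_mu:
            keep.append(k)
            best_mu = mu_row[k]
    return np.asarray(keep)


def _hull(cost: np.ndarray, mu: np.ndarray) -> list[int]:
    """Positions on the lower convex hull of the (mu, cost) Pareto path."""
    hull = [0]
    for j in range(1, len(cost)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # slope a->b must stay below slope b->j; drop b otherwise
            if (cost[b] - cost[a]) * (mu[b] - mu[j]) >= (cost[j] - cost[b]) * (
                mu[a] - mu[b]
            ):
                hull.pop()
            else:
                break
        hull.append(j)
    return hull


def _branch_and_bound(
    par_c: list[np.ndarray],
    par_m: list[np.ndarray],
    cap: float,
    node_limit: int,
    best_cost_init: float,
    best_pos_init: np.ndarray,
) -> tuple[bool, float, np.ndarray]:
    """Exact search over Pareto lists; returns (completed, cost, positions)."""
    P = len(par_c)
    base_c = np.array([c[0] for c in par_c])
    base_m = np.array([m[0] for m in par_m])
    min_mu = np.array([m[-1] for m in par_m])

    inc_rows: list[tuple[float, int, int, float, float]] = []
    hulls: list[list[int]] = []
    for p in range(P):
        h = _hull(par_c[p], par_m[p])
        hulls.append(h)
        for j in range(1, len(h)):
            a, b = h[j - 1], h[j]
            dc = par_c[p][b] - par_c[p][a]
            dm = par_m[p][a] - par_m[p][b]
            inc_rows.append((dc / dm, p, j, dc, dm))
    inc_rows.sort(key=lambda t: t[0])  # ties keep within-patient order

    scale = max(1.0, float(np.abs(base_c).sum()), abs(best_cost_init))
    prune_eps = 1e-9 * scale

    best_cost = best_cost_init
    best_pos = best_pos_init.copy()
    nodes = 0
    completed = True

    def lp_bound(free: np.ndarray, capacity: float):
        cost0 = float(base_c[free].sum())
        mu0 = float(base_m[free].sum())
        pos = np.zeros(P, dtype=int)
        if mu0 <= capacity + _FEAS_TOL:
            return cost0, True, -1, pos, 0.0
        need = mu0 - capacity
        bound = cost0
        for slope, p, j, dc, dm in inc_rows:
            if not free[p]:
                continue
            if dm >= need - _FEAS_TOL:
                frac = need / dm
                bound += dc * frac
                if frac >= 1.0 - 1e-12:
                    pos[p] = j
                    return bound, True, -1, pos, slope
                return bound, False, p, pos, slope
            need -= dm
            bound += dc
            pos[p] = j
        return np.inf, False, -1, pos, 0.0

    def dfs(fixed_pos: np.ndarray, free: np.ndarray, fixed_cost: float, fixed_mu: float):
        nonlocal nodes, completed, best_cost, best_pos
        if not completed:
            return
        nodes += 1
        if nodes > node_limit:
            completed = False
            return
        bound, integral, frac_p, hull_step, lam = lp_bound(free, cap - fixed_mu)
        total_bound = fixed_cost + bound
        if total_bound >= best_cost - prune_eps:
            return
        if integral:
            sol = fixed_pos.copy()
            for p in np.flatnonzero(free):
                sol[p] = hulls[p][hull_step[p]]
            best_cost = total_bound
            best_pos = sol
            return
        if frac_p < 0:
            return
        rest_min = float(min_mu[free].sum()) - float(min_mu[frac_p])
        # children in order of Lagrangian reduced cost at the node's multiplier
        order = np.argsort(par_c[frac_p] + lam * par_m[frac_p], kind="stable")
        for j in order:
            mu_j = float(par_m[frac_p][j])
            if fixed_mu + mu_j + rest_min > cap + _FEAS_TOL:
                continue
            child_fixed = fixed_pos.copy()
            child_fixed[frac_p] = j
            child_free = free.copy()
            child_free[frac_p] = False
            dfs(
                child_fixed,
                child_free,
                fixed_cost + float(par_c[frac_p][j]),
                fixed_mu + mu_j,
            )

    dfs(np.zeros(P, dtype=int), np.ones(P, dtype=bool), 0.0, 0.0)
    return completed, best_cost, best_pos


def solve_mckp(
    costs: np.ndarray,
    mu_hat: np.ndarray,
    cap: float,
    node_limit: int = 50000,
) -> MckpSolution:
    """Cost-minimal one-plan-per-patient assignment with Σ weight ≤ cap."""
    costs = np.asarray(costs, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    P, K = costs.shape
    rows = np.arange(P)

    min_mu_sum = float(mu_hat.min(axis=1).sum())
    if min_mu_sum > cap + _FEAS_TOL:
        return MckpSolution("infeasible", None, float("nan"), min_mu_sum)

    cheap = costs.argmin(axis=1)
    if float(mu_hat[rows, cheap].sum()) <= cap + _FEAS_TOL:
        return MckpSolution(
            "solved",
            cheap,
            float(costs[rows, cheap].sum()),
            float(mu_hat[rows, cheap].sum()),
        )

    # --- Lagrangian dual bound: bisection on the multiplier ---------------
    def argmin_mu(lam: float) -> tuple[np.ndarray, float]:
        kmin = (costs + lam * mu_hat).argmin(axis=1)
        return kmin, float(mu_hat[rows, kmin].sum())

    lam_lo, lam_hi = 0.0, 1.0
    while argmin_mu(lam_hi)[1] > cap:
        lam_hi *= 4.0
    for _ in range(100):
        mid = 0.5 * (lam_lo + lam_hi)
        if argmin_mu(mid)[1] > cap:
            lam_lo = mid
        else:
            lam_hi = mid
    lam = lam_hi
    red = costs + lam * mu_hat
    red_min = red.min(axis=1)
    lower_bound = float(red_min.sum()) - lam * cap

    # --- Incumbent: feasible Lagrangian choice + greedy slack filling ----
    choice = red.argmin(axis=1)
    slack = cap - float(mu_hat[rows, choice].sum())
    saving = costs[rows, choice][:, None] - costs
    weight = mu_hat - mu_hat[rows, choice][:, None]
    cand = np.argwhere((saving > 0) & (weight > 0))
    if len(cand):
        ratios = saving[cand[:, 0], cand[:, 1]] / weight[cand[:, 0], cand[:, 1]]
        for i in np.argsort(-ratios, kind="stable"):
            p, k = cand[i]
            dmu = float(mu_hat[p, k] - mu_hat[p, choice[p]])
            dcost = float(costs[p, choice[p]] - costs[p, k])
            if dcost > 0 and 0 < dmu <= slack:
                slack -= dmu
                choice[p] = k
    upper_bound = float(costs[rows, choice].sum())

    # --- Core reduction ---------------------------------------------------
    gap = upper_bound - lower_bound + 1e-9 * max(1.0, abs(upper_bound))
    candidate = red - red_min[:, None] <= gap
    core_patients = np.flatnonzero(candidate.sum(axis=1) > 1)
    if len(core_patients) == 0:
        return MckpSolution(
            "solved",
            choice,
            upper_bound,
            float(mu_hat[rows, choice].sum()),
        )

    fixed_mask = np.ones(P, dtype=bool)
    fixed_mask[core_patients] = False
    fixed_cost = float(costs[rows[fixed_mask], choice[fixed_mask]].sum())
    fixed_mu = float(mu_hat[rows[fixed_mask], choice[fixed_mask]].sum())

    par_c: list[np.ndarray] = []
    par_m: list[np.ndarray] = []
    par_idx: list[np.ndarray] = []
    init_pos = np.zeros(len(core_patients), dtype=int)
    for i, p in enumerate(core_patients):
        cols = np.flatnonzero(candidate[p])
        keep = _pareto(costs[p, cols], mu_hat[p, cols])
        idx = cols[keep]
        par_c.append(costs[p, idx])
        par_m.append(mu_hat[p, idx])
        par_idx.append(idx)
        # incumbent's plan survives pruning unless an equivalent-or-better
        # plan dominates it; point the initial position at the best match
        where = np.flatnonzero(idx == choice[p])
        if len(where):
            init_pos[i] = where[0]
        else:
            dominating = np.flatnonzero(
                (par_c[-1] <= costs[p, choice[p]] + 1e-12)
                & (par_m[-1] <= mu_hat[p, choice[p]] + 1e-12)
            )
            init_pos[i] = dominating[0]

    completed, core_cost, core_pos = _branch_and_bound(
        par_c,
        par_m,
        cap - fixed_mu,
        node_limit,
        upper_bound - fixed_cost,
        init_pos,
    )
    if not completed:
        return MckpSolution("node_limit", None, float("nan"), float("nan"))
    assignment = choice.copy()
    for i, p in enumerate(core_patients):
        assignment[p] = par_idx[i][core_pos[i]]
    return MckpSolution(
        "solved",
        assignment,
        float(costs[rows, assignment].sum()),
        float(mu_hat[rows, assignment].sum()),
    )
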
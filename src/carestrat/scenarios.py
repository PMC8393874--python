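"""Scenario generation for treatment-plan costs and readmission means.

Each scenario ω is one joint realization, for every condition, of a
|P_c| × |K_c| cost matrix (USD, triangular law) and a matching matrix of
per-plan mean readmission probabilities μ̂.  Readmission means are built
in two steps: a per-patient baseline rate drawn around the hospital's
condition mean, then a per-plan tier multiplier that makes Tier 1 plans
(high cost) the most effective and Tier 3 plans (low cost) the least.
Costs are drawn i.i.d. from the condition's triangular distribution and,
by default, sorted descending across the plan index so that the plan
ordering realizes the tier cost structure.

Scenario weights are uniform, p(ω) = 1/|Ω|.  All draws derive from a
single integer seed through one named substream per (condition index,
scenario index), so regenerating with more conditions appended never
shuffles existing draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .domain import HospitalSpec

__all__ = [
    "GeneratorSettings",
    "ScenarioSet",
    "required_scenario_count",
    "generate_scenarios",
    "triangular_quantile",
    "write_scenarios",
    "read_scenarios",
]

DEFAULT_TIER_MULTIPLIERS = ((0.4, 0.7), (0.7, 1.0), (1.0, 1.3))


@dataclass(frozen=True)
class GeneratorSettings:
    """Knobs of the scenario generator.

    ``tier_multiplier_ranges`` give, per tier (Tier 1 first), the uniform
    range of the factor applied to a patient's baseline rate for plans of
    that tier; midpoints must increase strictly across tiers so that
    effectiveness decreases from Tier 1 to Tier 3.  Baselines and the
    resulting per-plan means are kept inside ``probability_bounds``.
    """

    seed: int = 0
    tier_multiplier_ranges: tuple[tuple[float, float], ...] = DEFAULT_TIER_MULTIPLIERS
    probability_bounds: tuple[float, float] = (0.001, 0.999)
    cost_sorting: bool = True

    def __post_init__(self):
        for lo, hi in self.tier_multiplier_ranges:
            if not (0 < lo <= hi):
                raise ValueError(
                    f"tier multiplier ranges must satisfy 0 < low <= high, got {(lo, hi)}"
                )
        mids = [0.5 * (lo + hi) for lo, hi in self.tier_multiplier_ranges]
        if any(a >= b for a, b in zip(mids, mids[1:])):
            raise ValueError(
                "tier multiplier midpoints must increase strictly from Tier 1 onward"
            )
        lo, hi = self.probability_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"probability bounds must satisfy 0 < lo < hi < 1, got {(lo, hi)}")


@dataclass(frozen=True)
class ScenarioSet:
    """Realized cost and readmission-mean matrices for all scenarios.

    ``costs[cid]`` and ``mu_hat[cid]`` are arrays of shape
    (n_scenarios, |P_c|, |K_c|); ``probabilities`` sums to 1.
    """

    condition_ids: tuple[str, ...]
    probabilities: np.ndarray
    costs: Mapping[str, np.ndarray]
    mu_hat: Mapping[str, np.ndarray]
    plan_tiers: Mapping[str, tuple[int, ...]]
    seed: int
    settings: GeneratorSettings
    #: per-patient baseline rates (n_scenarios, |P_c|); provenance only,
    #: not part of the CSV round trip
    baselines: Mapping[str, np.ndarray] | None = None

    @property
    def n_scenarios(self) -> int:
        return len(self.probabilities)

    def check(self) -> "ScenarioSet":
        if abs(float(self.probabilities.sum()) - 1.0) > 1e-12:
            raise ValueError("scenario probabilities must sum to 1")
        if np.any(self.probabilities <= 0):
            raise ValueError("scenario probabilities must be positive")
        for cid in self.condition_ids:
            mh, co = self.mu_hat[cid], self.costs[cid]
            if mh.shape != co.shape:
                raise ValueError(f"{cid}: cost and mu_hat shapes differ")
            if np.any((mh <= 0) | (mh >= 1)):
                raise ValueError(f"{cid}: readmission means must lie in (0, 1)")
            if np.any(co <= 0):
                raise ValueError(f"{cid}: costs must be positive")
        return self


def required_scenario_count(
    sample_variance: float, confidence: float, tolerance: float
) -> int:
    """Scenarios needed to estimate the objective mean to ±tolerance.

    Returns the smallest integer strictly greater than
    (z_{α/2})²·s²/ε², where 1−α is the confidence level — the standard
    sample-size bound for a population mean — with a floor of 1.
    """
    if sample_variance < 0:
        raise ValueError(f"sample variance must be >= 0, got {sample_variance}")
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    alpha = 1.0 - confidence
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    bound = z * z * sample_variance / (tolerance * tolerance)
    return max(1, int(math.floor(bound)) + 1)


def triangular_quantile(u: float, tri: tuple[float, float, float]) -> float:
    """Inverse CDF of the triangular(min, mode, max) distribution."""
    lo, mode, hi = tri
    if not (lo <= mode <= hi):
        raise ValueError(f"invalid triangular triple {tri}")
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"u must be in [0, 1], got {u}")
    if lo == hi:
        return float(lo)
    c = (mode - lo) / (hi - lo)
    return float(stats.triang.ppf(u, c, loc=lo, scale=hi - lo))


def _rng_for(seed: int, condition_index: int, scenario_index: int) -> np.random.Generator:
    # Named substream: entropy = (seed, condition index, scenario index).
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(seed, condition_index, scenario_index))
    )


def _truncated_baselines(
    rng: np.random.Generator, n: int, mean: float, sd: float, bounds: tuple[float, float]
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    lo, hi = bounds
    bad = (out <= lo) | (out >= hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def generate_scenarios(
    spec: HospitalSpec,
    n_scenarios: int,
    settings: GeneratorSettings | None = None,
) -> ScenarioSet:
    """Draw ``n_scenarios`` joint realizations for every condition.

    Per (condition, scenario): each patient gets a baseline readmission
    rate drawn from a Gaussian centred on the hospital's condition mean
    μ_c with coefficient of variation λ_c (sd = λ_c·μ_c), resampled into
    the open probability bounds; each plan's μ̂ is the baseline times a
    tier multiplier drawn uniformly from that tier's range, clipped to
    the bounds; each plan's cost is an i.i.d. triangular draw, sorted
    descending across plans when ``cost_sorting`` is on.
    """
    if n_scenarios < 1:
        raise ValueError(f"n_scenarios must be >= 1, got {n_scenarios}")
    settings = settings or GeneratorSettings()
    spec.validate()
    lo_p, hi_p = settings.probability_bounds
    costs: dict[str, np.ndarray] = {}
    mu_hat: dict[str, np.ndarray] = {}
    baselines: dict[str, np.ndarray] = {}
    tiers: dict[str, tuple[int, ...]] = {}
    for ci, cond in enumerate(spec.conditions):
        P, K = cond.n_patients, cond.n_plans
        if len(cond.tier_sizes) > len(settings.tier_multiplier_ranges):
            raise ValueError(
                f"{cond.condition_id}: {len(cond.tier_sizes)} tiers but only "
                f"{len(settings.tier_multiplier_ranges)} multiplier ranges"
            )
        tiers[cond.condition_id] = cond.plan_tiers
        a_c = np.empty((n_scenarios, P, K))
        m_c = np.empty((n_scenarios, P, K))
        b_c = np.empty((n_scenarios, P))
        tri = cond.cost_triangular
        sd = cond.variance_coefficient * cond.hospital_mean_rate
        mult_lo = np.empty(K)
        mult_hi = np.empty(K)
        for k, t in enumerate(cond.plan_tiers):
            mult_lo[k], mult_hi[k] = settings.tier_multiplier_ranges[t - 1]
        for w in range(n_scenarios):
            rng = _rng_for(settings.seed, ci, w)
            base = _truncated_baselines(
                rng, P, cond.hospital_mean_rate, sd, settings.probability_bounds
            )
            b_c[w] = base
            mult = rng.uniform(mult_lo, mult_hi, size=(P, K))
            m_c[w] = np.clip(base[:, None] * mult, lo_p, hi_p)
            u = rng.uniform(0.0, 1.0, size=(P, K))
            if tri[0] == tri[2]:
                draw = np.full((P, K), float(tri[0]))
            else:
                c = (tri[1] - tri[0]) / (tri[2] - tri[0])
                draw = stats.triang.ppf(u, c, loc=tri[0], scale=tri[2] - tri[0])
            if settings.cost_sorting:
                draw = np.sort(draw, axis=1)[:, ::-1]
            a_c[w] = draw
        costs[cond.condition_id] = a_c
        mu_hat[cond.condition_id] = m_c
        baselines[cond.condition_id] = b_c
    probs = np.full(n_scenarios, 1.0 / n_scenarios)
    return ScenarioSet(
        condition_ids=spec.condition_ids,
        probabilities=probs,
        costs=costs,
        mu_hat=mu_hat,
        plan_tiers=tiers,
        seed=settings.seed,
        settings=settings,
        baselines=baselines,
    ).check()


# ---------------------------------------------------------------------------
# CSV + JSON sidecar round trip

def write_scenarios(scen: ScenarioSet, csv_path: str | Path) -> None:
    """Write a ScenarioSet to long-format CSV plus a JSON sidecar.

    CSV columns: scenario, condition, patient, plan, tier, cost, mu_hat.
    The sidecar (<csv>.meta.json) carries p(ω), the seed and settings.
    """
    csv_path = Path(csv_path)
    frames = []
    for cid in scen.condition_ids:
        n, P, K = scen.costs[cid].shape
        idx = np.indices((n, P, K))
        frames.append(
            pd.DataFrame(
                {
                    "scenario": idx[0].ravel(),
                    "condition": cid,
                    "patient": idx[1].ravel(),
                    "plan": idx[2].ravel(),
                    "tier": np.asarray(scen.plan_tiers[cid])[idx[2].ravel()],
                    "cost": scen.costs[cid].ravel(),
                    "mu_hat": scen.mu_hat[cid].ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "condition_ids": list(scen.condition_ids),
        "probabilities": scen.probabilities.tolist(),
        "seed": scen.seed,
        "settings": {
            "seed": scen.settings.seed,
            "tier_multiplier_ranges": [list(r) for r in scen.settings.tier_multiplier_ranges],
            "probability_bounds": list(scen.settings.probability_bounds),
            "cost_sorting": scen.settings.cost_sorting,
        },
        "plan_tiers": {cid: list(t) for cid, t in scen.plan_tiers.items()},
    }
    csv_path.with_suffix(csv_path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1)
    )


def read_scenarios(csv_path: str | Path) -> ScenarioSet:
    """Inverse of :func:`write_scenarios`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    meta = json.loads(csv_path.with_suffix(csv_path.suffix + ".meta.json").read_text())
    costs: dict[str, np.ndarray] = {}
    mu_hat: dict[str, np.ndarray] = {}
    for cid in meta["condition_ids"]:
        sub = df[df["condition"] == cid]
        n = int(sub["scenario"].max()) + 1
        P = int(sub["patient"].max()) + 1
        K = int(sub["plan"].max()) + 1
        sub = sub.sort_values(["scenario", "patient", "plan"])
        costs[cid] = sub["cost"].to_numpy().reshape(n, P, K)
        mu_hat[cid] = sub["mu_hat"].to_numpy().reshape(n, P, K)
    s = meta["settings"]
    settings = GeneratorSettings(
        seed=s["seed"],
        tier_multiplier_ranges=tuple(tuple(r) for r in s["tier_multiplier_ranges"]),
        probability_bounds=tuple(s["probability_bounds"]),
        cost_sorting=s["cost_sorting"],
    )
    return ScenarioSet(
        condition_ids=tuple(meta["condition_ids"]),
        probabilities=np.asarray(meta["probabilities"]),
        costs=costs,
        mu_hat=mu_hat,
        plan_tiers={cid: tuple(t) for cid, t in meta["plan_tiers"].items()},
        seed=meta["seed"],
        settings=settings,
    ).check()
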
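"""Deterministic equivalent of the Gaussian readmission chance constraint.

The care-strategy model requires, per condition, that the mean readmission
probability of the selected plans stay below a target θ with confidence β:

    P( Σ_p μ_p / |P|  ≤  θ )  ≥  β,

where each selected plan's realized readmission probability is Gaussian,
μ_p ~ N(μ̂_p, λ·μ̂_p) (mean μ̂_p, variance λ·μ̂_p), independently across
patients.  Because the variance of the selected sum is λ times its mean,
the chance constraint is equivalent to a single deterministic cap on the
sum of the selected means:

    Σ_p μ̂_p  ≤  μ*,   where   θ|P| − μ* = sqrt(λ μ*) · Φ⁻¹(β).

With z = Φ⁻¹(β) the defining equation is a quadratic in s = sqrt(μ*):
s² + sqrt(λ)·z·s − θ|P| = 0, whose two roots have product −θ|P| < 0, so
exactly one root is positive and μ* = s² is unique.

This module provides the closed-form threshold, a bisection-based
root-finder used as an internal consistency check, and a Monte-Carlo
oracle that estimates the chance constraint's left-hand side directly by
simulating the (untruncated) Gaussian response model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ChanceThreshold",
    "inverse_normal_cdf",
    "deterministic_threshold",
    "threshold_by_bisection",
    "chance_coverage_oracle",
]


def inverse_normal_cdf(beta: float) -> float:
    """Standard-normal quantile Φ⁻¹(β) for β strictly inside (0, 1)."""
    if not (0.0 < beta < 1.0):
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    return float(stats.norm.ppf(beta))


@dataclass(frozen=True)
class ChanceThreshold:
    """The deterministic-equivalent cap μ* for one condition.

    ``mu_star`` is the unique positive root of
    θ|P| − m = sqrt(λ m)·Φ⁻¹(β); any selection with Σ μ̂ ≤ μ* meets the
    θ-target with probability ≥ β under the Gaussian response model.
    ``degenerate`` flags the θ|P| = 0 corner where the constraint forces
    zero readmission mass.
    """

    condition_id: str
    beta: float
    theta: float
    n_patients: int
    lam: float
    mu_star: float
    degenerate: bool = False

    @property
    def residual(self) -> float:
        """θ|P| − μ* − sqrt(λ μ*)·Φ⁻¹(β); ~0 for a valid threshold."""
        z = inverse_normal_cdf(self.beta)
        return (
            self.theta * self.n_patients
            - self.mu_star
            - math.sqrt(self.lam * self.mu_star) * z
        )


def deterministic_threshold(
    theta: float,
    n_patients: int,
    lam: float,
    beta: float,
    condition_id: str = "",
) -> ChanceThreshold:
    """Closed-form μ* for target θ, |P| patients, variance scale λ, level β.

    β = 0.5 gives μ* = θ|P| exactly (the Gaussian median); μ* decreases
    strictly in β.  β < 0.5 is allowed and gives μ* > θ|P|.
    """
    if not (0.0 < theta <= 1.0):
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    if n_patients < 0:
        raise ValueError(f"n_patients must be >= 0, got {n_patients}")
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    target_mass = theta * n_patients
    if target_mass == 0.0:
        return ChanceThreshold(condition_id, beta, theta, n_patients, lam, 0.0, True)
    z = inverse_normal_cdf(beta)
    if z == 0.0:
        mu_star = target_mass
    else:
        s = (-math.sqrt(lam) * z + math.sqrt(lam * z * z + 4.0 * target_mass)) / 2.0
        mu_star = s * s
    return ChanceThreshold(condition_id, beta, theta, n_patients, lam, mu_star)


def threshold_by_bisection(
    theta: float, n_patients: int, lam: float, beta: float
) -> float:
    """μ* by bracketed root-finding on the defining equation.

    Serves as an internal cross-check for the closed form; agrees with it
    to better than 1e-10 relative.
    """
    z = inverse_normal_cdf(beta)
    target_mass = theta * n_patients
    if target_mass == 0.0:
        return 0.0

    def f(m: float) -> float:
        return target_mass - m - math.sqrt(lam * m) * z

    hi = (math.sqrt(target_mass) + math.sqrt(lam) * abs(z) + 1.0) ** 2
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-15, maxiter=500))


def chance_coverage_oracle(
    mu_hat_selected: Sequence[float],
    theta: float,
    lam: float,
    n_draws: int,
    seed: int | np.random.Generator,
) -> float:
    """Monte-Carlo estimate of P(Σ_p μ_p ≤ θ|P|) for a fixed selection.

    Draws μ_p ~ N(μ̂_p, λ·μ̂_p) independently per patient, *without*
    truncation — exactly the Gaussian model under which the deterministic
    equivalent is derived — and returns the fraction of draws whose
    patient sum stays within the target mass θ|P|.
    """
    mu_hat = np.asarray(mu_hat_selected, dtype=float)
    if mu_hat.size == 0:
        raise ValueError("selection must contain at least one patient")
    if np.any(mu_hat <= 0.0) or np.any(mu_hat >= 1.0):
        raise ValueError("selected means must lie strictly in (0, 1)")
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sd = np.sqrt(lam * mu_hat)
    target_mass = theta * mu_hat.size
    # The sum of independent Gaussians is simulated patient-by-patient in
    # blocks to bound memory at large n_draws.
    block = max(1, min(n_draws, 10_000_000 // mu_hat.size))
    hits = 0
    remaining = n_draws
    while remaining > 0:
        b = min(block, remaining)
        draws = rng.standard_normal((b, mu_hat.size)) * sd + mu_hat
        hits += int(np.count_nonzero(draws.sum(axis=1) <= target_mass))
        remaining -= b
    return hits / n_draws
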
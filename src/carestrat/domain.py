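"""Hospital decision-instance data model.

A hospital instance describes, for each HRRP condition, the target
readmission rate (the peer-group mean the hospital wants to stay under),
the hospital's own current mean readmission rate, the expected patient
volume over the decision period, a triangular cost distribution for its
treatment plans, and the tier structure of those plans.  All rates are
stored as probabilities on (0, 1); dollar amounts are plain USD floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "ConditionSpec",
    "HospitalSpec",
    "BetaVector",
    "SpecFormatError",
    "SpecValidationError",
    "load_hospital_spec",
    "write_hospital_spec",
    "example_spec",
]

#: λ_c used when a condition omits it: coefficient of variance assumed
#: identical across conditions in the reference experiments.
DEFAULT_LAMBDA = 0.25

#: Default tier split of the 10 treatment plans: Tier 1 = plans 1-3,
#: Tier 2 = plans 4-7, Tier 3 = plans 8-10.
DEFAULT_TIER_SIZES = (3, 4, 3)


class SpecFormatError(ValueError):
    """The config text does not parse as the documented schema."""


class SpecValidationError(ValueError):
    """One or more instance invariants are violated.

    ``errors`` carries every violation found, not just the first.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid hospital spec:\n  - " + "\n  - ".join(self.errors))


@dataclass(frozen=True)
class ConditionSpec:
    """One HRRP condition of a hospital instance.

    Parameters
    ----------
    condition_id:
        Short label, e.g. ``"AMI"``.
    target_rate:
        θ_c — target readmission rate, a probability in (0, 1].
    hospital_mean_rate:
        μ_c — the hospital's current mean readmission probability, in (0, 1).
    variance_coefficient:
        λ_c — scale of the Gaussian response model (variance of a selected
        plan's realized readmission probability is λ_c·μ̂).
    n_patients:
        |P_c| — expected number of patients in the decision period.
    cost_triangular:
        (min, mode, max) of the treatment-plan cost distribution, USD.
    n_plans:
        |K_c| — number of treatment plans per patient.
    tier_sizes:
        Plans per tier, ordered Tier 1 → Tier 3, summing to ``n_plans``.
    """

    condition_id: str
    target_rate: float
    hospital_mean_rate: float
    n_patients: int
    cost_triangular: tuple[float, float, float]
    variance_coefficient: float = DEFAULT_LAMBDA
    n_plans: int = 10
    tier_sizes: tuple[int, ...] = DEFAULT_TIER_SIZES

    def validation_errors(self) -> list[str]:
        e = []
        cid = self.condition_id
        if not cid:
            e.append("condition_id must be a non-empty label")
        if not (0.0 < self.target_rate <= 1.0):
            e.append(f"{cid}: target_rate must be in (0, 1], got {self.target_rate}")
        if not (0.0 < self.hospital_mean_rate < 1.0):
            e.append(
                f"{cid}: hospital_mean_rate must be in (0, 1), got {self.hospital_mean_rate}"
            )
        if not self.variance_coefficient > 0:
            e.append(f"{cid}: lambda must be > 0, got {self.variance_coefficient}")
        if not (isinstance(self.n_patients, int) and self.n_patients >= 1):
            e.append(f"{cid}: n_patients must be a positive integer, got {self.n_patients}")
        tri = self.cost_triangular
        if len(tri) != 3:
            e.append(f"{cid}: cost_triangular must be a (min, mode, max) triple")
        else:
            lo, mode, hi = tri
            if not (lo <= mode <= hi):
                e.append(f"{cid}: cost_triangular must satisfy min <= mode <= max, got {tri}")
            if lo <= 0:
                e.append(f"{cid}: cost_triangular min must be > 0, got {lo}")
        if not (isinstance(self.n_plans, int) and self.n_plans >= 1):
            e.append(f"{cid}: n_plans must be a positive integer, got {self.n_plans}")
        if any((not isinstance(t, int)) or t < 1 for t in self.tier_sizes):
            e.append(f"{cid}: tier_sizes must be positive integers, got {self.tier_sizes}")
        elif sum(self.tier_sizes) != self.n_plans:
            e.append(
                f"{cid}: tier_sizes {self.tier_sizes} must sum to n_plans={self.n_plans}"
            )
        return e

    @property
    def plan_tiers(self) -> tuple[int, ...]:
        """Tier index (1-based) of each plan k = 0..|K_c|-1."""
        tiers: list[int] = []
        for t, size in enumerate(self.tier_sizes, start=1):
            tiers.extend([t] * size)
        return tuple(tiers)

    @property
    def penalized(self) -> bool:
        """Strict exceedance of the target: μ_c > θ_c."""
        return self.hospital_mean_rate > self.target_rate


@dataclass(frozen=True)
class HospitalSpec:
    """A full hospital decision instance (one row per HRRP condition)."""

    hospital_id: str
    annual_penalty: float
    conditions: tuple[ConditionSpec, ...]
    decision_period: str = "3 months"

    def validation_errors(self) -> list[str]:
        e = []
        if self.annual_penalty < 0:
            e.append(f"annual_penalty must be >= 0, got {self.annual_penalty}")
        if not self.conditions:
            e.append("conditions must be non-empty")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            e.append(f"condition ids must be unique, got {ids}")
        for c in self.conditions:
            e.extend(c.validation_errors())
        return e

    def validate(self) -> "HospitalSpec":
        errors = self.validation_errors()
        if errors:
            raise SpecValidationError(errors)
        return self

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return tuple(c.condition_id for c in self.conditions)

    def condition(self, condition_id: str) -> ConditionSpec:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    def penalized_condition_ids(self) -> tuple[str, ...]:
        """Conditions whose hospital mean strictly exceeds the target rate.

        This mirrors the penalty test against the peer-group level: a
        condition is flagged when μ_c > θ_c (a hospital exactly at the
        target is not flagged).
        """
        return tuple(c.condition_id for c in self.conditions if c.penalized)


@dataclass(frozen=True)
class BetaVector:
    """Per-condition confidence levels β_c, each strictly in (0, 1)."""

    levels: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "levels", dict(self.levels))

    @classmethod
    def uniform(cls, spec: HospitalSpec, beta: float) -> "BetaVector":
        return cls({cid: beta for cid in spec.condition_ids})

    def with_level(self, condition_id: str, beta: float) -> "BetaVector":
        levels = dict(self.levels)
        levels[condition_id] = beta
        return BetaVector(levels)

    def __getitem__(self, condition_id: str) -> float:
        return self.levels[condition_id]

    def validate_for(self, spec: HospitalSpec) -> "BetaVector":
        errors = []
        for cid in spec.condition_ids:
            if cid not in self.levels:
                errors.append(f"missing confidence level for condition {cid}")
            elif not (0.0 < self.levels[cid] < 1.0):
                errors.append(
                    f"{cid}: confidence level must be in (0, 1), got {self.levels[cid]}"
                )
        extra = set(self.levels) - set(spec.condition_ids)
        if extra:
            errors.append(f"confidence levels for unknown conditions: {sorted(extra)}")
        if errors:
            raise SpecValidationError(errors)
        return self


# ---------------------------------------------------------------------------
# Serialization (YAML; JSON is a YAML subset and parses too)

_REQUIRED_CONDITION_KEYS = (
    "id",
    "target_rate",
    "hospital_mean_rate",
    "n_patients",
    "cost_triangular",
)


def _condition_from_mapping(m: Mapping) -> ConditionSpec:
    for key in _REQUIRED_CONDITION_KEYS:
        if key not in m:
            raise SpecFormatError(f"condition block missing required key '{key}': {m}")
    tri = m["cost_triangular"]
    if not isinstance(tri, (list, tuple)) or len(tri) != 3:
        raise SpecFormatError(
            f"key 'cost_triangular' must be a [min, mode, max] list, got {tri!r}"
        )
    return ConditionSpec(
        condition_id=str(m["id"]),
        target_rate=float(m["target_rate"]),
        hospital_mean_rate=float(m["hospital_mean_rate"]),
        variance_coefficient=float(m.get("lambda", DEFAULT_LAMBDA)),
        n_patients=int(m["n_patients"]),
        cost_triangular=tuple(float(x) for x in tri),
        n_plans=int(m.get("n_plans", 10)),
        tier_sizes=tuple(int(t) for t in m.get("tier_sizes", DEFAULT_TIER_SIZES)),
    )


def load_hospital_spec(source: str | Path) -> HospitalSpec:
    """Parse and validate a hospital spec from YAML/JSON text or a path.

    Raises
    ------
    SpecFormatError
        If the text does not parse or a required key is missing (the
        message names the offending key).
    SpecValidationError
        If any invariant is violated; all violations are listed.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SpecFormatError(f"hospital spec does not parse as YAML/JSON: {exc}") from exc
    if not isinstance(data, Mapping):
        raise SpecFormatError("hospital spec must be a mapping at the top level")
    for key in ("hospital_id", "annual_penalty", "conditions"):
        if key not in data:
            raise SpecFormatError(f"hospital spec missing required key '{key}'")
    conditions = tuple(_condition_from_mapping(m) for m in data["conditions"])
    spec = HospitalSpec(
        hospital_id=str(data["hospital_id"]),
        annual_penalty=float(data["annual_penalty"]),
        conditions=conditions,
        decision_period=str(data.get("decision_period", "3 months")),
    )
    return spec.validate()


def write_hospital_spec(spec: HospitalSpec, path: str | Path | None = None) -> str:
    """Emit YAML that :func:`load_hospital_spec` reparses to an equal spec."""
    data = {
        "hospital_id": spec.hospital_id,
        "annual_penalty": spec.annual_penalty,
        "decision_period": spec.decision_period,
        "conditions": [
            {
                "id": c.condition_id,
                "target_rate": c.target_rate,
                "hospital_mean_rate": c.hospital_mean_rate,
                "lambda": c.variance_coefficient,
                "n_patients": c.n_patients,
                "cost_triangular": list(c.cost_triangular),
                "n_plans": c.n_plans,
                "tier_sizes": list(c.tier_sizes),
            }
            for c in spec.conditions
        ],
    }
    text = yaml.safe_dump(data, sort_keys=False, default_flow_style=None)
    if path is not None:
        Path(path).write_text(text)
    return text


def example_spec(which: str = "A") -> HospitalSpec:
    """Load one of the packaged example hospitals.

    ``"A"`` is the low-performing instance (five conditions above target),
    ``"B"`` the high-performing one (one condition above target).
    """
    from importlib.resources import files

    name = {"A": "hospital_a.yaml", "B": "hospital_b.yaml"}[which.upper()]
    return load_hospital_spec(files("carestrat.data").joinpath(name).read_text())
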
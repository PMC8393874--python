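import numpy as np
import pytest

import carestrat as cs


@pytest.fixture(scope="session")
def hospital_a() -> cs.HospitalSpec:
    return cs.example_spec("A")


@pytest.fixture(scope="session")
def hospital_b() -> cs.HospitalSpec:
    return cs.example_spec("B")


@pytest.fixture(scope="session")
def scenarios_a(hospital_a) -> cs.ScenarioSet:
    """50 scenarios for the low-performing example hospital, fixed seed."""
    return cs.generate_scenarios(hospital_a, 50, cs.GeneratorSettings(seed=1))


@pytest.fixture(scope="session")
def scenarios_b(hospital_b) -> cs.ScenarioSet:
    return cs.generate_scenarios(hospital_b, 50, cs.GeneratorSettings(seed=1))


@pytest.fixture
def tiny_spec() -> cs.HospitalSpec:
    """A two-condition toy hospital small enough for exhaustive checks."""
    return cs.HospitalSpec(
        hospital_id="toy",
        annual_penalty=1000.0,
        conditions=(
            cs.ConditionSpec(
                condition_id="C1",
                target_rate=0.2,
                hospital_mean_rate=0.25,
                n_patients=3,
                cost_triangular=(100.0, 150.0, 300.0),
                n_plans=4,
                tier_sizes=(1, 2, 1),
            ),
            cs.ConditionSpec(
                condition_id="C2",
                target_rate=0.15,
                hospital_mean_rate=0.1,
                n_patients=2,
                cost_triangular=(50.0, 80.0, 120.0),
                n_plans=3,
                tier_sizes=(1, 1, 1),
            ),
        ),
    ).validate()


def manual_scenario_set(mu_hat_by_cid, costs_by_cid, tiers_by_cid, probs=None):
    """Build a ScenarioSet directly from arrays (for hand-crafted tests)."""
    cids = tuple(mu_hat_by_cid)
    n = next(iter(mu_hat_by_cid.values())).shape[0]
    p = np.asarray(probs) if probs is not None else np.full(n, 1.0 / n)
    return cs.ScenarioSet(
        condition_ids=cids,
        probabilities=p,
        costs={c: np.asarray(a, float) for c, a in costs_by_cid.items()},
        mu_hat={c: np.asarray(a, float) for c, a in mu_hat_by_cid.items()},
        plan_tiers=tiers_by_cid,
        seed=0,
        settings=cs.GeneratorSettings(seed=0),
    )
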
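"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest

from hdxsim import (
    ExchangeConditions,
    ProtectionProfile,
    Workflow,
    WorkflowStage,
    load_default_table,
)
from hdxsim.scenarios import (
    DIGESTION_CONDITIONS,
    LABELING_CONDITIONS,
    LC_CONDITIONS,
    standard_bottom_up_workflow,
)


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def labeling_conditions() -> ExchangeConditions:
    return LABELING_CONDITIONS


@pytest.fixture(scope="session")
def quench_conditions() -> ExchangeConditions:
    return LC_CONDITIONS


@pytest.fixture()
def standard_workflow() -> Workflow:
    return standard_bottom_up_workflow()


def rk4_relax(start, rates, duration, target, dt=0.005):
    """Fixed-step classic Runge-Kutta integration of dD/dt = k (target - D).

    Brute-force time stepping, independent of the closed-form exponential
    used by the implementation. NaN rates hold their occupancy fixed at NaN.
    """
    d = np.array(start, dtype=float)
    k = np.nan_to_num(np.asarray(rates, dtype=float))
    nan_mask = np.isnan(np.asarray(rates, dtype=float))
    t = 0.0
    while t < duration - 1e-12:
        h = min(dt, duration - t)
        f1 = k * (target - d)
        f2 = k * (target - (d + 0.5 * h * f1))
        f3 = k * (target - (d + 0.5 * h * f2))
        f4 = k * (target - (d + h * f3))
        d = d + h / 6.0 * (f1 + 2 * f2 + 2 * f3 + f4)
        t += h
    d[nan_mask] = np.nan
    return d


def rk4_workflow(sequence, protection, workflow, table, start, dt=0.005):
    """Integrate a full multi-stage workflow with the RK4 oracle."""
    from hdxsim import stage_rates

    occ = np.array(start, dtype=float)
    for stage in workflow.stages:
        rates = stage_rates(sequence, stage, protection, table)
        occ = rk4_relax(occ, rates, stage.duration_s, stage.target_occupancy, dt=dt)
    return occ * workflow.esi_retention


def random_workflow(rng: np.random.Generator, n_res: int):
    """A randomized labeling/back-exchange stage sequence for oracle checks.

    Durations are kept modest (the oracle is a fixed-step integrator) and
    labeling protection is at least log P = 1 so rate * step stays small.
    """
    protection = ProtectionProfile(rng.uniform(1.0, 5.0, size=n_res))
    stages = []
    for i in range(int(rng.integers(1, 4))):
        if rng.random() < 0.5:
            stages.append(
                WorkflowStage(
                    f"label{i}", float(rng.uniform(2.0, 30.0)),
                    LABELING_CONDITIONS, True, 1.0,
                )
            )
        else:
            conditions = DIGESTION_CONDITIONS if rng.random() < 0.5 else LC_CONDITIONS
            stages.append(
                WorkflowStage(
                    f"bx{i}", float(rng.uniform(5.0, 60.0)), conditions, False, 0.0
                )
            )
    esi = float(rng.uniform(0.9, 1.0))
    return protection, Workflow(stages=tuple(stages), esi_retention=esi)
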
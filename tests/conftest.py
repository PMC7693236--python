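"""Shared fixtures: a desk-scale scenario and one simulated fraction, reused
across test modules to keep the suite fast."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from fragmon.synthetic import (
    PlanSpec,
    ScenarioConfig,
    build_plan,
    make_phantom,
    simulate_fraction,
)
from fragmon.pipeline import PipelineConfig, plan_spbs, process_fraction


def small_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """A scaled-down scenario (~50 spots x 3 slices) for unit-level tests."""
    base = ScenarioConfig(
        plan=PlanSpec(half_extent_mm=9.0, spacing_mm=3.0,
                      end_depths_mm=(40.0, 52.0, 64.0)),
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


@pytest.fixture(scope="session")
def scenario():
    return small_scenario(seed=42)


@pytest.fixture(scope="session")
def plan(scenario):
    return build_plan(scenario)


@pytest.fixture(scope="session")
def phantom(scenario):
    return make_phantom(scenario.phantom)


@pytest.fixture(scope="session")
def spbs(scenario, plan, phantom):
    return plan_spbs(plan, phantom, scenario.range_shifter_wet_mm)


@pytest.fixture(scope="session")
def sim(scenario, plan):
    return simulate_fraction(scenario, 0, plan=plan)


@pytest.fixture(scope="session")
def processed(scenario, plan, spbs, sim):
    pipe = PipelineConfig(rs_z_mm=scenario.rs_z_mm)
    return process_fraction(sim.tracks, plan, spbs, scenario.pose(), pipe)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
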
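"""Shared fixtures: paired emission-scenario runs and a century run.

The expensive engine runs are session-scoped so the paired comparisons and
budget checks reuse them.  All runs share one weather seed, the paired
design in which scenario contrasts are purely scenario-driven.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import baltfate as bf

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")

#: weather seed of the paired scenario experiment
SEED = 20
#: horizon window (inclusive years) for effectiveness metrics
HORIZON = (2015, 2025)


@pytest.fixture(scope="session")
def control_config() -> bf.SimulationConfig:
    return bf.SimulationConfig(start_year=1990, end_year=2030, seed=SEED)


@pytest.fixture(scope="session")
def control_run(control_config) -> bf.SimulationOutput:
    return bf.run_simulation(control_config)


@pytest.fixture(scope="session")
def red_river_run(control_config) -> bf.SimulationOutput:
    cfg = control_config.with_scenario(
        bf.ScenarioSpec(emissions="red_river", reduction_year=2006,
                        reduction_fraction=0.9))
    return bf.run_simulation(cfg)


@pytest.fixture(scope="session")
def red_air_run(control_config) -> bf.SimulationOutput:
    cfg = control_config.with_scenario(
        bf.ScenarioSpec(emissions="red_air", reduction_year=2006,
                        reduction_fraction=0.9))
    return bf.run_simulation(cfg)


@pytest.fixture(scope="session")
def century_run() -> bf.SimulationOutput:
    cfg = bf.SimulationConfig(start_year=1990, end_year=2089, seed=SEED)
    return bf.run_simulation(cfg)
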
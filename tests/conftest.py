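"""Shared fixtures: canonical scenario runs, executed once per session."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import venapump as vp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clino_result() -> vp.ScenarioResult:
    return vp.run_scenario("clinostatism")


@pytest.fixture(scope="session")
def ortho_result() -> vp.ScenarioResult:
    return vp.run_scenario("orthostatism")


@pytest.fixture(scope="session")
def walk_healthy() -> vp.ScenarioResult:
    return vp.run_scenario("walking_healthy")


@pytest.fixture(scope="session")
def walk_severe() -> vp.ScenarioResult:
    return vp.run_scenario("walking_severe")


@pytest.fixture(scope="session")
def walk_partial() -> vp.ScenarioResult:
    return vp.run_scenario("walking_partial")


@pytest.fixture(scope="session")
def all_walking(walk_healthy, walk_severe, walk_partial):
    return {"walking_healthy": walk_healthy,
            "walking_severe": walk_severe,
            "walking_partial": walk_partial}
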
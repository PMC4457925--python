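"""Shared fixtures: scenario histograms are expensive, so cache per session."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from flowcycle.scenarios import build_histograms, get_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario_data():
    """name -> (sample, exponential histogram, run-out histogram), built once."""
    cache: dict = {}

    def get(name: str):
        if name not in cache:
            cache[name] = build_histograms(get_scenario(name))
        return cache[name]

    return get
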
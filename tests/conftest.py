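"""Shared fixtures: default configuration, homeostatic state, evolved trajectories.

The expensive pipeline artifacts (homeostasis search, full evolution runs)
are computed once per session and shared by the pipeline and acceptance
tests; everything is generated programmatically from the default
configuration, no external data.
"""

from __future__ import annotations

import copy
import warnings

import pytest

from fsgsim.config import RunConfig
from fsgsim.pipeline import initialize_state, run_evolution, run_homeostasis


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def homeostasis_result(default_cfg):
    """Converged initial-homeostasis search on the default idealized sac."""
    state, waveform = initialize_state(default_cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_homeostasis(state, waveform, default_cfg)
    return result, waveform


@pytest.fixture()
def homeostatic_state(homeostasis_result):
    """A fresh deep copy of the homeostatic state (mutable per test)."""
    result, waveform = homeostasis_result
    return copy.deepcopy(result.state), waveform


@pytest.fixture(scope="session")
def low_wss_trajectory(homeostasis_result, default_cfg):
    """Full 150-step low-WSS degradation + stabilization run."""
    result, waveform = homeostasis_result
    state = copy.deepcopy(result.state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj = run_evolution(state, waveform, default_cfg, scenario="low_wss")
    return traj
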
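"""Shared fixtures: nominal parameters and the reference runs reused
across tests (single-cell beat, cable run, synthetic AP ensemble)."""

import numpy as np
import pytest

from prmodel.analysis import measure_ap
from prmodel.engine import (
    SimulationConfig,
    StimulusSpec,
    resting_state,
    simulate_cell,
)
from prmodel.model_core import default_parameters
from prmodel.spatial import CableConfig, simulate_cable
from prmodel.synthetic import EnsembleSpec, generate_ap_ensemble

PACING_STIM = StimulusSpec(amplitude=-20.0, duration=2.0)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def rest_state(params):
    na, k = params
    return resting_state(na, k)


@pytest.fixture(scope="session")
def cell_beat(params, rest_state):
    """One nominal AP: 2 ms, -20 uA/uF pulse from rest, dt = 0.001 ms."""
    na, k = params
    cfg = SimulationConfig(dt=0.001, record_stride=1)
    return simulate_cell(rest_state, PACING_STIM, cfg, 400.0, na=na, k=k)


@pytest.fixture(scope="session")
def cell_metrics(cell_beat, rest_state):
    return measure_ap(cell_beat, rest_vm=rest_state.vm)


@pytest.fixture(scope="session")
def cable_run(params):
    """Nominal 4 cm cable run (dx = 0.01 cm, dt = 0.001 ms, 300 ms)."""
    na, k = params
    return simulate_cable(na, k, CableConfig(), 300.0)


@pytest.fixture(scope="session")
def ap_ensemble(params):
    """Six synthetic myocyte AP waveforms (10 paced beats each)."""
    return generate_ap_ensemble(EnsembleSpec(n_cells=6, seed=1))
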
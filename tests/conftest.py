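"""Shared fixtures: the expensive steady states and 1-h perturbation runs
are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from mitoh2o2.model_core import default_initial_state, default_parameters
from mitoh2o2.simulate import find_steady_state, integrate


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def basal_states(params):
    """Basal steady states keyed by total Prx3 pool (uM)."""
    return {
        prx3: find_steady_state(default_initial_state(prx3), params)
        for prx3 in (48.0, 62.0, 96.0, 110.0)
    }


@pytest.fixture(scope="session")
def perturbation_endpoints(params, basal_states):
    """1-h endpoint states at Prx3 = 62 uM for the printed DAAO grid."""
    baseline = basal_states[62.0].state
    out = {}
    for kd in (0.0, 8.0, 23.0, 47.0, 54.0, 70.0):
        traj = integrate(baseline, params.with_values(kdaao=kd), 3600.0,
                         output_times=[3600.0])
        out[kd] = traj.final
    return out
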
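"""Shared fixtures; the long pattern-formation runs are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from ksnet.kinetics import Params
from ksnet.pde_sim import SimConfig, simulate


@pytest.fixture(scope="session")
def default_params() -> Params:
    return Params()


def _long_run(gamma: float, t_end: float = 180.0, snapshot_times=None,
              seed: int = 0):
    cfg = SimConfig(params=Params(gamma=gamma), t_end=t_end,
                    snapshot_times=snapshot_times or [0.0, t_end],
                    seed=seed)
    return simulate(cfg)


@pytest.fixture(scope="session")
def run_g01():
    """gamma=0.1 to t=15: homogeneous convergence, numerically stationary."""
    return _long_run(0.1, t_end=15.0, snapshot_times=[0.0, 3.0, 15.0])


@pytest.fixture(scope="session")
def run_g02():
    return _long_run(0.2)


@pytest.fixture(scope="session")
def run_g025():
    """gamma=0.25 network run with dense snapshots for the trace analysis."""
    snaps = list(np.round(np.arange(0.0, 180.0 + 0.25, 0.5), 6))
    return _long_run(0.25, snapshot_times=snaps)


@pytest.fixture(scope="session")
def run_g029():
    return _long_run(0.29)


@pytest.fixture(scope="session")
def ode4_enumerations(default_params):
    """phi-route and brute-force Newton equilibrium sets at b in {10,15,25}."""
    from ksnet.ode4 import classify_stability, find_equilibria, newton_equilibria

    out = {}
    for b in (10.0, 15.0, 25.0):
        via_phi = [classify_stability(e, default_params, b)
                   for e in find_equilibria(default_params, b)]
        via_newton = newton_equilibria(default_params, b)
        out[b] = (via_phi, via_newton)
    return out
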
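"""Shared fixtures: grids, analytic phantoms, and cached scenario runs."""

from __future__ import annotations

import numpy as np
import pytest

from phasecell import GridSpec, ModelParams
from phasecell import dynamics as dyn
from phasecell.scenarios import build_scenario


def tanh_sphere(grid: GridSpec, center, radius: float, width: float = 1.0):
    """Diffuse sphere ρ(r) = ½(1 − tanh((r − R)/w)); ρ ≈ 1 inside."""
    x, y, z = grid.meshgrid()
    r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2
                + (z - center[2]) ** 2)
    return 0.5 * (1.0 - np.tanh((r - radius) / width))


@pytest.fixture(scope="session")
def desk_params() -> ModelParams:
    """Scenario-scale integration controls: 1 μm lattice, dt = 0.02."""
    return ModelParams(dx=1.0, dt=0.02)


@pytest.fixture(scope="session")
def free_reference(desk_params):
    """Relaxed free cell (A0 + steady state) at the desk lattice."""
    A0, state = dyn.run_free_cell_reference(desk_params)
    return A0, state


_SCENARIO_CACHE: dict = {}


@pytest.fixture(scope="session")
def scenario_run():
    """Factory running a named scenario once per session and caching it.

    Returns (trajectory, info, substrate).  Runs are deterministic, so
    caching cannot change any outcome.
    """

    def _run(name: str, **overrides):
        key = (name, tuple(sorted(overrides.items())))
        if key not in _SCENARIO_CACHE:
            substrate, state, params, run_kw, info = build_scenario(
                name, **overrides)
            run_kw = dict(run_kw)
            traj = dyn.run_simulation(state, substrate, params, **run_kw)
            _SCENARIO_CACHE[key] = (traj, info, substrate)
        return _SCENARIO_CACHE[key]

    return _run
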
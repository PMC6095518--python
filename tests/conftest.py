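"""Shared fixtures.

The reference trajectory (the 4-whorl parameter set of the coupled model)
is session-scoped because several acceptance properties are read off the
same run; it uses the desk-scale schedule documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pytest

import phyllosim as ps


@pytest.fixture(scope="session")
def small_grid() -> ps.GridSpec:
    return ps.GridSpec(nx=16, ny=16, nz=16)


@pytest.fixture(scope="session")
def default_grid() -> ps.GridSpec:
    return ps.GridSpec()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def desk_config(eta: float, c: float, seed: int = 1, kappa: float = 2.0,
                g_width: float = 5.0, **schedule_kw) -> ps.RunConfig:
    """Desk-scale coupled-run configuration (see docs/methods.md)."""
    kw = dict(n_chem=400, n_mech=500, n_cycles=110, stress_every=50,
              stop_after_generations=1, on_divergence="truncate")
    kw.update(schedule_kw)
    return ps.RunConfig(
        chem=ps.BVAMParams(eta=eta, c=c),
        mech=ps.MechParams(kappa=kappa, g_width=g_width),
        schedule=ps.ScheduleParams(**kw),
        seed=seed,
    )


@pytest.fixture(scope="session")
def whorl4_trajectory() -> ps.SimulationTrajectory:
    """Reference coupled run at the 4-whorl parameter set (eta=0.3902,
    c=0.57, beta=0.5, gamma=0.2, kappa=2, tip width R/2), seed 1."""
    return ps.run_simulation(desk_config(eta=0.3902, c=0.57, seed=1))
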
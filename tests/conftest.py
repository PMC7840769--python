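"""Shared fixtures.

The reference treadmilling-speed sweep (10 speeds x 100 trajectories at
D = 0.04 um^2/s, U0 = 10 k_BT) is the most expensive object in the suite;
it is computed once per session and shared by the propensity, run-distance
and theory-comparison tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import endtrack as et

SWEEP_SPEEDS = tuple(range(10, 101, 10))
SWEEP_SEED = 2026


@pytest.fixture(scope="session")
def speed_sweep():
    """100 shrinking-end-start trajectories per treadmilling speed."""
    base = et.RatchetParams(D=4e4, U0=10.0, V_Z=25.0, t_max=120.0)
    out = {}
    for vz in SWEEP_SPEEDS:
        p = base.replace(
            V_Z=float(vz),
            seed=int(np.random.SeedSequence((SWEEP_SEED, vz)).generate_state(1)[0] >> 1),
            dt=et.choose_dt(4e4, 10.0, float(vz)),
        )
        out[vz] = et.simulate_ensemble(p, n_traj=100)
    return out


@pytest.fixture(scope="session")
def speed_sweep_classified(speed_sweep):
    """Per-speed (n_persistent, RunStats) under the default criteria."""
    crit = et.EndTrackCriteria()
    out = {}
    for vz, trajs in speed_sweep.items():
        res = [et.classify_end_tracking(t, crit) for t in trajs]
        n_persistent = sum(flag for flag, _ in res)
        runs = et.RunStats.concat([r for _, r in res])
        out[vz] = (n_persistent, runs)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
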
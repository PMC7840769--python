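"""Trajectory and ensemble drivers for the end-tracking scenarios.

Scenarios: the enzyme starts at the shrinking end (the default used for
processivity statistics), at a uniformly random live subunit center
(mid-filament, used for bound-lifetime statistics), or at the growing end
(a control that fails to produce directional motion).  Multi-enzyme runs
add pairwise hard-core exclusion ("knock-off").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import _kernels
from .params import RatchetParams

#: default recorded cadence, s (matches a 0.05 s plotting interval)
RECORD_CADENCE = 0.05

#: default escape margin beyond either filament end, nm
ESCAPE_MARGIN = 100.0

#: a trajectory terminates after being continuously escaped this long, s
ESCAPE_PERSIST = 1.0

_INIT_MODES = ("at_shrinking_end", "mid_filament", "at_growing_end")


@dataclass(frozen=True)
class ScenarioSpec:
    """Initial condition and tracked end for a simulation run."""

    init_mode: str = "at_shrinking_end"
    n_enzymes: int = 1
    track_end: str = "shrinking"

    def __post_init__(self) -> None:
        if self.init_mode not in _INIT_MODES:
            raise ValueError(f"init_mode must be one of {_INIT_MODES}")
        if self.n_enzymes < 1:
            raise ValueError("n_enzymes must be >= 1")
        if self.track_end not in ("shrinking", "growing"):
            raise ValueError("track_end must be 'shrinking' or 'growing'")


@dataclass
class Trajectory:
    """Recorded time series of one enzyme on one treadmilling filament."""

    t: np.ndarray          # s
    x: np.ndarray          # enzyme position, nm
    x_S: np.ndarray        # shrinking-end subunit center, nm
    x_G: np.ndarray        # growing-end subunit center, nm
    bound: np.ndarray      # True while within range a of a live subunit
    params: RatchetParams
    scenario: ScenarioSpec
    seed: int
    first_escape: float    # s; NaN if the enzyme never left the margin
    censored: bool         # True if the run hit t_max without escaping

    def __len__(self) -> int:
        return self.t.size


@dataclass
class MultiTrajectory:
    """Recorded multi-enzyme run; ``x`` has shape (n_enzymes, n_samples)."""

    t: np.ndarray
    x: np.ndarray
    x_S: np.ndarray
    x_G: np.ndarray
    params: RatchetParams
    seed: int
    first_escape: np.ndarray   # s per enzyme; NaN if never escaped
    censored: np.ndarray       # bool per enzyme

    @property
    def n_enzymes(self) -> int:
        return self.x.shape[0]

    def enzyme(self, e: int) -> Trajectory:
        """View of enzyme ``e`` as a single-enzyme Trajectory."""
        return Trajectory(
            t=self.t,
            x=self.x[e],
            x_S=self.x_S,
            x_G=self.x_G,
            bound=np.zeros(self.t.size, dtype=bool),
            params=self.params,
            scenario=ScenarioSpec(n_enzymes=self.x.shape[0]),
            seed=self.seed,
            first_escape=float(self.first_escape[e]),
            censored=bool(self.censored[e]),
        )


def _derive_seeds(master: int, n: int) -> np.ndarray:
    """Deterministic, independent per-trajectory seeds below 2**31."""
    ss = np.random.SeedSequence(master)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def _initial_position(params: RatchetParams, mode: str, rng: np.random.Generator) -> float:
    if mode == "at_shrinking_end":
        return 0.0
    if mode == "at_growing_end":
        return (params.N_fil - 1) * params.L0
    # mid_filament: a uniformly random live subunit center
    idx = int(rng.integers(params.N_fil))
    return idx * params.L0


def default_record_every(dt: float, cadence: float = RECORD_CADENCE) -> int:
    return max(1, int(round(cadence / dt)))


def simulate_trajectory(
    params: RatchetParams,
    scenario: Optional[ScenarioSpec] = None,
    record_every: Optional[int] = None,
    escape_margin: float = ESCAPE_MARGIN,
) -> Trajectory:
    """Run one stochastic trajectory until ``t_max`` or escape.

    Open boundaries: the enzyme may wander off either side; a run is cut
    short once it has stayed more than ``escape_margin`` beyond both
    filament ends for longer than 1 s, since free diffusion far from the
    filament carries no further information.
    """
    scenario = scenario or ScenarioSpec()
    params.validate_stability()
    _ = params.steps_per_event  # raises if dt too large for V_Z
    if record_every is None:
        record_every = default_record_every(params.dt)
    rng = np.random.default_rng(params.seed)
    x0 = _initial_position(params, scenario.init_mode, rng)
    kseed = int(rng.integers(2**31))
    n_steps = int(round(params.t_max / params.dt))
    persist = max(1, int(round(ESCAPE_PERSIST / params.dt)))
    rec_x, rec_xs, rec_bound, n_rec, first_out, end_step = _kernels.trajectory_kernel(
        kseed,
        x0,
        0.0,
        params.N_fil,
        params.L0,
        params.a,
        params.U0,
        params.D,
        params.V_Z,
        params.dt,
        n_steps,
        record_every,
        escape_margin,
        persist,
    )
    t = np.arange(n_rec) * record_every * params.dt
    x = rec_x[:n_rec].copy()
    x_s = rec_xs[:n_rec].copy()
    span = (params.N_fil - 1) * params.L0
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("enzyme position became non-finite during run")
    return Trajectory(
        t=t,
        x=x,
        x_S=x_s,
        x_G=x_s + span,
        bound=rec_bound[:n_rec].astype(bool),
        params=params,
        scenario=scenario,
        seed=kseed,
        first_escape=first_out * params.dt if first_out >= 0 else float("nan"),
        censored=first_out < 0,
    )


def draw_treadmill_speed(mean: float, cv: float, rng: np.random.Generator) -> float:
    """One filament's treadmilling speed: Gaussian, redrawn until positive.

    ``cv`` is the coefficient of variation (SD/mean); measured in vivo
    spreads are ~30 % of the mean.
    """
    if mean <= 0:
        raise ValueError("mean treadmilling speed must be positive")
    if not 0 <= cv < 1:
        raise ValueError("cv must lie in [0, 1)")
    if cv == 0:
        return float(mean)
    while True:
        v = rng.normal(mean, cv * mean)
        if v > 0:
            return float(v)


def simulate_ensemble(
    params: RatchetParams,
    scenario: Optional[ScenarioSpec] = None,
    n_traj: int = 100,
    speed_dist: Optional[dict] = None,
    record_every: Optional[int] = None,
    escape_margin: float = ESCAPE_MARGIN,
) -> List[Trajectory]:
    """Independent seeded trajectories; V_Z fixed within each trajectory.

    ``speed_dist={"mean": .., "cv": ..}`` draws a treadmilling speed per
    trajectory (the ensemble-level stochasticity of filament kinetics);
    otherwise every trajectory uses ``params.V_Z``.  Two calls with the
    same ``params.seed`` are bit-identical.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    seeds = _derive_seeds(params.seed, n_traj)
    speed_rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xC0FFEE)))
    out: List[Trajectory] = []
    failures = []
    for i in range(n_traj):
        p = params.replace(seed=int(seeds[i]))
        if speed_dist is not None:
            v = draw_treadmill_speed(speed_dist["mean"], speed_dist["cv"], speed_rng)
            p = p.replace(V_Z=v)
        try:
            out.append(
                simulate_trajectory(
                    p, scenario, record_every=record_every, escape_margin=escape_margin
                )
            )
        except Exception as exc:  # noqa: BLE001 - reported with indices below
            failures.append((i, exc))
    if failures:
        idx = [i for i, _ in failures]
        raise RuntimeError(f"trajectories {idx} failed: {failures[0][1]}") from failures[0][1]
    return out


def simulate_multi_enzyme(
    params: RatchetParams,
    n_enzymes: int = 2,
    exclusion_rule: Optional[str] = "hardcore",
    init_positions: Optional[Sequence[float]] = None,
    record_every: Optional[int] = None,
    escape_margin: float = ESCAPE_MARGIN,
) -> MultiTrajectory:
    """Several enzymes on one filament, with hard-core knock-off exclusion.

    By default enzyme 0 starts at the shrinking end and the others at
    distinct random interior subunit centers.  ``exclusion_rule=None``
    makes the enzymes mutually transparent (each then behaves as an
    independent single-enzyme run).
    """
    if n_enzymes < 2:
        raise ValueError("n_enzymes must be >= 2")
    if exclusion_rule not in (None, "hardcore"):
        raise ValueError("exclusion_rule must be 'hardcore' or None")
    params.validate_stability()
    if record_every is None:
        record_every = default_record_every(params.dt)
    rng = np.random.default_rng(params.seed)
    if init_positions is None:
        interior = rng.choice(
            np.arange(1, params.N_fil), size=n_enzymes - 1, replace=False
        )
        x0 = np.concatenate(([0.0], np.sort(interior) * params.L0))
    else:
        x0 = np.asarray(init_positions, dtype=float)
        if x0.size != n_enzymes:
            raise ValueError("init_positions length must equal n_enzymes")
    kseed = int(rng.integers(2**31))
    n_steps = int(round(params.t_max / params.dt))
    persist = max(1, int(round(ESCAPE_PERSIST / params.dt)))
    rec_x, rec_xs, n_rec, first_out, end_step = _kernels.multi_enzyme_kernel(
        kseed,
        x0,
        0.0,
        params.N_fil,
        params.L0,
        params.a,
        params.U0,
        params.D,
        params.V_Z,
        params.dt,
        n_steps,
        record_every,
        escape_margin,
        persist,
        1 if exclusion_rule == "hardcore" else 0,
    )
    t = np.arange(n_rec) * record_every * params.dt
    span = (params.N_fil - 1) * params.L0
    x_s = rec_xs[:n_rec].copy()
    return MultiTrajectory(
        t=t,
        x=rec_x[:, :n_rec].copy(),
        x_S=x_s,
        x_G=x_s + span,
        params=params,
        seed=kseed,
        first_escape=np.where(first_out >= 0, first_out * params.dt, np.nan),
        censored=first_out < 0,
    )
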
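"""Ensemble analysis: end-tracking classification, processivity, phase
diagrams, bound lifetimes and binding-potential fitting.

Persistent end-tracking follows the single-molecule criteria used for the
experimental trajectories: the enzyme stays within ``max_gap`` (100 nm) of
the tracked filament end while making net forward progress, continuously
for at least ``min_duration`` (4 s).  A parameter point is scored as
end-tracking when at least half of its simulated trajectories contain
such a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import analytic
from .params import RatchetParams, choose_dt
from .simulate import (
    ESCAPE_MARGIN,
    ScenarioSpec,
    Trajectory,
    simulate_ensemble,
)


@dataclass(frozen=True)
class EndTrackCriteria:
    """Persistence criteria for a directional run.

    ``min_follow_fraction`` quantifies "persistently follows": over a
    candidate interval the enzyme's net advance must be at least this
    fraction of the end's advance.  Directional segments of genuine runs
    move at the treadmilling speed, so a substantial fraction separates
    following from an enzyme that has detached but still sits within
    ``max_gap`` while the end recedes past it.

    ``max_backtrack`` enforces "unidirectionally": a run ends once the
    enzyme falls more than this many nm below its forward maximum, even
    if it later re-advances (the re-advance opens a new run).  The
    default equals the catch-up failure distance — a few subunit lengths
    of lost ground against a receding end is the scale at which a ratchet
    step has failed.

    ``scope`` selects which runs count: "first" (default) scores only the
    run that begins at the start of the trajectory — the natural reading
    of a trajectory that "tracks the end persistently and
    unidirectionally" from its shrinking-end initial condition, and the
    quantity the closed-form run-statistics describe — while "any"
    accepts a qualifying run anywhere.

    ``cadence_s`` is the analysis sampling interval: the criteria are
    applied to the trajectory resampled at this cadence (default 1 s,
    the frame time of the single-molecule experiments these criteria
    mirror), so sub-frame excursions that would be invisible to the
    measurement do not break a run.
    """

    max_gap: float = 100.0          # nm, distance to the tracked end
    min_duration: float = 4.0       # s
    max_backtrack: float = 20.0     # nm
    min_follow_fraction: float = 0.5
    scope: str = "first"
    cadence_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.max_gap > 0 and self.min_duration > 0):
            raise ValueError("criteria must be positive")
        if not self.cadence_s > 0:
            raise ValueError("cadence_s must be positive")
        if not self.max_backtrack > 0:
            raise ValueError("max_backtrack must be positive")
        if not 0 <= self.min_follow_fraction <= 1:
            raise ValueError("min_follow_fraction must lie in [0, 1]")
        if self.scope not in ("first", "any"):
            raise ValueError("scope must be 'first' or 'any'")


@dataclass
class RunStats:
    """Per-run statistics of persistent directional segments."""

    speeds: np.ndarray     # nm/s
    durations: np.ndarray  # s
    distances: np.ndarray  # nm

    @property
    def n(self) -> int:
        return self.speeds.size

    @staticmethod
    def concat(items: Sequence["RunStats"]) -> "RunStats":
        if not items:
            return RunStats(np.empty(0), np.empty(0), np.empty(0))
        return RunStats(
            np.concatenate([r.speeds for r in items]),
            np.concatenate([r.durations for r in items]),
            np.concatenate([r.distances for r in items]),
        )


@dataclass
class PhaseDiagram:
    """Propensity matrix over a 2-parameter grid."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    propensity: np.ndarray  # shape (len(axis1), len(axis2)), in [0, 1]
    threshold: float = 0.5

    def above_threshold(self) -> np.ndarray:
        return self.propensity >= self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.propensity,
            index=pd.Index(self.axis1_values, name=self.axis1_name),
            columns=pd.Index(self.axis2_values, name=self.axis2_name),
        )


def _true_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal [i, j] index intervals (inclusive) where mask is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts, ends))


def classify_end_tracking(
    traj: Trajectory,
    criteria: EndTrackCriteria = EndTrackCriteria(),
    end: Optional[str] = None,
) -> Tuple[bool, RunStats]:
    """Score one trajectory against the persistence criteria.

    Runs are maximal recorded intervals with |x - x_end| < max_gap over
    which the enzyme makes net progress in the treadmilling direction;
    the trajectory is persistent if any run lasts >= min_duration.  The
    returned RunStats covers the persistent runs only.
    """
    end = end or traj.scenario.track_end
    # resample at the analysis cadence (no-op if already coarser)
    stride = 1
    if traj.t.size > 1:
        sample_dt = traj.t[1] - traj.t[0]
        stride = max(1, int(round(criteria.cadence_s / sample_dt)))
    t = traj.t[::stride]
    x = traj.x[::stride]
    x_s = traj.x_S[::stride]
    x_g = traj.x_G[::stride]
    ref = x_s if end == "shrinking" else x_g
    # two-sided distance criterion: falling behind the end loses the
    # ratchet; roaming ahead along the filament interior (fast-diffusing
    # enzymes hop between interior wells) equally breaks end-tracking
    near = np.abs(x - ref) < criteria.max_gap
    speeds, durations, distances = [], [], []
    persistent = False
    intervals = _true_runs(near)
    if criteria.scope == "first":
        # only the interval that begins at the start of the trajectory
        intervals = [iv for iv in intervals[:1] if iv[0] == 0]

    def _score(s: int, jm: int) -> None:
        nonlocal persistent
        if jm <= s:
            return
        dur = t[jm] - t[s]
        net = x[jm] - x[s]
        end_advance = ref[jm] - ref[s]
        if net <= 0 or net < criteria.min_follow_fraction * end_advance:
            return
        if dur >= criteria.min_duration:
            persistent = True
            durations.append(dur)
            distances.append(net)
            speeds.append(net / dur)

    for i, j in intervals:
        if j <= i:
            continue
        # split the contact interval into unidirectional stretches: a run
        # closes (at its forward maximum) once the enzyme has dropped
        # max_backtrack below that maximum
        s = i
        m = x[i]
        jm = i
        for k in range(i + 1, j + 1):
            xk = x[k]
            if xk > m:
                m = xk
                jm = k
            elif m - xk > criteria.max_backtrack:
                _score(s, jm)
                if criteria.scope == "first":
                    s = -1
                    break
                s, m, jm = k, xk, k
        if s >= 0:
            _score(s, jm)
        if criteria.scope == "first":
            break
    return persistent, RunStats(
        np.asarray(speeds), np.asarray(durations), np.asarray(distances)
    )


def propensity(
    trajs: Sequence[Trajectory],
    criteria: EndTrackCriteria = EndTrackCriteria(),
    end: Optional[str] = None,
) -> float:
    """Fraction of trajectories scored persistent."""
    if len(trajs) == 0:
        raise ValueError("propensity of an empty ensemble is undefined")
    flags = [classify_end_tracking(t, criteria, end)[0] for t in trajs]
    return float(np.mean(flags))


def relative_propensity(counts: Sequence[int]) -> np.ndarray:
    """Per-condition persistent counts normalised to sum to 1."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total == 0:
        return np.zeros_like(c)
    return c / total


def _ensemble_at(
    params: RatchetParams,
    scenario: ScenarioSpec,
    n_traj: int,
    auto_dt: bool,
    escape_margin: float = ESCAPE_MARGIN,
) -> List[Trajectory]:
    if auto_dt:
        params = params.replace(
            dt=choose_dt(params.D, params.U0, params.V_Z, params.a, params.L0)
        )
    return simulate_ensemble(
        params, scenario, n_traj=n_traj, escape_margin=escape_margin
    )


def phase_diagram(
    axis1: Tuple[str, Sequence[float]],
    axis2: Tuple[str, Sequence[float]],
    fixed: RatchetParams,
    n_traj: int = 50,
    criteria: EndTrackCriteria = EndTrackCriteria(),
    auto_dt: bool = True,
    progress: Optional[Callable[[str], None]] = None,
) -> PhaseDiagram:
    """Propensity over a 2D parameter grid (axis names: D, U0, V_Z).

    Each cell runs ``n_traj`` shrinking-end-start trajectories with a cell
    seed derived from ``fixed.seed``, and with the time step re-chosen per
    cell when ``auto_dt`` (stiffer wells and faster diffusion need finer
    steps).
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if vals1.size == 0 or vals2.size == 0:
        raise ValueError("phase diagram axes must be non-empty")
    mat = np.empty((vals1.size, vals2.size))
    scenario = ScenarioSpec(init_mode="at_shrinking_end")
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            cell_seed = int(
                np.random.SeedSequence((fixed.seed, i, j)).generate_state(1)[0] >> 1
            )
            p = fixed.replace(**{name1: float(v1), name2: float(v2), "seed": cell_seed})
            trajs = _ensemble_at(p, scenario, n_traj, auto_dt)
            mat[i, j] = propensity(trajs, criteria)
            if progress is not None:
                progress(f"{name1}={v1:g} {name2}={v2:g} -> {mat[i, j]:.2f}")
    return PhaseDiagram(name1, vals1, name2, vals2, mat)


def _bootstrap_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator, level: float = 0.95
) -> Tuple[float, float]:
    if values.size == 0:
        return (np.nan, np.nan)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def run_length_duration_curves(
    vz_values: Sequence[float],
    params: RatchetParams,
    n_traj: int = 100,
    criteria: EndTrackCriteria = EndTrackCriteria(),
    n_boot: int = 1000,
    auto_dt: bool = True,
    progress: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Mean persistent-run duration and distance versus treadmilling speed.

    Returns a tidy table with per-speed persistent counts, means and
    bootstrap CIs; speeds with no persistent runs carry NaN means rather
    than zeros.  The duration falls monotonically with V_Z while the
    distance is biphasic with a peak near V_Z* = L0/sqrt(tau_C*tau_D).
    """
    rows = []
    for k, vz in enumerate(vz_values):
        cell_seed = int(
            np.random.SeedSequence((params.seed, 17, k)).generate_state(1)[0] >> 1
        )
        p = params.replace(V_Z=float(vz), seed=cell_seed)
        trajs = _ensemble_at(p, ScenarioSpec(), n_traj, auto_dt)
        per_traj = [classify_end_tracking(t, criteria) for t in trajs]
        n_persistent = sum(flag for flag, _ in per_traj)
        runs = RunStats.concat([r for _, r in per_traj])
        rng = np.random.default_rng(cell_seed)
        dur_lo, dur_hi = _bootstrap_ci(runs.durations, n_boot, rng)
        dist_lo, dist_hi = _bootstrap_ci(runs.distances, n_boot, rng)
        rows.append(
            {
                "V_Z": vz,
                "n_traj": n_traj,
                "n_persistent": n_persistent,
                "n_runs": runs.n,
                "duration_mean": runs.durations.mean() if runs.n else np.nan,
                "duration_lo": dur_lo,
                "duration_hi": dur_hi,
                "distance_mean": runs.distances.mean() if runs.n else np.nan,
                "distance_lo": dist_lo,
                "distance_hi": dist_hi,
            }
        )
        if progress is not None:
            progress(f"V_Z={vz:g}: {n_persistent}/{n_traj} persistent")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bound lifetimes and activity


def bound_lifetime(
    traj: Trajectory, escape_margin: float = ESCAPE_MARGIN
) -> Tuple[float, bool]:
    """First time the enzyme is > escape_margin beyond either filament end.

    The kernel records the first passage exactly (at step resolution);
    censored runs return the horizon time with ``censored=True``.
    """
    if not np.isnan(traj.first_escape):
        return float(traj.first_escape), False
    return float(traj.params.t_max), True


def mean_bound_lifetime(
    trajs: Sequence[Trajectory], escape_margin: float = ESCAPE_MARGIN
) -> dict:
    """Naive and censoring-aware (Kaplan–Meier) mean lifetimes."""
    pairs = [bound_lifetime(t, escape_margin) for t in trajs]
    times = np.array([p[0] for p in pairs])
    observed = np.array([not p[1] for p in pairs])
    out = {
        "mean_naive": float(times.mean()),
        "censored_fraction": float(1.0 - observed.mean()),
        "n": len(pairs),
    }
    if observed.all():
        out["mean_km"] = out["mean_naive"]
    else:
        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        km = KaplanMeierFitter().fit(times, event_observed=observed)
        out["mean_km"] = float(restricted_mean_survival_time(km, t=times.max()))
    return out


def lifetime_vs_speed(
    vz_values: Sequence[float],
    D: float,
    U0: float,
    n_traj: int = 200,
    base: Optional[RatchetParams] = None,
    t_max: float = 600.0,
    auto_dt: bool = True,
    progress: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Mean bound lifetime at each treadmilling speed, mid-filament start."""
    base = base or RatchetParams(D=D, U0=U0, V_Z=10.0)
    rows = []
    for k, vz in enumerate(vz_values):
        seed = int(np.random.SeedSequence((base.seed, 23, k)).generate_state(1)[0] >> 1)
        p = base.replace(D=D, U0=U0, V_Z=float(vz), t_max=t_max, seed=seed)
        if auto_dt:
            p = p.replace(dt=choose_dt(p.D, p.U0, p.V_Z, p.a, p.L0))
        trajs = simulate_ensemble(
            p, ScenarioSpec(init_mode="mid_filament"), n_traj=n_traj,
            record_every=10**6,
        )
        stats = mean_bound_lifetime(trajs)
        rows.append({"V_Z": vz, **stats})
        if progress is not None:
            progress(f"V_Z={vz:g}: lifetime {stats['mean_naive']:.1f} s")
    return pd.DataFrame(rows)


def activity_curve(
    vz_values: Sequence[float],
    D: float,
    U0: float,
    n_traj: int = 200,
    base: Optional[RatchetParams] = None,
    t_max: float = 600.0,
    censor_flag_level: float = 0.5,
    progress: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Normalised off-rate (1/lifetime) versus treadmilling speed.

    The off-rate of the filament-bound enzyme is the rate at which it
    becomes available for septal wall synthesis, hence a proxy for the
    synthesis rate.  Values are normalised to the slowest simulated speed.
    Cells whose censored fraction exceeds ``censor_flag_level`` are
    flagged.
    """
    df = lifetime_vs_speed(
        vz_values, D, U0, n_traj=n_traj, base=base, t_max=t_max, progress=progress
    )
    df["off_rate"] = 1.0 / df["mean_naive"]
    ref = df.loc[df["V_Z"].idxmin(), "off_rate"]
    df["off_rate_rel"] = df["off_rate"] / ref
    df["flagged"] = df["censored_fraction"] > censor_flag_level
    return df


class PotentialFitError(RuntimeError):
    """No binding-potential depth in the search range fits the data."""

    def __init__(self, message: str, residuals: Optional[pd.DataFrame] = None):
        super().__init__(message)
        self.residuals = residuals


def fit_binding_potential(
    activity_data,
    D: float,
    U_grid: Optional[np.ndarray] = None,
    rel_tol: float = 0.15,
    model: Optional[Callable[[float, float, float], float]] = None,
) -> Tuple[float, float]:
    """Bracket the well depth compatible with a relative-activity curve.

    ``activity_data`` is a table (or 2-column array) of (V_Z, relative
    activity), activity normalised at the slowest speed.  For each depth
    on ``U_grid`` the predicted normalised off-rate is computed from the
    closed-form bound-lifetime model (``model(V_Z, D, U0)`` may override
    it, e.g. with a simulation-backed curve) and depths whose root mean
    square relative residual is within ``rel_tol`` (or within twice the
    best fit, if larger) are accepted.  Returns (U_low, U_high).
    """
    if isinstance(activity_data, pd.DataFrame):
        vz = activity_data.iloc[:, 0].to_numpy(dtype=float)
        act = activity_data.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(activity_data, dtype=float)
        vz, act = arr[:, 0], arr[:, 1]
    if vz.size < 3:
        raise ValueError("need at least 3 (V_Z, activity) points")
    if not D > 0:
        raise ValueError("D must be positive")
    if U_grid is None:
        U_grid = np.arange(0.5, 20.01, 0.25)
    lifetime = model or (
        lambda v, d, u: analytic.model_bound_lifetime(v, d, u)
    )
    v_ref = vz.min()
    rms = np.empty(U_grid.size)
    for i, u0 in enumerate(U_grid):
        life = np.array([lifetime(v, D, float(u0)) for v in vz])
        ref = lifetime(v_ref, D, float(u0))
        pred = ref / life  # normalised off-rate
        rms[i] = float(np.sqrt(np.mean((pred - act) ** 2)))
    best = int(np.argmin(rms))
    accept_level = max(rel_tol, 2.0 * rms[best])
    ok = rms <= accept_level
    if rms[best] > 0.5:
        raise PotentialFitError(
            f"no depth in [{U_grid[0]}, {U_grid[-1]}] k_BT fits "
            f"(best rms residual {rms[best]:.2f})",
            residuals=pd.DataFrame({"U0": U_grid, "rms": rms}),
        )
    # contiguous accepted interval containing the best fit
    lo = best
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = best
    while hi < U_grid.size - 1 and ok[hi + 1]:
        hi += 1
    return float(U_grid[lo]), float(U_grid[hi])
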
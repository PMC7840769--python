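"""Closed-form theory of the end-tracking ratchet.

A persistent run decomposes into repeating steps: the enzyme *stays on*
the end subunit's well until that subunit dissociates (competition between
well escape, time scale tau_D, and subunit loss, time scale
tau_Z = L0/V_Z), then must *catch up* with the next well over the vacated
~5 nm (time scale tau_C).  The per-step survival probability is

    P = P1 * P2 ~ exp(-(tau_Z/tau_D + tau_C/tau_Z)),

the mean number of completed steps in the continuum limit is
<N> = tau_D*tau_Z/(tau_Z^2 + tau_C*tau_D) = -1/ln(P), and the mean run
length and duration follow as <L> = L0*<N> and <T> = <N>*tau_Z.  The run
length is maximal at tau_Z* = sqrt(tau_C*tau_D), i.e. at the treadmilling
speed V_Z* = L0/sqrt(tau_C*tau_D): a slower filament loses the enzyme to
well escape per step, a faster one loses it to failed catch-ups.

tau_D and tau_C can be computed by quadrature (``tau_D_theory``,
``tau_C_theory``) or measured from targeted micro-simulations
(``estimate_tau_D_tau_C``); both routes are exposed so the simulator and
the theory can be compared without circularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .params import RatchetParams
from .simulate import ESCAPE_MARGIN, _derive_seeds, simulate_trajectory

#: default distance (nm) behind the vacated well center at which a
#: catch-up attempt is scored as failed (a few subunit lengths; beyond
#: this lag the receding end is effectively out of reach)
CATCHUP_FAIL_DISTANCE = 20.0


@dataclass(frozen=True)
class AnalyticParams:
    """Time scales feeding the closed-form run statistics."""

    tau_D: float   # mean in-well dwell absent treadmilling, s
    tau_C: float   # mean catch-up time, s
    tau_Z: float   # end-subunit lifetime L0/V_Z, s
    L0: float = 5.0

    def __post_init__(self) -> None:
        for name in ("tau_D", "tau_C", "tau_Z", "L0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_speed(
        cls, tau_D: float, tau_C: float, V_Z: float, L0: float = 5.0
    ) -> "AnalyticParams":
        return cls(tau_D=tau_D, tau_C=tau_C, tau_Z=L0 / V_Z, L0=L0)

    @property
    def V_Z(self) -> float:
        return self.L0 / self.tau_Z

    @property
    def persistent_regime(self) -> bool:
        """True when tau_D >> tau_Z >> tau_C (each by a factor >= 10)."""
        return self.tau_D >= 10 * self.tau_Z >= 100 * self.tau_C


def step_probability(p: AnalyticParams) -> float:
    """Per-step survival probability P = exp(-(tau_Z/tau_D + tau_C/tau_Z))."""
    return float(np.exp(-(p.tau_Z / p.tau_D + p.tau_C / p.tau_Z)))


def mean_steps(p: AnalyticParams) -> float:
    """Continuum-limit mean number of ratchet steps per persistent run."""
    return p.tau_D * p.tau_Z / (p.tau_Z**2 + p.tau_C * p.tau_D)


def mean_steps_discrete(p: AnalyticParams) -> float:
    """Mean of the discrete geometric step count, sum N P^N (1-P) = P/(1-P)."""
    P = step_probability(p)
    return P / (1.0 - P)


def mean_run_length(p: AnalyticParams) -> float:
    """<L> = L0 * <N>, nm."""
    return p.L0 * mean_steps(p)


def mean_run_duration(p: AnalyticParams) -> float:
    """<T> = <N> * tau_Z, s."""
    return mean_steps(p) * p.tau_Z


def optimal_tau_Z(tau_D: float, tau_C: float) -> float:
    """tau_Z maximising P (and <L>): sqrt(tau_C * tau_D)."""
    return float(np.sqrt(tau_C * tau_D))


def optimal_speed(tau_D: float, tau_C: float, L0: float = 5.0) -> float:
    """Treadmilling speed maximising the run length, V_Z* = L0/sqrt(tau_C*tau_D)."""
    return L0 / optimal_tau_Z(tau_D, tau_C)


# ---------------------------------------------------------------------------
# quadrature expressions for the two time scales


def _well_energy(y: np.ndarray, U0: float, a: float) -> np.ndarray:
    u = np.zeros_like(y)
    inside = np.abs(y) <= a
    u[inside] = -U0 * (1.0 - (y[inside] / a) ** 2)
    return u


def tau_D_theory(
    D: float,
    U0: float,
    a: float = 2.5,
    escape_distance: float = ESCAPE_MARGIN,
    n_grid: int = 40001,
) -> float:
    """Mean first-passage time from the well bottom to +-escape_distance.

    Single static well centered at 0; the escape distance defaults to the
    100 nm criterion that also terminates persistent runs.  Computed by
    the standard double-quadrature MFPT formula
    tau = (1/D) * int_0^b exp(U(y)) int_0^y exp(-U(z)) dz dy.
    """
    y = np.linspace(0.0, escape_distance, n_grid)
    u = _well_energy(y, U0, a)
    inner = np.concatenate(([0.0], np.cumsum(
        0.5 * (np.exp(-u[1:]) + np.exp(-u[:-1])) * np.diff(y)
    )))
    integrand = np.exp(u) * inner
    return float(np.trapezoid(integrand, y) / D)


def tau_C_theory(
    D: float,
    L0: float = 5.0,
    a: float = 2.5,
    fail_distance: float = CATCHUP_FAIL_DISTANCE,
) -> float:
    """Mean successful catch-up time by free diffusion.

    The enzyme starts at the vacated well center; the next well's edge is
    ``L0 - a`` ahead, and an attempt is scored failed once the enzyme lags
    ``fail_distance`` behind.  For free diffusion on an interval the
    conditional mean exit time through the far boundary is
    (l^2 - x0^2)/(6D) with l the interval length and x0 the start offset.
    """
    l = fail_distance + (L0 - a)
    return float((l**2 - fail_distance**2) / (6.0 * D))


# ---------------------------------------------------------------------------
# simulation-based estimators


def estimate_tau_D(
    params: RatchetParams,
    n_traj: int = 50,
    escape_distance: float = ESCAPE_MARGIN,
    t_max: Optional[float] = None,
) -> float:
    """Mean escape time from a single static well, by direct simulation.

    Runs a one-subunit filament with treadmilling off; each trajectory
    ends at its first excursion beyond ``escape_distance``.  If more than
    half of the runs are censored the horizon is doubled and the batch
    rerun.
    """
    if t_max is None:
        t_max = max(10.0 * tau_D_theory(params.D, params.U0, params.a), 1.0)
    p = params.replace(V_Z=0.0, t_max=t_max)
    p.validate_stability()
    persist = 1  # stop at the first crossing: a first-passage measurement
    while True:
        seeds = _derive_seeds(p.seed, n_traj)
        times = []
        censored = 0
        n_steps = int(round(p.t_max / p.dt))
        for s in seeds:
            # one isolated static well (n_sub=1), enzyme starting at its
            # center; escape is the first excursion beyond the criterion
            # distance on either side
            rng = np.random.default_rng(int(s))
            kseed = int(rng.integers(2**31))
            *_, first_out, _end = _kernels.trajectory_kernel(
                kseed, 0.0, 0.0, 1, p.L0, p.a, p.U0, p.D, 0.0, p.dt,
                n_steps, 10**9, escape_distance, persist,
            )
            if first_out < 0:
                censored += 1
                times.append(p.t_max)
            else:
                times.append(first_out * p.dt)
        if censored <= n_traj // 2:
            return float(np.mean(times))
        p = p.replace(t_max=2 * p.t_max)


def estimate_tau_C(
    params: RatchetParams,
    n_samples: int = 2000,
    fail_distance: float = CATCHUP_FAIL_DISTANCE,
) -> float:
    """Mean successful catch-up time from targeted micro-simulations.

    Free diffusion from the departed end subunit's former center until the
    next well's edge is reached (success) or the enzyme lags
    ``fail_distance`` behind (failure); the mean is over successes only.
    """
    seeds = _derive_seeds(params.seed ^ 0x5EED, n_samples)
    max_steps = int(1e9)
    times = []
    for s in seeds:
        n, ok = _kernels.catchup_kernel(
            int(s), params.D, params.dt, params.a, params.L0, fail_distance, max_steps
        )
        if ok:
            times.append(n * params.dt)
    if not times:
        raise RuntimeError("no successful catch-up events observed")
    return float(np.mean(times))


def estimate_tau_D_tau_C(
    params: RatchetParams,
    n_traj: int = 50,
    n_catchup: int = 2000,
    escape_distance: float = ESCAPE_MARGIN,
    fail_distance: float = CATCHUP_FAIL_DISTANCE,
) -> AnalyticParams:
    """Measure (tau_D, tau_C) for a parameter point and bundle with tau_Z."""
    if params.V_Z <= 0:
        raise ValueError("V_Z must be positive to define tau_Z")
    tau_d = estimate_tau_D(params, n_traj=n_traj, escape_distance=escape_distance)
    tau_c = estimate_tau_C(params, n_samples=n_catchup, fail_distance=fail_distance)
    return AnalyticParams.from_speed(tau_d, tau_c, params.V_Z, params.L0)


# ---------------------------------------------------------------------------
# composite lifetime model used for binding-potential fitting


def model_bound_lifetime(
    V_Z: float,
    D: float,
    U0: float,
    a: float = 2.5,
    L0: float = 5.0,
    N_fil: int = 50,
    margin: float = ESCAPE_MARGIN,
    fail_distance: float = CATCHUP_FAIL_DISTANCE,
) -> float:
    """Closed-form mean bound lifetime from a random start on the filament.

    Decomposes the first passage beyond ``margin`` of either end into the
    mean wait until the shrinking end reaches a uniformly placed enzyme
    (filament half-length / V_Z), the mean end-tracking run duration <T>,
    and the final recession of the end by ``margin``.  Escape during the
    wait is negligible for the deep wells this model targets.
    """
    tau_d = tau_D_theory(D, U0, a, escape_distance=margin)
    tau_c = tau_C_theory(D, L0, a, fail_distance=fail_distance)
    p = AnalyticParams.from_speed(tau_d, tau_c, V_Z, L0)
    half = 0.5 * (N_fil - 1) * L0
    return half / V_Z + mean_run_duration(p) + margin / V_Z
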
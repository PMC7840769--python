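"""Physical and numerical parameters of the treadmilling Brownian ratchet.

All quantities are carried in (nm, s, k_BT) units.  The enzyme (FtsI is the
model transpeptidase) diffuses on a 1D septal axis with diffusion constant
``D`` (nm^2/s); each live filament subunit presents a truncated harmonic
binding well of depth ``U0`` (k_BT) and half-width ``a`` (nm); the filament
treadmills rightward at ``V_Z`` (nm/s) by losing its left-most (shrinking-end)
subunit and gaining one on the right (growing end) every ``L0/(V_Z*dt)``
simulation steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

KBT = 1.0  #: energies are dimensionless multiples of k_B*T
NM2_PER_UM2 = 1.0e6  #: conversion factor, um^2/s -> nm^2/s


class ConfigError(ValueError):
    """A parameter combination that cannot be simulated."""


class StabilityError(ConfigError):
    """Time step too large for stable integration of the binding force."""


@dataclass(frozen=True)
class RatchetParams:
    """Physical and numerical constants of the ratchet model.

    Parameters
    ----------
    D : float
        Free diffusion constant of the enzyme, nm^2/s.
    U0 : float
        Binding-well depth, k_BT (dimensionless energy units).
    V_Z : float
        Filament treadmilling speed, nm/s.  ``0`` freezes the filament.
    a : float
        Well half-width, nm.  Default 2.5 nm so that adjacent wells tile
        the filament interior.
    L0 : float
        Subunit length, nm (5 nm, the size of an FtsZ monomer).
    N_fil : int
        Filament length in subunits (50 subunits = 250 nm at steady state).
    dt : float
        Integration time step, s.
    t_max : float
        Maximum simulated time per trajectory, s.
    seed : int
        Master RNG seed for a trajectory or ensemble.
    """

    D: float
    U0: float
    V_Z: float
    a: float = 2.5
    L0: float = 5.0
    N_fil: int = 50
    dt: float = 5e-6
    t_max: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ConfigError(f"D must be positive, got {self.D}")
        if self.U0 < 0:
            raise ConfigError(f"U0 must be non-negative, got {self.U0}")
        if not self.a > 0:
            raise ConfigError(f"a must be positive, got {self.a}")
        if not self.L0 > 0:
            raise ConfigError(f"L0 must be positive, got {self.L0}")
        if self.a > self.L0 / 2 + 1e-12:
            raise ConfigError("well half-width a may not exceed L0/2")
        if self.N_fil < 2:
            raise ConfigError(f"N_fil must be >= 2, got {self.N_fil}")
        if self.V_Z < 0:
            raise ConfigError(f"V_Z must be non-negative, got {self.V_Z}")
        if not self.dt > 0:
            raise ConfigError(f"dt must be positive, got {self.dt}")
        if not self.t_max > 0:
            raise ConfigError(f"t_max must be positive, got {self.t_max}")

    # -- derived numerical quantities ------------------------------------

    @property
    def stability_q(self) -> float:
        """Dimensionless in-well rate number q = (2*D*U0/a^2)*dt.

        q is the per-step contraction of the linearised in-well dynamics.
        The production integrator (exact in-well OU transition) is stable
        for any q; the Euler reference step is stable only for q < 2 and
        accurate for q well below 1.
        """
        return 2.0 * self.D * self.U0 / (self.a * self.a) * self.dt

    @property
    def noise_step(self) -> float:
        """RMS free-diffusion displacement per step, sqrt(2*D*dt) in nm."""
        import math

        return math.sqrt(2.0 * self.D * self.dt)

    @property
    def steps_per_event(self) -> int:
        """Simulation steps between treadmilling events (0 when V_Z == 0)."""
        if self.V_Z == 0:
            return 0
        n = int(round(self.L0 / (self.V_Z * self.dt)))
        if n < 1:
            raise ConfigError(
                f"dt={self.dt} too large for V_Z={self.V_Z}: less than one "
                "step per treadmilling event"
            )
        return n

    def validate_stability(self) -> None:
        """Refuse configurations whose step cannot resolve well-edge crossings.

        The piecewise-exact propagator is unconditionally stable, but its
        accuracy rests on the per-step noise displacement staying below
        the well half-width; beyond 0.8*a a single step can jump across a
        well and escape statistics become meaningless.
        """
        if self.U0 == 0:
            return  # no wells: a free-diffusion step is exact at any dt
        if self.noise_step > 0.8 * self.a:
            raise StabilityError(
                f"noise step {self.noise_step:.3g} nm exceeds 0.8*a for "
                f"dt={self.dt}; use dt <= {(0.8 * self.a) ** 2 / (2 * self.D):.3g} s"
            )

    def replace(self, **kwargs) -> "RatchetParams":
        return replace(self, **kwargs)


def choose_dt(
    D: float,
    U0: float,
    V_Z: float,
    a: float = 2.5,
    L0: float = 5.0,
    step_fraction: float = 0.25,
    dt_max: float = 1e-4,
) -> float:
    """Largest adequate time step for a parameter point.

    Two constraints: the RMS free-diffusion displacement per step stays at
    ``step_fraction`` of the well half-width (so well-edge crossings are
    resolved), and at least 20 steps elapse per treadmilling event so the
    subunit clock is resolved.  At the reference point D = 0.04 um^2/s
    this yields ~5e-6 s, the standard fine step for this model.
    """
    dt = min(dt_max, (step_fraction * a) ** 2 / (2.0 * D))
    if V_Z > 0:
        dt = min(dt, L0 / V_Z / 20.0)
    return dt
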
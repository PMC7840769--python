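"""Core ratchet physics: binding landscape, forces, single-step updates.

This module is the readable reference implementation of the model's
elementary operations.  Production trajectory generation uses the compiled
kernels in :mod:`endtrack._kernels`, which implement exactly the same
update rules; unit tests pin the two against each other statistically.

The enzyme feels the potential of the *nearest live subunit* only.  Each
subunit carries a truncated inverted parabola

    U(x) = -U0 * (1 - ((x - x_c)/a)^2)   for |x - x_c| <= a,  else 0,

so with a = L0/2 the wells tile the filament interior without barriers,
and the loss of the end subunit leaves a flat ~5 nm stretch of membrane
before the next well — the time asymmetry that rectifies diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import RatchetParams


class EmptyFilamentError(ValueError):
    """Raised when a fully depolymerised filament is queried."""


@dataclass
class FilamentState:
    """Positions of a treadmilling filament's live subunits.

    ``subunit_centers`` are equally spaced by ``L0``; ``x_S`` / ``x_G`` are
    the centers of the shrinking-end (left) and growing-end (right)
    subunits.  ``steps_until_event`` counts down to the next treadmilling
    event (0 means treadmilling is off).
    """

    x_S: float
    x_G: float
    subunit_centers: np.ndarray
    steps_until_event: int

    @property
    def n_subunits(self) -> int:
        return int(self.subunit_centers.size)


@dataclass
class EnzymeState:
    """Enzyme position on the 1D septal axis and its in-range subunit."""

    x: float
    bound_subunit: Optional[int] = None


def new_filament(params: RatchetParams, x_S: float = 0.0) -> FilamentState:
    centers = x_S + np.arange(params.N_fil) * params.L0
    return FilamentState(
        x_S=float(centers[0]),
        x_G=float(centers[-1]),
        subunit_centers=centers,
        steps_until_event=params.steps_per_event,
    )


def _nearest_subunit(x: np.ndarray, filament: FilamentState) -> np.ndarray:
    """Index of the nearest live subunit (ties break toward smaller index)."""
    if filament.n_subunits < 1:
        raise EmptyFilamentError("filament is fully depolymerised")
    x = np.asarray(x, dtype=float)
    d = np.abs(x[..., None] - filament.subunit_centers)
    return np.argmin(d, axis=-1)


def binding_potential(x, filament: FilamentState, params: RatchetParams):
    """Binding energy U(x) in k_BT; always <= 0.

    Outside the range ``a`` of every live subunit the landscape is flat
    (U = 0), which is what the enzyme experiences over the ~5 nm gap left
    by a departed end subunit.
    """
    x = np.asarray(x, dtype=float)
    idx = _nearest_subunit(x, filament)
    dx = x - filament.subunit_centers[idx]
    u = np.where(
        np.abs(dx) <= params.a,
        -params.U0 * (1.0 - (dx / params.a) ** 2),
        0.0,
    )
    return u if u.ndim else float(u)


def binding_force(x, filament: FilamentState, params: RatchetParams):
    """f = -dU/dx in k_BT/nm; pulls toward the nearest well center."""
    x = np.asarray(x, dtype=float)
    idx = _nearest_subunit(x, filament)
    dx = x - filament.subunit_centers[idx]
    f = np.where(
        np.abs(dx) <= params.a,
        -2.0 * params.U0 * dx / params.a**2,
        0.0,
    )
    return f if f.ndim else float(f)


def step_enzyme(
    state: EnzymeState,
    filament: FilamentState,
    params: RatchetParams,
    rng: np.random.Generator,
) -> EnzymeState:
    """One Euler–Maruyama update of the overdamped Langevin equation.

    x <- x + D*f(x)*dt + sqrt(2*D*dt)*eta, with eta ~ N(0, 1).  With
    k_BT = 1 the mobility is D, so D*f has units nm/s.
    """
    f = binding_force(state.x, filament, params)
    noise = np.sqrt(2.0 * params.D * params.dt) * rng.standard_normal()
    x_new = state.x + params.D * f * params.dt + noise
    if not np.isfinite(x_new):
        raise FloatingPointError(
            f"enzyme position became non-finite (x={state.x}, f={f})"
        )
    idx = int(_nearest_subunit(np.float64(x_new), filament))
    bound = idx if abs(x_new - filament.subunit_centers[idx]) <= params.a else None
    return EnzymeState(x=float(x_new), bound_subunit=bound)


def step_filament(filament: FilamentState, params: RatchetParams) -> FilamentState:
    """Advance the treadmilling clock by one simulation step.

    On an event the shrinking-end subunit is removed (its well vanishes
    with it) and a new subunit appears one lattice spacing beyond the
    growing end, so the subunit count is conserved and both ends advance
    by exactly ``L0``.
    """
    if params.V_Z == 0:
        return filament
    countdown = filament.steps_until_event - 1
    if countdown > 0:
        return FilamentState(
            x_S=filament.x_S,
            x_G=filament.x_G,
            subunit_centers=filament.subunit_centers,
            steps_until_event=countdown,
        )
    centers = np.append(filament.subunit_centers[1:], filament.x_G + params.L0)
    return FilamentState(
        x_S=float(centers[0]),
        x_G=float(centers[-1]),
        subunit_centers=centers,
        steps_until_event=params.steps_per_event,
    )
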
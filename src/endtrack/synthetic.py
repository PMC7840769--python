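"""Synthetic single-molecule data generators.

These emulate the inputs the SMT pipeline consumes: localizations of a
molecule moving on a ~1 um division ring imaged at 1 s/frame with
Gaussian localization noise and occasional dark frames; two-population
log-normal speed samples; and 2D diffusive tracks whose MSDs carry a
localization-noise offset.  Every generator is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .smt import LOCALIZATION_COLUMNS


@dataclass(frozen=True)
class RingTrackSpec:
    """One molecule on a septal ring.

    ``mode`` is "directional" (constant arc speed ``speed_nm_s``) or
    "diffusive" (arc diffusion with constant ``D_um2_s``).  The ring
    diameter default matches the 1.2–1.4 um nanopillar range used to trap
    cells vertically; frames default to 1 s (500 ms exposure + 500 ms
    dark).
    """

    diameter_nm: float = 1300.0
    mode: str = "directional"
    speed_nm_s: float = 25.0
    D_um2_s: float = 0.01
    frame_interval_s: float = 1.0
    n_frames: int = 60
    noise_sd_nm: float = 20.0
    drop_prob: float = 0.0
    center: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.diameter_nm > 0:
            raise ValueError("diameter must be positive")
        if self.noise_sd_nm < 0:
            raise ValueError("noise SD must be >= 0")
        if self.mode not in ("directional", "diffusive"):
            raise ValueError("mode must be 'directional' or 'diffusive'")


def generate_ring_localizations(
    spec: RingTrackSpec, seed: int = 0, theta0: Optional[float] = None
) -> pd.DataFrame:
    """Localization table for one molecule moving on the ring.

    The molecule's arc position advances ballistically or diffusively; 2D
    positions on the circle get isotropic Gaussian localization noise, and
    frames are dropped independently with ``drop_prob`` (never the first
    frame, so every table starts with a localization).
    """
    rng = np.random.default_rng(seed)
    r = spec.diameter_nm / 2.0
    dt = spec.frame_interval_s
    if theta0 is None:
        theta0 = rng.uniform(0, 2 * np.pi)
    if spec.mode == "directional":
        arc = spec.speed_nm_s * dt * np.arange(spec.n_frames)
    else:
        d_nm2 = spec.D_um2_s * 1e6
        steps = rng.normal(0.0, np.sqrt(2 * d_nm2 * dt), size=spec.n_frames - 1)
        arc = np.concatenate(([0.0], np.cumsum(steps)))
    theta = theta0 + arc / r
    x = spec.center[0] + r * np.cos(theta) + rng.normal(0, spec.noise_sd_nm, spec.n_frames)
    y = spec.center[1] + r * np.sin(theta) + rng.normal(0, spec.noise_sd_nm, spec.n_frames)
    keep = rng.random(spec.n_frames) >= spec.drop_prob
    keep[0] = True
    frames = np.arange(spec.n_frames)[keep]
    table = pd.DataFrame(
        {
            "frame": frames,
            "x": x[keep],
            "y": y[keep],
            "intensity": rng.normal(1000.0, 100.0, frames.size).clip(min=301.0),
            "sigma": rng.normal(150.0, 15.0, frames.size).clip(61.0, 299.0),
            "uncertainty": np.full(frames.size, spec.noise_sd_nm),
        }
    )
    return table[LOCALIZATION_COLUMNS]


def generate_ring_points(
    circle_center: Tuple[float, float],
    radius_nm: float,
    n_points: int,
    noise_sd_nm: float,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Ring-marker point set (positions, intensity weights) for circle fits."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n_points)
    pts = np.column_stack(
        [
            circle_center[0] + radius_nm * np.cos(theta),
            circle_center[1] + radius_nm * np.sin(theta),
        ]
    ) + rng.normal(0, noise_sd_nm, (n_points, 2))
    weights = rng.uniform(0.5, 1.5, n_points)
    return pts, weights


def generate_speed_samples(
    P_fast: float,
    mu_slow: float,
    sigma_slow: float,
    mu_fast: float,
    sigma_fast: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """i.i.d. draws from a two-component log-normal speed mixture (nm/s)."""
    if not 0 <= P_fast <= 1:
        raise ValueError("P_fast must lie in [0, 1]")
    if sigma_slow < 0 or sigma_fast < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    fast = rng.random(n) < P_fast
    logs = np.where(
        fast,
        rng.normal(mu_fast, sigma_fast, n),
        rng.normal(mu_slow, sigma_slow, n),
    )
    return np.exp(logs)


def generate_diffusive_tracks(
    D_um2_s: float,
    n_tracks: int,
    n_frames: int,
    noise_sd_nm: float,
    frame_interval_s: float = 0.03,
    seed: int = 0,
) -> List[np.ndarray]:
    """2D Brownian tracks (nm) with localization noise.

    Per-axis increments have variance 2*D*dt; isotropic Gaussian noise of
    SD ``noise_sd_nm`` is added to each localization, producing the
    4*noise^2 MSD offset that the anomalous-diffusion fit absorbs in D0.
    The 30 ms default frame interval matches streamed fast-tracking
    acquisitions.
    """
    if D_um2_s < 0:
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    d_nm2 = D_um2_s * 1e6
    out = []
    for _ in range(n_tracks):
        steps = rng.normal(
            0.0, np.sqrt(2 * d_nm2 * frame_interval_s), size=(n_frames - 1, 2)
        )
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        xy = xy + rng.normal(0, noise_sd_nm, xy.shape)
        out.append(xy)
    return out
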
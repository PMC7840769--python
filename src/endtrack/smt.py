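"""Single-molecule tracking analysis for septal-ring trajectories.

The pipeline mirrors how vertically trapped cells are analysed: a
localization table (frame, x, y, intensity, sigma, uncertainty) is
quality-filtered, linked into tracks by nearest-neighbour assignment with
gap closing, projected onto a circle fitted to the division-ring marker,
unwrapped to 1D arc-length displacement, segmented, and each segment
classified as processive or stationary by the dimensionless residual
ratio R = r/d.  Speed distributions are deconvolved with a two-component
log-normal mixture, and free-diffusion data are summarised by
time-averaged MSD curves fitted with MSD = 4*D*t^alpha + D0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

LOCALIZATION_COLUMNS = ["frame", "x", "y", "intensity", "sigma", "uncertainty"]


# ---------------------------------------------------------------------------
# localization filtering and linking


def filter_localizations(
    table: pd.DataFrame,
    min_intensity: float = 300.0,
    sigma_band: Tuple[float, float] = (60.0, 300.0),
) -> pd.DataFrame:
    """Drop localizations failing the intensity or PSF-width gates."""
    for col in ("intensity", "sigma"):
        if col not in table.columns:
            raise KeyError(f"localization table lacks column '{col}'")
    lo, hi = sigma_band
    keep = (
        (table["intensity"] >= min_intensity)
        & (table["sigma"] >= lo)
        & (table["sigma"] <= hi)
    )
    return table.loc[keep].reset_index(drop=True)


def link_localizations(
    table: pd.DataFrame,
    max_disp: float = 300.0,
    max_gap: int = 15,
) -> pd.DataFrame:
    """Greedy nearest-neighbour linking with gap closing.

    Localizations in successive frames closer than ``max_disp`` (nm) are
    joined, allowing up to ``max_gap`` consecutive dark frames; pairs are
    assigned in order of increasing distance so no two tracks share a
    localization.  Returns the table sorted by (track_id, frame) with a
    ``track_id`` column added.
    """
    for col in ("frame", "x", "y"):
        if col not in table.columns:
            raise KeyError(f"localization table lacks column '{col}'")
    df = table.sort_values("frame", kind="stable").reset_index(drop=True)
    track_id = np.full(len(df), -1, dtype=int)
    # active track registry: id -> (last_frame, x, y)
    active: dict = {}
    next_id = 0
    for frame, idx in df.groupby("frame").groups.items():
        idx = np.asarray(idx)
        xs = df.loc[idx, "x"].to_numpy(float)
        ys = df.loc[idx, "y"].to_numpy(float)
        # purge tracks that have been dark too long
        active = {
            tid: rec for tid, rec in active.items() if frame - rec[0] <= max_gap + 1
        }
        cand = []
        for tid, (f0, x0, y0) in active.items():
            d = np.hypot(xs - x0, ys - y0)
            for k in range(idx.size):
                if d[k] <= max_disp:
                    cand.append((d[k], tid, k))
        cand.sort(key=lambda c: c[0])
        used_tracks, used_locs = set(), set()
        for d, tid, k in cand:
            if tid in used_tracks or k in used_locs:
                continue
            track_id[idx[k]] = tid
            active[tid] = (frame, xs[k], ys[k])
            used_tracks.add(tid)
            used_locs.add(k)
        for k in range(idx.size):
            if k not in used_locs:
                track_id[idx[k]] = next_id
                active[next_id] = (frame, xs[k], ys[k])
                next_id += 1
    df["track_id"] = track_id
    return df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ring geometry


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")


def fit_septal_circle(
    points: np.ndarray, weights: Optional[np.ndarray] = None
) -> Circle:
    """Weighted algebraic least-squares circle fit.

    Solves the linearised circle equation 2*cx*x + 2*cy*y + c = x^2 + y^2
    in the (optionally intensity-weighted) least-squares sense; three
    non-collinear points give the circumscribed circle exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n, 3<=n) x 2 array of points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        A = A * w[:, None]
        b = b * w
    sol, residuals, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear or degenerate; no unique circle")
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    return Circle(float(cx), float(cy), float(math.sqrt(r2)))


def unwrap_trajectory(
    track: pd.DataFrame,
    circle: Circle,
    t_column: str = "frame",
    frame_interval: float = 1.0,
) -> pd.DataFrame:
    """Project a 2D septal track onto the fitted ring and unwrap to 1D.

    Each point is projected radially onto the circle; its angle is
    converted to arc length (angle * radius) and the angle series is
    phase-unwrapped so consecutive displacements lie within half the
    circumference.  Returns columns t (s), arc (nm), theta (rad) and
    radial_residual (nm).
    """
    dx = track["x"].to_numpy(float) - circle.cx
    dy = track["y"].to_numpy(float) - circle.cy
    rho = np.hypot(dx, dy)
    if np.any(rho < 1e-9):
        raise ValueError("track point at the circle center: angle undefined")
    theta = np.unwrap(np.arctan2(dy, dx))
    return pd.DataFrame(
        {
            "t": track[t_column].to_numpy(float) * frame_interval,
            "arc": theta * circle.radius,
            "theta": theta,
            "radial_residual": rho - circle.radius,
        }
    )


# ---------------------------------------------------------------------------
# segment statistics and classification

#: sentinel R value for segments with (near-)zero net displacement
R_STATIONARY = np.inf


@dataclass
class Segment:
    """Linear-fit summary of one track segment.

    v: fitted slope (nm/s); d: total fitted displacement (nm);
    l_seconds / l_points: segment length in both units (1 s/frame makes
    them numerically equal in the native data); r: SD of residuals (nm);
    R = r/d, the noise-to-signal ratio used for classification.
    """

    v: float
    d: float
    l_seconds: float
    l_points: int
    r: float
    R: float
    label: str = "unclassified"
    t_start: float = 0.0


def segment_statistics(
    times: np.ndarray, positions: np.ndarray, min_points: int = 4
) -> Segment:
    """OLS line fit of a segment with the {v, d, l, r, R} observables."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(positions, dtype=float)
    if t.size < min_points:
        raise ValueError(f"segment needs >= {min_points} points, got {t.size}")
    res = stats.linregress(t, y)
    fitted = res.intercept + res.slope * t
    r = float(np.std(y - fitted))
    d = float(abs(fitted[-1] - fitted[0]))
    R = r / d if d > 1.0 else R_STATIONARY
    return Segment(
        v=float(res.slope),
        d=d,
        l_seconds=float(t[-1] - t[0]),
        l_points=int(t.size),
        r=r,
        R=R,
        t_start=float(t[0]),
    )


def _best_breakpoint(t: np.ndarray, y: np.ndarray, min_points: int) -> Tuple[int, float]:
    """Best single split by total squared residual of two line fits."""
    best_k, best_sse = -1, np.inf
    for k in range(min_points, t.size - min_points + 1):
        sse = 0.0
        for sl in (slice(0, k), slice(k, t.size)):
            rr = stats.linregress(t[sl], y[sl])
            sse += float(np.sum((y[sl] - rr.intercept - rr.slope * t[sl]) ** 2))
        if sse < best_sse:
            best_k, best_sse = k, sse
    return best_k, best_sse


def split_changepoints(
    times: np.ndarray,
    positions: np.ndarray,
    penalty: Optional[float] = None,
    min_points: int = 4,
) -> List[int]:
    """Automatic piecewise-linear breakpoints (recursive binary splitting).

    An extension over the manual segmentation used on experimental data:
    a split is accepted when it lowers the squared residual by more than
    ``penalty`` (default: 4 * noise variance estimated from second
    differences * log n).  Returns interior breakpoint indices, sorted.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(positions, dtype=float)
    if penalty is None:
        dd = np.diff(y, 2)
        noise_var = np.median(dd**2) / 6.0 if dd.size else 1.0
        penalty = 4.0 * max(noise_var, 1e-12) * np.log(max(t.size, 2))
    out: List[int] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_points:
            return
        rr = stats.linregress(t[lo:hi], y[lo:hi])
        sse0 = float(np.sum((y[lo:hi] - rr.intercept - rr.slope * t[lo:hi]) ** 2))
        k, sse1 = _best_breakpoint(t[lo:hi], y[lo:hi], min_points)
        if k > 0 and sse0 - sse1 > penalty:
            out.append(lo + k)
            recurse(lo, lo + k)
            recurse(lo + k, hi)

    recurse(0, t.size)
    return sorted(out)


def classify_segments(
    times: np.ndarray,
    positions: np.ndarray,
    breakpoints: Optional[Sequence[int]] = None,
    R_threshold: float = 0.4,
    min_points: int = 4,
    min_duration: float = 4.0,
    auto: bool = False,
) -> List[Segment]:
    """Split a 1D track into segments and label each one.

    A segment is *processive* when R <= R_threshold, it has at least
    ``min_points`` localizations and spans at least ``min_duration``
    seconds; otherwise *stationary*.  Segments shorter than ``min_points``
    are dropped.  Breakpoints may be supplied (the analogue of manual
    segmentation) or found automatically (``auto=True``).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(positions, dtype=float)
    if breakpoints is None:
        breakpoints = split_changepoints(t, y, min_points=min_points) if auto else []
    edges = [0, *sorted(breakpoints), t.size]
    segments: List[Segment] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo < min_points:
            continue
        seg = segment_statistics(t[lo:hi], y[lo:hi], min_points=min_points)
        processive = (
            seg.R <= R_threshold
            and seg.l_points >= min_points
            and seg.l_seconds >= min_duration
        )
        seg.label = "processive" if processive else "stationary"
        segments.append(seg)
    return segments


# ---------------------------------------------------------------------------
# speed-distribution deconvolution


@dataclass
class MixtureFit:
    """Two-component log-normal mixture of a speed distribution.

    Component 1 is the slower one (mu1 < mu2); ``P`` is the fast-population
    fraction so the density is
    (1-P)*LogN(mu1, sigma1) + P*LogN(mu2, sigma2).
    """

    P: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    bootstrap_sd: dict = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        slow = stats.lognorm.cdf(x, self.sigma1, scale=np.exp(self.mu1))
        fast = stats.lognorm.cdf(x, self.sigma2, scale=np.exp(self.mu2))
        return (1 - self.P) * slow + self.P * fast

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        slow = stats.lognorm.pdf(x, self.sigma1, scale=np.exp(self.mu1))
        fast = stats.lognorm.pdf(x, self.sigma2, scale=np.exp(self.mu2))
        return (1 - self.P) * slow + self.P * fast

    def slow_share(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability that a speed x came from the slow component."""
        x = np.asarray(x, dtype=float)
        slow = (1 - self.P) * stats.lognorm.pdf(x, self.sigma1, scale=np.exp(self.mu1))
        tot = self.pdf(x)
        return np.divide(slow, tot, out=np.zeros_like(slow), where=tot > 0)


def _fit_mixture_once(x: np.ndarray, theta0: np.ndarray) -> Tuple[np.ndarray, float]:
    xs = np.sort(x)
    ecdf = (np.arange(1, xs.size + 1) - 0.5) / xs.size

    def resid(theta):
        P, mu1, s1, mu2, s2 = theta
        model = (1 - P) * stats.lognorm.cdf(xs, s1, scale=np.exp(mu1)) + P * stats.lognorm.cdf(
            xs, s2, scale=np.exp(mu2)
        )
        return model - ecdf

    lo = [0.0, np.log(xs[0]) - 2, 1e-3, np.log(xs[0]) - 2, 1e-3]
    hi = [1.0, np.log(xs[-1]) + 2, 5.0, np.log(xs[-1]) + 2, 5.0]
    res = optimize.least_squares(resid, theta0, bounds=(lo, hi))
    return res.x, float(np.sum(res.fun**2))


def fit_lognormal_mixture(
    speeds: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> MixtureFit:
    """Least-squares fit of the two-population log-normal CDF.

    The model CDF is fitted to the empirical CDF with multi-start local
    optimisation; parameters are bootstrap-resampled ``n_boot`` times to
    estimate their spread.  Components are ordered so mu1 < mu2, and
    identifiability edge cases (vanishing component weight, coincident
    components) are flagged rather than raised.
    """
    x = np.asarray(speeds, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 30:
        raise ValueError("need at least 30 positive speed samples")
    logx = np.log(x)
    starts = []
    for q in (0.5, 0.3, 0.7):
        cut = np.quantile(logx, q)
        lo_part, hi_part = logx[logx <= cut], logx[logx > cut]
        if lo_part.size < 2 or hi_part.size < 2:
            continue
        starts.append(
            np.array(
                [
                    hi_part.size / logx.size,
                    lo_part.mean(),
                    max(lo_part.std(), 0.05),
                    hi_part.mean(),
                    max(hi_part.std(), 0.05),
                ]
            )
        )
    starts.append(np.array([0.5, logx.mean() - 0.5, 0.3, logx.mean() + 0.5, 0.3]))
    best, best_sse = None, np.inf
    for theta0 in starts:
        try:
            theta, sse = _fit_mixture_once(x, theta0)
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if sse < best_sse:
            best, best_sse = theta, sse
    if best is None:
        raise RuntimeError("log-normal mixture fit failed from every start")
    P, mu1, s1, mu2, s2 = best
    if mu1 > mu2:  # enforce slow-first ordering
        mu1, s1, mu2, s2 = mu2, s2, mu1, s1
        P = 1 - P
    flags = []
    if P < 0.05 or P > 0.95:
        flags.append("degenerate_component")
    if abs(mu1 - mu2) < 0.05 and abs(s1 - s2) < 0.05:
        flags.append("components_coincide")
    rng = np.random.default_rng(seed)
    boots = []
    theta_hat = np.array([P, mu1, s1, mu2, s2])
    for _ in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        try:
            tb, _ = _fit_mixture_once(xb, theta_hat)
        except Exception:  # noqa: BLE001
            continue
        if tb[1] > tb[3]:
            tb = np.array([1 - tb[0], tb[3], tb[4], tb[1], tb[2]])
        boots.append(tb)
    sd = {}
    if boots:
        bs = np.array(boots)
        for i, name in enumerate(["P", "mu1", "sigma1", "mu2", "sigma2"]):
            sd[name] = float(bs[:, i].std())
    return MixtureFit(
        P=float(P), mu1=float(mu1), sigma1=float(s1), mu2=float(mu2),
        sigma2=float(s2), bootstrap_sd=sd, flags=flags,
    )


def resample_fast_population(
    speeds: np.ndarray,
    fit: MixtureFit,
    n_rounds: int = 100,
    seed: int = 0,
    bins: str = "fd",
) -> List[np.ndarray]:
    """Strip the slow component from a speed sample, bin by bin.

    For each display-histogram bin, every sample is removed with
    probability equal to the slow component's share of the mixture
    density in that bin, leaving (in expectation) the fast population.
    Returns ``n_rounds`` independently thinned subsets.
    """
    x = np.asarray(speeds, dtype=float)
    edges = np.histogram_bin_edges(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    share = fit.slow_share(centers)
    which = np.clip(np.digitize(x, edges) - 1, 0, centers.size - 1)
    p_remove = share[which]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_rounds):
        keep = rng.random(x.size) >= p_remove
        out.append(x[keep])
    return out


# ---------------------------------------------------------------------------
# MSD analysis


@dataclass(frozen=True)
class MSDFit:
    """Anomalous-diffusion fit MSD(t) = 4*D*t^alpha + D0 (2D)."""

    D_app: float   # um^2/s
    alpha: float
    D0: float      # um^2 (localization-noise floor)

    def __post_init__(self) -> None:
        if self.D_app < 0:
            raise ValueError("D_app must be >= 0")
        if not 0 < self.alpha <= 2:
            raise ValueError("alpha must lie in (0, 2]")


def compute_msd(
    track: np.ndarray, frame_interval: float, max_lag: Optional[int] = None
) -> pd.DataFrame:
    """Time-averaged 2D MSD over overlapping displacement pairs.

    ``track`` is an (n, 2) array of positions in nm; lags default to a
    quarter of the track length to limit correlation between lag points.
    Returns columns lag (s) and msd (nm^2).
    """
    xy = np.asarray(track, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 5:
        raise ValueError("track must be an (n>=5, 2) array")
    n = xy.shape[0]
    if max_lag is None:
        max_lag = max(1, n // 4)
    lags = np.arange(1, min(max_lag, n - 1) + 1)
    msd = np.array(
        [np.mean(np.sum((xy[k:] - xy[:-k]) ** 2, axis=1)) for k in lags]
    )
    return pd.DataFrame({"lag": lags * frame_interval, "msd": msd})


def average_msd(msds: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average per-track MSD curves on their common lag grid."""
    merged = pd.concat(msds).groupby("lag", as_index=False)["msd"].mean()
    return merged


def fit_anomalous_diffusion(msd: pd.DataFrame) -> MSDFit:
    """Nonlinear least squares for (D, alpha, D0), with physical bounds."""
    t = msd["lag"].to_numpy(float)
    y = msd["msd"].to_numpy(float) * 1e-6  # nm^2 -> um^2
    if t.size < 4:
        raise ValueError("need at least 4 lag points")

    def f(t, D, alpha, D0):
        return 4.0 * D * t**alpha + D0

    slope0 = max((y[min(3, y.size - 1)] - y[0]) / (4 * (t[min(3, t.size - 1)] - t[0] + 1e-12)), 1e-8)
    p0 = [slope0, 1.0, max(y[0], 1e-9)]
    try:
        popt, _ = optimize.curve_fit(
            f, t, y, p0=p0,
            bounds=([0.0, 1e-3, 0.0], [np.inf, 2.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"anomalous-diffusion fit failed to converge: {exc}"
        ) from exc
    return MSDFit(D_app=float(popt[0]), alpha=float(popt[1]), D0=float(popt[2]))
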
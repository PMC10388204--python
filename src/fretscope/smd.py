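"""Desk-scale analog of constant-velocity steered molecular dynamics.

A 1-D overdamped Langevin particle on a configurable multi-well
landscape is pulled by the moving harmonic potential

    U_steer(x, t) = 1/2 k [v t - (x - x0)]^2,     F = k [v t - (x - x0)],

the 1-D projection of the constant-velocity steering protocol (spring
constant k, pulling rate v, pulled coordinate x measured along the fixed
pulling direction).  Units follow the all-atom convention: energy in
kcal/mol, length in angstroms, time in ns; the default k = 5
(kcal/mol)/A^2 and v = 1.5 A/ns.

During a pull the recorded steering force ramps roughly linearly while
the particle is trapped in the bound well and drops abruptly to the
drag plateau once it escapes over the barrier — the "critical turning
point" marking rupture of the bound (closed) conformation.  The
trajectory-analysis operators (:func:`detect_turning_point`,
:func:`detect_distance_steps`, :func:`synchrony_report`) are independent
of the simulator and apply to any imported force / inter-residue
distance time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._changepoint import binary_segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "PullSettings",
    "Landscape",
    "two_well_landscape",
    "flat_landscape",
    "PullingTrajectory",
    "RuptureEvent",
    "steering_energy_force",
    "integrate_pull",
    "detect_turning_point",
    "detect_distance_steps",
    "synchrony_report",
]

KBT_298 = 0.5925  # kcal/mol at 298 K


@dataclass
class PullSettings:
    """Steering and integration parameters (kcal/mol, angstrom, ns)."""

    k: float = 5.0            # spring constant, (kcal/mol)/A^2
    v: float = 1.5            # pulling rate, A/ns
    direction: float = 1.0    # unit vector; fixed +1 in 1-D
    x0: float = 0.0           # initial pulled-coordinate value
    dt: float = 0.002         # ns
    n_steps: int = 10000
    friction: float = 0.5     # gamma, kcal/mol * ns / A^2; drag gamma*v stays
                              # well below rupture forces so the post-rupture
                              # force plateau is near zero
    temperature: float = KBT_298  # k_B T energy scale, kcal/mol
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.v > 0 and self.dt > 0 and self.friction > 0):
            raise ValueError("k, v, dt and friction must be positive")
        if abs(abs(self.direction) - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector (+-1 in 1-D)")


@dataclass
class Landscape:
    """Sum-of-Gaussians potential: smooth wells (negative amplitude) and
    barriers (positive) on a finite simulated range."""

    terms: list  # (amplitude kcal/mol, center A, width A)
    x_range: tuple[float, float] = (-10.0, 40.0)

    def potential(self, x):
        x = np.asarray(x, dtype=float)
        u = np.zeros_like(x)
        for amp, c, w in self.terms:
            u = u + amp * np.exp(-0.5 * ((x - c) / w) ** 2)
        return u

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for amp, c, w in self.terms:
            g = g + amp * np.exp(-0.5 * ((x - c) / w) ** 2) * (-(x - c) / w**2)
        return g

    @property
    def min_feature(self) -> float:
        return min((w for _, _, w in self.terms), default=np.inf)

    @property
    def max_curvature(self) -> float:
        # |d2U/dx2| <= |amp| / w^2 for a Gaussian term
        return sum(abs(amp) / w**2 for amp, _, w in self.terms)


def two_well_landscape(
    well_depth: float = 12.0,
    well_width: float = 1.0,
    barrier_height: float = 6.0,
    barrier_pos: float = 3.0,
    barrier_width: float = 0.8,
) -> Landscape:
    """Bound (closed) well at the origin, barrier, then an open flat
    region: the minimal landscape exhibiting rupture under pulling."""
    return Landscape(
        terms=[(-well_depth, 0.0, well_width), (barrier_height, barrier_pos, barrier_width)]
    )


def flat_landscape() -> Landscape:
    return Landscape(terms=[])


@dataclass
class PullingTrajectory:
    times: np.ndarray
    x: np.ndarray
    reference: np.ndarray            # x0 + v * t
    force: np.ndarray                # k * (reference - x), recorded each step
    distances: dict = field(default_factory=dict)  # named auxiliary series
    settings: PullSettings | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.x) == len(self.reference) == len(self.force) == n):
            raise ValueError("series lengths differ")


@dataclass
class RuptureEvent:
    turning_time: float
    turning_index: int
    peak_force: float
    post_drop_mean: float


def steering_energy_force(x, t, settings: PullSettings):
    """Steering potential energy and force at coordinate x, time t.

    ``U = 1/2 k [v t - (x - x0)]^2`` and ``F = k [v t - (x - x0)]``
    (signed along the pulling direction).
    """
    ext = settings.v * t - (np.asarray(x, dtype=float) - settings.x0) * settings.direction
    return 0.5 * settings.k * ext**2, settings.k * ext


def integrate_pull(landscape: Landscape, settings: PullSettings) -> PullingTrajectory:
    """Euler-Maruyama integration of the pulled overdamped particle.

    dx = [-U_landscape'(x) + F_steer] / gamma * dt
         + sqrt(2 T dt / gamma) * N(0, 1).

    The recorded force equals k * (reference - x) at every step.  The
    run terminates early (flagged) if the particle leaves the landscape
    range.
    """
    drift = settings.v * settings.dt
    if drift >= 0.1 * landscape.min_feature:
        raise ValueError("dt too large: reference drift per step exceeds 10% of "
                         "the smallest landscape feature")
    stiffness = settings.k + landscape.max_curvature
    if settings.dt * stiffness / settings.friction > 0.5:
        raise ValueError("dt too large for stable integration (dt * k_total / gamma > 0.5)")
    rng = np.random.default_rng(settings.seed)
    n = settings.n_steps
    noise = np.sqrt(2.0 * settings.temperature * settings.dt / settings.friction)
    xi = rng.standard_normal(n)
    times = np.arange(n) * settings.dt
    x = np.empty(n)
    x[0] = settings.x0
    lo, hi = landscape.x_range
    truncated = False
    last = n
    for i in range(n - 1):
        f_steer = settings.k * (settings.v * times[i] - (x[i] - settings.x0))
        dx = (-landscape.gradient(x[i]) + f_steer) / settings.friction * settings.dt
        x[i + 1] = x[i] + dx + noise * xi[i]
        if not lo <= x[i + 1] <= hi:
            truncated = True
            last = i + 2
            logger.warning("trajectory left landscape range at step %d; truncated", i + 1)
            break
    times, x = times[:last], x[:last]
    reference = settings.x0 + settings.v * times
    force = settings.k * (reference - x)
    return PullingTrajectory(times, x, reference, force, settings=settings,
                             truncated=truncated)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(window - 1 - pad, x[-1])])
    return np.convolve(padded, kernel, mode="valid")


def detect_turning_point(
    force: np.ndarray,
    smooth_window: int = 201,
    drop_fraction: float = 0.2,
    sustain_frames: int = 500,
    times: np.ndarray | None = None,
    min_peak_z: float = 10.0,
) -> RuptureEvent | None:
    """Locate the critical turning point of a steering-force series.

    On the moving-average-smoothed series, the turning point is the last
    local maximum after which the force drops below ``drop_fraction`` of
    that maximum and stays there for at least ``sustain_frames``:
    "stays" is assessed on the sustained window as a whole (its mean
    below the threshold and at least 80% of its frames below), which
    tolerates the brief thermal excursions any finite-temperature force
    trace shows.  Only maxima comparable to the global smoothed maximum
    (at least half of it) are candidate turning points — a rupture is by
    definition the release of the largest accumulated force, and this
    keeps small post-rupture thermal bumps from shadowing it.
    Candidates whose peak does not exceed ``min_peak_z`` times the
    smoothed noise scale are rejected, so pure noise yields None, as
    does a monotone ramp.
    """
    force = np.asarray(force, dtype=float)
    if len(force) <= 2 * smooth_window:
        raise ValueError("series shorter than 2*smooth_window")
    s = _moving_average(force, smooth_window)
    # robust noise scale of the smoothed series
    sigma = 1.4826 * np.median(np.abs(np.diff(force))) / np.sqrt(2.0)
    sigma_s = sigma / np.sqrt(smooth_window)
    interior = np.arange(1, len(s) - 1)
    is_max = (s[interior] >= s[interior - 1]) & (s[interior] > s[interior + 1])
    candidates = interior[is_max]
    best = None
    global_max = float(s.max())
    for i in candidates:
        peak = s[i]
        if peak <= max(min_peak_z * sigma_s, 0.5 * global_max):
            continue
        thr = drop_fraction * peak
        below = np.nonzero(s[i + 1:] < thr)[0]
        if len(below) == 0:
            continue
        j = i + 1 + below[0]
        if j + sustain_frames > len(s):
            continue
        window = s[j: j + sustain_frames]
        if window.mean() < thr and np.mean(window < thr) >= 0.8:
            best = (int(i), float(peak), float(window.mean()))
    if best is None:
        return None
    idx, peak, post = best
    t = float(times[idx]) if times is not None else float(idx)
    return RuptureEvent(turning_time=t, turning_index=idx, peak_force=peak,
                        post_drop_mean=post)


def detect_distance_steps(
    series: np.ndarray,
    penalty: float | None = None,
    min_seg: int = 10,
) -> list[int]:
    """Mean-shift changepoints of a distance series (binary
    segmentation), sorted ascending.

    The default penalty is ``10 * sigma^2 * log(n)`` with sigma the
    robust (median absolute difference) noise scale, so a constant or
    pure-noise series yields no changepoints.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    if penalty is None:
        sigma = 1.4826 * np.median(np.abs(np.diff(x))) / np.sqrt(2.0)
        penalty = 10.0 * max(sigma, 1e-12) ** 2 * np.log(max(len(x), 2))
    return binary_segmentation(x, penalty=penalty, min_seg=min_seg)


def synchrony_report(
    rupture: RuptureEvent,
    steps: dict[str, list[int]],
    tolerance: int = 50,
) -> pd.DataFrame:
    """Match each distance series' changepoints to the turning point.

    A series is "synchronous" if any of its changepoints lies within
    ``tolerance`` frames of the turning index; the signed lag (changepoint
    minus turning index, frames) of the nearest changepoint is always
    reported, so a step preceding the turning point shows a negative lag.
    """
    rows = []
    for name, cps in steps.items():
        if len(cps) == 0:
            rows.append({"distance": name, "synchronous": False,
                         "lag_frames": np.nan, "n_steps": 0})
            continue
        lags = np.asarray(cps) - rupture.turning_index
        nearest = lags[np.argmin(np.abs(lags))]
        rows.append({
            "distance": name,
            "synchronous": bool(abs(nearest) <= tolerance),
            "lag_frames": int(nearest),
            "n_steps": len(cps),
        })
    return pd.DataFrame(rows)
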
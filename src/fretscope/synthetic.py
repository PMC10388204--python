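"""Synthetic data generation for every stage of the pipeline.

The generator states a ground-truth world and samples from it:

* a discrete-time Markov chain over K conformational states (one step per
  100 ms camera frame), with the per-state mean FRET efficiencies and
  equilibrium occupancies of the constructs under study as presets;
* dual-channel intensity traces with Gaussian per-state efficiency
  spread, additive camera noise, and single-step photobleaching with an
  exponential dye lifetime (~20 s by default);
* small dual-view image stacks containing diffraction-limited spots, for
  exercising detection/pairing/photometry;
* one-site ITC titration heats under a configurable injection schedule;
* (rupture-bearing force/distance series live in :mod:`fretscope.smd`.)

Presets :func:`yeast_ykt6_model` (3 states) and :func:`rat_ykt6_model`
(5 states) encode the measured state efficiencies and populations of the
yeast and rat Ykt6ΔC constructs; their transition matrices are
birth-death chains (nearest-neighbour transitions only) satisfying
detailed balance with the stated occupancies, so direct open<->closed
jumps that skip intermediate states are never generated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .traces import FretTrace

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthModel",
    "MovieSpec",
    "birth_death_transition",
    "yeast_ykt6_model",
    "rat_ykt6_model",
    "simulate_state_path",
    "simulate_trace",
    "simulate_batch",
    "simulate_movie",
    "simulate_itc_protocol",
]


@dataclass
class GroundTruthModel:
    """Generative model for one construct's conformational dynamics.

    ``transition_matrix`` holds *per-frame* transition probabilities
    (row-stochastic); ``occupancy`` must be its stationary distribution.
    ``bleach_lifetime_s = inf`` disables photobleaching.
    """

    K: int
    occupancy: np.ndarray
    efficiency_means: np.ndarray
    efficiency_sds: np.ndarray
    transition_matrix: np.ndarray
    frame_dt: float = 0.1          # 100 ms exposure
    bleach_lifetime_s: float = 20.0
    total_intensity: float = 1000.0
    camera_sd: float = 50.0        # 5% of total_intensity
    name: str = ""

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.efficiency_means = np.asarray(self.efficiency_means, dtype=float)
        self.efficiency_sds = np.asarray(self.efficiency_sds, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for name in ("occupancy", "efficiency_means", "efficiency_sds"):
            if getattr(self, name).shape != (self.K,):
                raise ValueError(f"{name} must have length K={self.K}")
        if self.transition_matrix.shape != (self.K, self.K):
            raise ValueError("transition_matrix must be K x K")
        if np.any(self.transition_matrix < 0) or np.any(
            np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ValueError("transition_matrix rows must be stochastic (sum to 1)")
        if np.max(np.abs(self.occupancy @ self.transition_matrix - self.occupancy)) > 1e-6:
            raise ValueError("occupancy is not the stationary distribution")
        if self.K > 1 and np.any(np.diff(self.efficiency_means) <= 0):
            raise ValueError("efficiency_means must be strictly increasing")
        if not self.frame_dt > 0:
            raise ValueError("frame_dt must be positive")


def birth_death_transition(stationary: np.ndarray, forward: np.ndarray) -> np.ndarray:
    """Nearest-neighbour transition matrix with a prescribed stationary law.

    ``forward[i]`` is the per-frame probability of the i -> i+1 step; the
    backward probabilities follow from detailed balance
    ``pi_i P_{i,i+1} = pi_{i+1} P_{i+1,i}``.
    """
    pi = np.asarray(stationary, dtype=float)
    pi = pi / pi.sum()
    K = len(pi)
    P = np.zeros((K, K))
    for i in range(K - 1):
        P[i, i + 1] = forward[i]
        P[i + 1, i] = pi[i] * forward[i] / pi[i + 1]
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    if np.any(np.diag(P) < 0):
        raise ValueError("forward rates too large for a valid chain")
    return P


def yeast_ykt6_model(**overrides) -> GroundTruthModel:
    """3-state ground truth: yeast Ykt6ΔC.

    State efficiencies 0.20 / 0.42 / 0.68 with equilibrium occupancies
    50.7 / 39.7 / 10.2 % (normalized).  Forward rates give ~1 s dwells in
    the open state, and the E1<->E2 exchange dominates while direct
    E1<->E3 jumps never occur, matching the observed transition-density
    structure.
    """
    pi = np.array([50.7, 39.7, 10.2])
    pi = pi / pi.sum()
    defaults = dict(
        K=3,
        occupancy=pi,
        efficiency_means=np.array([0.20, 0.42, 0.68]),
        efficiency_sds=np.full(3, 0.05),
        transition_matrix=birth_death_transition(pi, np.array([0.10, 0.04])),
        name="yYkt6dC",
    )
    defaults.update(overrides)
    return GroundTruthModel(**defaults)


def rat_ykt6_model(**overrides) -> GroundTruthModel:
    """5-state ground truth: rat Ykt6ΔC.

    State efficiencies 0.20 / 0.35 / 0.48 / 0.64 / 0.79 with occupancies
    31.4 / 19.8 / 19.3 / 16.2 / 13.3 %.
    """
    pi = np.array([31.4, 19.8, 19.3, 16.2, 13.3])
    pi = pi / pi.sum()
    defaults = dict(
        K=5,
        occupancy=pi,
        efficiency_means=np.array([0.20, 0.35, 0.48, 0.64, 0.79]),
        efficiency_sds=np.full(5, 0.05),
        transition_matrix=birth_death_transition(pi, np.full(4, 0.08)),
        name="rYkt6dC",
    )
    defaults.update(overrides)
    return GroundTruthModel(**defaults)


def simulate_state_path(
    model: GroundTruthModel, n_frames: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample a state-index path from the model's Markov chain.

    The initial state is drawn from the equilibrium occupancy, so long
    paths have empirical occupancies converging to it at the usual
    n^{-1/2} rate.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cum = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random(n_frames)
    path = np.empty(n_frames, dtype=np.int64)
    path[0] = np.searchsorted(np.cumsum(model.occupancy), u[0], side="right")
    for t in range(1, n_frames):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t], side="right")
    return path


def simulate_trace(
    path: np.ndarray,
    model: GroundTruthModel,
    seed: int | np.random.Generator,
    trace_id: str = "sim",
) -> FretTrace:
    """Render a state path into a dual-channel intensity trace.

    Per frame the true efficiency is drawn Normal(mean_k, sd_k); the
    acceptor receives ``e * T`` photons and the donor ``(1 - e) * T``
    (T = total_intensity), each plus Normal(0, camera_sd) camera noise.
    A bleach time drawn Exponential(bleach_lifetime_s) truncates the
    trace: both channels drop to pure camera noise afterwards.
    """
    path = np.asarray(path)
    if path.min() < 0 or path.max() >= model.K:
        raise ValueError("state path invalid for model")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(path)
    e = model.efficiency_means[path] + model.efficiency_sds[path] * rng.standard_normal(n)
    T = model.total_intensity
    acceptor = e * T + model.camera_sd * rng.standard_normal(n)
    donor = (1.0 - e) * T + model.camera_sd * rng.standard_normal(n)
    bleach_frame: int | None = None
    if np.isfinite(model.bleach_lifetime_s):
        t_bleach = rng.exponential(model.bleach_lifetime_s)
        k = int(t_bleach / model.frame_dt)
        if k < n:
            bleach_frame = k
            acceptor[k:] = model.camera_sd * rng.standard_normal(n - k)
            donor[k:] = model.camera_sd * rng.standard_normal(n - k)
    return FretTrace(
        trace_id=trace_id,
        frame_dt=model.frame_dt,
        donor=donor,
        acceptor=acceptor,
        bleach_frame=bleach_frame,
        metadata={"true_path": path.copy(), "model": model.name},
    )


def simulate_batch(
    model: GroundTruthModel,
    n_traces: int,
    n_frames: int,
    seed: int,
    n_movies: int = 4,
) -> list[FretTrace]:
    """Generate a batch of traces; molecules are round-robined over
    ``n_movies`` acquisition groups (used for per-movie statistics)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_traces):
        path = simulate_state_path(model, n_frames, rng)
        tr = simulate_trace(path, model, rng, trace_id=f"{model.name or 'sim'}-{i:04d}")
        tr.metadata["movie"] = i % n_movies
        out.append(tr)
    return out


# ---------------------------------------------------------------------------
# Dual-view movies

@dataclass
class MovieSpec:
    """Geometry of a small synthetic dual-view acquisition.

    ``spot_positions`` are donor-view (x, y) coordinates; the acceptor
    view is the same field translated by ``channel_offset``.
    """

    width: int = 64
    height: int = 64
    n_frames: int = 100
    psf_sigma: float = 1.0
    spot_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    channel_offset: tuple[float, float] = (0.0, 0.0)
    background_level: float = 10.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.spot_positions = np.asarray(self.spot_positions, dtype=float).reshape(-1, 2)
        if not self.psf_sigma > 0:
            raise ValueError("psf_sigma must be positive")
        if len(self.spot_positions):
            x, y = self.spot_positions[:, 0], self.spot_positions[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() >= self.width or y.max() >= self.height:
                raise ValueError("spot_positions outside frame bounds")


def _render_spots(
    shape: tuple[int, int], positions: np.ndarray, amplitudes: np.ndarray, sigma: float
) -> np.ndarray:
    """Pixel-integrated isotropic Gaussian spots (amplitude = total mass).

    Pixel (i, j) covers [i - 0.5, i + 0.5] x [j - 0.5, j + 0.5]: integer
    coordinates are pixel centers, matching the photometry convention.
    """
    h, w = shape
    img = np.zeros((h, w))
    edges_x = np.arange(w + 1) - 0.5
    edges_y = np.arange(h + 1) - 0.5
    for (x, y), amp in zip(positions, amplitudes):
        if amp <= 0:
            continue
        px = np.diff(ndtr((edges_x - x) / sigma))
        py = np.diff(ndtr((edges_y - y) / sigma))
        img += amp * np.outer(py, px)
    return img


def simulate_movie(
    spec: MovieSpec, traces: list[FretTrace]
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces into (donor_stack, acceptor_stack) image series.

    Each frame is background + pixel-integrated Gaussian spots whose
    total mass equals the per-frame channel intensity; Poisson shot noise
    is applied to the whole frame unless ``spec.shot_noise`` is False.
    """
    if len(traces) != len(spec.spot_positions):
        raise ValueError("need exactly one trace per spot position")
    pos_d = spec.spot_positions
    if len(pos_d) > 1:
        from scipy.spatial.distance import pdist

        if len(pos_d) and pdist(pos_d).min() < 4 * spec.psf_sigma:
            warnings.warn("spots closer than 4*psf_sigma: overlapping PSFs", stacklevel=2)
    pos_a = pos_d + np.asarray(spec.channel_offset)
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    stacks = []
    for positions, channel in ((pos_d, "donor"), (pos_a, "acceptor")):
        stack = np.empty((spec.n_frames,) + shape)
        for f in range(spec.n_frames):
            amps = np.array(
                [getattr(tr, channel)[f] if f < len(tr) else 0.0 for tr in traces]
            )
            frame = spec.background_level + _render_spots(shape, positions, amps, spec.psf_sigma)
            if spec.shot_noise:
                frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
            stack[f] = frame
        stacks.append(stack)
    return stacks[0], stacks[1]


# ---------------------------------------------------------------------------
# ITC

def simulate_itc_protocol(truth, protocol, noise_sd: float = 0.0, seed: int = 0):
    """Simulate per-injection heats for a one-site titration.

    ``truth`` is an :class:`~fretscope.itc.ItcFit` parameter set and
    ``protocol`` an :class:`~fretscope.itc.ItcIsotherm` whose heats may
    be unset; returns a new isotherm with heats = model + N(0, noise_sd).
    """
    from dataclasses import replace as _replace

    from .itc import model_heats

    heats = model_heats(truth, protocol)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=len(heats))
    return _replace(protocol, heats=heats)
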
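"""Global conformational-state analysis of idealized trajectories.

After per-trace HMM idealization, every change point contributes an
(E_initial, E_final) pair to the transition density plot (TDP), whose
clusters identify the state-to-state transitions.  Global state centers
are estimated by deterministic 1-D k-means on the pooled idealized
efficiencies; thresholds are the midpoints between adjacent centers — an
automated, reproducible stand-in for reading them off the TDP by eye.
Threshold assignment of every frame then yields the headline numbers:
per-state occupancies (time-weighted, over all pooled frames),
most-probable efficiencies (Gaussian fits to the per-state raw-histogram),
dwell times, and transition counts.  Group comparisons use per-movie
occupancy fractions and Welch two-tailed t tests (no multiplicity
correction; flagged in the output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .hmm import IdealizedTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionDensity",
    "StatePopulations",
    "build_tdp",
    "derive_global_states",
    "assign_and_count",
    "most_probable_efficiencies",
    "build_fret_histogram",
    "compare_populations",
]


@dataclass
class TransitionDensity:
    """All (E_initial, E_final) pairs at idealized change points,
    plus their 2-D histogram."""

    pairs: np.ndarray  # (n, 2)
    histogram: np.ndarray
    bin_edges: np.ndarray

    @property
    def n_transitions(self) -> int:
        return len(self.pairs)


@dataclass
class StatePopulations:
    K: int
    centers: np.ndarray
    thresholds: np.ndarray
    fractions: np.ndarray
    per_movie_fractions: pd.DataFrame
    dwell_summaries: pd.DataFrame
    transition_counts: np.ndarray
    n_frames: int = 0
    low_confidence: np.ndarray | None = None


def build_tdp(
    idealized: list[IdealizedTrajectory],
    range_: tuple[float, float] = (0.0, 1.0),
    bins: int = 50,
) -> TransitionDensity:
    """Compile the transition density plot.

    One pair per change point of each idealized trajectory; histogram on
    ``bins x bins`` cells over ``range_`` (default 50x50 over [0, 1]).
    An empty TDP (no transitions) is returned with a log entry rather
    than an error.
    """
    pairs = []
    for tr in idealized:
        e = tr.idealized_efficiency
        jumps = np.nonzero(np.diff(e) != 0)[0]
        for j in jumps:
            pairs.append((e[j], e[j + 1]))
    pairs_arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if len(pairs_arr) == 0:
        logger.info("build_tdp: no transitions; empty TDP")
        edges = np.linspace(range_[0], range_[1], bins + 1)
        return TransitionDensity(pairs_arr, np.zeros((bins, bins)), edges)
    hist, edges, _ = np.histogram2d(
        pairs_arr[:, 0], pairs_arr[:, 1], bins=bins, range=[range_, range_]
    )
    return TransitionDensity(pairs_arr, hist, edges)


def _kmeans_1d(values: np.ndarray, weights: np.ndarray, K: int) -> np.ndarray:
    """Exact (globally optimal) weighted 1-D k-means.

    In one dimension the optimal K-clustering is contiguous in sorted
    order, so it is found exactly by dynamic programming over segment
    boundaries — deterministic and immune to the init failures of Lloyd
    iteration on clusters of very unequal mass.
    """
    order = np.argsort(values, kind="stable")
    v, w = values[order].astype(float), weights[order].astype(float)
    n = len(v)
    W = np.concatenate([[0.0], np.cumsum(w)])
    S = np.concatenate([[0.0], np.cumsum(w * v)])
    Q = np.concatenate([[0.0], np.cumsum(w * v * v)])

    def seg_cost(i, j):  # weighted SSE of v[i..j] inclusive, vectorized over i
        wt = W[j + 1] - W[i]
        sm = S[j + 1] - S[i]
        return (Q[j + 1] - Q[i]) - sm * sm / np.maximum(wt, 1e-300)

    idx = np.arange(n)
    D = seg_cost(0, idx)          # k = 1
    back = np.zeros((K, n), dtype=np.int64)
    for k in range(1, K):
        D_new = np.full(n, np.inf)
        for j in range(k, n):
            i = np.arange(k, j + 1)  # first index of the last segment
            cand = D[i - 1] + seg_cost(i, j)
            best = int(np.argmin(cand))
            D_new[j] = cand[best]
            back[k, j] = k + best
        D = D_new
    # backtrack segment boundaries
    centers = np.empty(K)
    j = n - 1
    for k in range(K - 1, -1, -1):
        i = int(back[k, j]) if k > 0 else 0
        centers[k] = (S[j + 1] - S[i]) / (W[j + 1] - W[i])
        j = i - 1
    return np.sort(centers)


def derive_global_states(
    idealized: list[IdealizedTrajectory], K: int
) -> tuple[np.ndarray, np.ndarray]:
    """Global state centers and thresholds from pooled idealized values.

    Centers: deterministic 1-D k-means (K clusters) over the distinct
    idealized efficiencies, weighted by their frame counts; thresholds:
    midpoints between adjacent centers.  Trace order never matters.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    pooled = np.concatenate([tr.idealized_efficiency for tr in idealized])
    values, counts = np.unique(pooled, return_counts=True)
    if len(values) < K:
        raise ValueError(
            f"only {len(values)} distinct idealized values; reduce K below {K + 1}"
        )
    centers = _kmeans_1d(values, counts.astype(float), K)
    thresholds = 0.5 * (centers[:-1] + centers[1:])
    return centers, thresholds


def assign_and_count(
    idealized: list[IdealizedTrajectory],
    centers: np.ndarray,
    thresholds: np.ndarray,
) -> StatePopulations:
    """Threshold analysis: label every frame, pool the statistics.

    Each frame is labeled by the threshold interval containing its
    idealized efficiency.  Fractions are frame-weighted over the whole
    pool; dwell times are consecutive-run lengths times the frame
    duration; transition counts come from label changes within a trace
    (never across the bleach cut, since idealized trajectories only
    cover pre-bleach frames); per-movie fractions group by each
    trajectory's ``metadata['movie']``.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    K = len(centers)
    if len(thresholds) != K - 1 or (K > 1 and np.any(np.diff(thresholds) <= 0)):
        raise ValueError("need K-1 strictly increasing thresholds")
    counts = np.zeros(K)
    trans = np.zeros((K, K))
    dwell_times: list[list[float]] = [[] for _ in range(K)]
    movie_rows: dict[object, np.ndarray] = {}
    total = 0
    for tr in idealized:
        labels = np.searchsorted(thresholds, tr.idealized_efficiency)
        counts += np.bincount(labels, minlength=K)
        total += len(labels)
        movie = tr.metadata.get("movie", "all")
        movie_rows.setdefault(movie, np.zeros(K))
        movie_rows[movie] += np.bincount(labels, minlength=K)
        change = np.nonzero(np.diff(labels) != 0)[0]
        for j in change:
            trans[labels[j], labels[j + 1]] += 1
        # dwell runs
        bounds = np.concatenate([[0], change + 1, [len(labels)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            dwell_times[labels[a]].append((b - a) * tr.frame_dt)
    fractions = counts / max(total, 1)
    per_movie = pd.DataFrame(
        {m: row / max(row.sum(), 1) for m, row in movie_rows.items()}
    ).T
    per_movie.columns = [f"state_{k}" for k in range(K)]
    per_movie.index.name = "movie"
    dwells = pd.DataFrame(
        {
            "state": np.arange(K),
            "mean_dwell_s": [np.mean(d) if d else np.nan for d in dwell_times],
            "n_dwells": [len(d) for d in dwell_times],
        }
    )
    return StatePopulations(
        K=K,
        centers=np.asarray(centers, dtype=float),
        thresholds=thresholds,
        fractions=fractions,
        per_movie_fractions=per_movie,
        dwell_summaries=dwells,
        transition_counts=trans,
        n_frames=total,
    )


def _gauss(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def most_probable_efficiencies(
    raw_series: list[np.ndarray],
    idealized: list[IdealizedTrajectory],
    thresholds: np.ndarray,
    bins: int = 50,
    range_: tuple[float, float] = (-0.2, 1.2),
    min_frames: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state modal raw efficiency.

    ``raw_series[i]`` must hold the raw efficiencies the i-th idealized
    trajectory was fitted on (same frames, same order).  Frames are
    grouped by their threshold-assigned state label; each state's
    raw-efficiency histogram is fitted with a single Gaussian whose mean
    is the reported mode (falling back to the peak bin if the fit fails,
    logged).  States with fewer than ``min_frames`` frames are flagged
    low-confidence.

    Returns ``(modes, low_confidence_flags)``.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    K = len(thresholds) + 1
    by_state: list[list[np.ndarray]] = [[] for _ in range(K)]
    for raw, ideal in zip(raw_series, idealized, strict=True):
        raw = np.asarray(raw, dtype=float)
        labels = np.searchsorted(thresholds, ideal.idealized_efficiency)
        if len(raw) != len(labels):
            raise ValueError(f"trace {ideal.trace_id}: labels not aligned to raw frames")
        ok = np.isfinite(raw)
        for k in range(K):
            sel = (labels == k) & ok
            if sel.any():
                by_state[k].append(raw[sel])
    modes = np.full(K, np.nan)
    low_conf = np.zeros(K, dtype=bool)
    for k in range(K):
        if not by_state[k]:
            low_conf[k] = True
            continue
        vals = np.concatenate(by_state[k])
        low_conf[k] = len(vals) < min_frames
        hist, edges = np.histogram(vals, bins=bins, range=range_, density=True)
        mids = 0.5 * (edges[:-1] + edges[1:])
        peak = mids[np.argmax(hist)]
        try:
            popt, _ = optimize.curve_fit(
                _gauss, mids, hist,
                p0=[hist.max(), peak, max(np.std(vals), 0.01)],
                maxfev=5000,
            )
            modes[k] = popt[1]
        except RuntimeError:
            logger.warning("state %d: Gaussian fit failed; using peak bin", k)
            modes[k] = peak
    return modes, low_conf


def build_fret_histogram(
    values: np.ndarray | list[np.ndarray],
    bins: int = 50,
    range_: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Density-normalized efficiency histogram (pooled frames).

    ``values`` may be one array or a list of per-trace/per-state arrays
    to pool.  Non-finite values are dropped.
    """
    if isinstance(values, list):
        values = np.concatenate([np.asarray(v, dtype=float) for v in values])
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("no frames to histogram")
    hist, edges = np.histogram(values, bins=bins, range=range_, density=True)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": hist}
    )


def compare_populations(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-state Welch two-sample two-tailed t test on per-movie fractions.

    No multiple-testing correction is applied (flagged in the output).
    Zero variance in both groups with equal means gives p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 movies per group")
    cols = [c for c in group_a.columns if c in group_b.columns]
    rows = []
    for c in cols:
        a = group_a[c].to_numpy(float)
        b = group_b[c].to_numpy(float)
        if np.var(a) == 0 and np.var(b) == 0:
            t, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"state": c, "t": float(t), "p_two_tailed": float(p)})
    out = pd.DataFrame(rows)
    out.attrs["multiplicity_correction"] = "none"
    return out
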
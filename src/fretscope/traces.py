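"""Trace data model, TSV I/O, FRET-efficiency computation, photobleach
detection and quality filtering.

A :class:`FretTrace` holds the donor/acceptor intensity time series of one
immobilized molecule, sampled at a fixed camera exposure (``frame_dt``
seconds per frame).  The apparent FRET efficiency

    E_t = (A_t - bg_A) / [(A_t - bg_A) + gamma * (D_t - bg_D)]

is the distance-sensitive observable: high E means the two dye sites are
close (closed conformation), low E means they are far apart (open
conformation).  Efficiencies are deliberately *not* clamped to [0, 1]:
clamping before HMM fitting biases the emission-mean estimates; display
stages may clamp their axis ranges instead.

Traces end when a dye photobleaches; :func:`detect_bleach` locates the
downward intensity step and everything downstream operates on the
pre-bleach segment only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._changepoint import best_single_shift

logger = logging.getLogger(__name__)

__all__ = [
    "FretTrace",
    "compute_efficiency",
    "detect_bleach",
    "filter_traces",
    "write_traces",
    "read_traces",
]


@dataclass
class FretTrace:
    """Donor/acceptor intensity time series of a single molecule.

    Parameters
    ----------
    trace_id:
        Identifier, unique within a batch.
    frame_dt:
        Seconds per frame (camera exposure), > 0.
    donor, acceptor:
        Intensity series of equal length >= 1.
    efficiency:
        Apparent FRET efficiency per frame; NaN where undefined
        (post-bleach frames, non-positive total intensity).  Filled by
        :func:`compute_efficiency`.
    bleach_frame:
        Index of the first post-bleach frame, or None if the dyes survive
        the whole record.
    metadata:
        Free-form key/values (acquisition id, ground-truth parameters...).
    """

    trace_id: str
    frame_dt: float
    donor: np.ndarray
    acceptor: np.ndarray
    efficiency: np.ndarray | None = None
    bleach_frame: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor must be 1-D arrays of equal length")
        if len(self.donor) < 1:
            raise ValueError("trace must contain at least one frame")
        if not self.frame_dt > 0:
            raise ValueError("frame_dt must be positive")
        if self.efficiency is not None:
            self.efficiency = np.asarray(self.efficiency, dtype=float)
            if self.efficiency.shape != self.donor.shape:
                raise ValueError("efficiency must match channel length")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def n_prebleach(self) -> int:
        """Number of usable frames (before the bleach cut)."""
        return len(self.donor) if self.bleach_frame is None else int(self.bleach_frame)

    @property
    def total(self) -> np.ndarray:
        """Summed donor + acceptor intensity per frame."""
        return self.donor + self.acceptor

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.donor)) * self.frame_dt

    def prebleach_efficiency(self) -> np.ndarray:
        """Finite efficiency values of the pre-bleach segment."""
        if self.efficiency is None:
            raise ValueError(f"trace {self.trace_id}: efficiency not computed")
        e = self.efficiency[: self.n_prebleach]
        return e[np.isfinite(e)]


def _background_estimates(
    trace: FretTrace, background_d: float | None, background_a: float | None
) -> tuple[float, float]:
    # Post-bleach frames are the natural dark reference for each channel;
    # fall back to the configured constants (default 0) otherwise.
    if background_d is not None and background_a is not None:
        return float(background_d), float(background_a)
    bd = 0.0 if background_d is None else float(background_d)
    ba = 0.0 if background_a is None else float(background_a)
    if trace.bleach_frame is not None and trace.bleach_frame < len(trace) - 1:
        post = slice(trace.bleach_frame, None)
        if background_d is None:
            bd = float(np.median(trace.donor[post]))
        if background_a is None:
            ba = float(np.median(trace.acceptor[post]))
    return bd, ba


def compute_efficiency(
    trace: FretTrace,
    gamma: float = 1.0,
    background_d: float | None = None,
    background_a: float | None = None,
) -> FretTrace:
    """Fill the apparent FRET efficiency series of a trace.

    ``E_t = (A_t - bg_A) / [(A_t - bg_A) + gamma * (D_t - bg_D)]``.

    Backgrounds default to the median of the post-bleach segment of each
    channel when a bleach frame is known, else 0.  Frames whose corrected
    total intensity is <= 0 are flagged invalid (NaN), as are post-bleach
    frames.  Values outside [0, 1] are retained.

    Returns a new trace; the input is not modified.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    bd, ba = _background_estimates(trace, background_d, background_a)
    a = trace.acceptor - ba
    d = trace.donor - bd
    denom = a + gamma * d
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(denom > 0, a / denom, np.nan)
    if trace.bleach_frame is not None:
        eff[trace.bleach_frame:] = np.nan
    n_valid = int(np.isfinite(eff[: len(eff) if trace.bleach_frame is None else trace.bleach_frame]).sum())
    if n_valid == 0:
        logger.warning("trace %s: no valid efficiency frames; flagged", trace.trace_id)
    out = replace(trace, efficiency=eff)
    out.metadata = dict(trace.metadata, all_invalid=(n_valid == 0))
    return out


def detect_bleach(trace: FretTrace, window: int = 5, z_threshold: float = 4.0) -> int | None:
    """Locate the photobleach step in the total-intensity series.

    Finds the single changepoint that maximizes the two-segment
    mean-shift likelihood of donor + acceptor, and accepts it as a bleach
    if the shift is *downward* and its standardized magnitude
    (mean drop / pooled within-segment sd) exceeds ``z_threshold``.
    Returns the index of the first post-bleach frame, or None.
    """
    total = trace.total
    if len(total) < 2 * window:
        raise ValueError("trace shorter than 2*window")
    split, shift, z = best_single_shift(total, min_seg=window)
    if split is None or shift >= 0 or z < z_threshold:
        return None
    return int(split)


def filter_traces(
    traces: list[FretTrace],
    min_frames: int = 30,
    min_total_intensity: float = 0.0,
) -> tuple[list[FretTrace], dict[str, int]]:
    """Quality filter; returns survivors and a per-reason rejection count.

    A trace survives if its pre-bleach segment has at least ``min_frames``
    frames and a mean total intensity of at least ``min_total_intensity``.
    Traces marked all-invalid by :func:`compute_efficiency` are dropped.
    Raises if no trace survives (the pipeline cannot proceed).
    """
    if min_frames < 0 or min_total_intensity < 0:
        raise ValueError("thresholds must be non-negative")
    kept: list[FretTrace] = []
    report = {"short": 0, "dim": 0, "invalid": 0}
    for tr in traces:
        n = tr.n_prebleach
        if tr.metadata.get("all_invalid"):
            report["invalid"] += 1
        elif n < min_frames:
            report["short"] += 1
        elif n > 0 and float(np.mean(tr.total[:n])) < min_total_intensity:
            report["dim"] += 1
        else:
            kept.append(tr)
    if not kept:
        raise RuntimeError(f"no traces survived filtering (rejections: {report})")
    return kept, report


# ---------------------------------------------------------------------------
# TSV I/O.  One long-format table: trace_id, frame, time_s, donor, acceptor
# (extra columns tolerated); optional JSON sidecar with per-trace metadata.

def write_traces(traces: list[FretTrace], path: str | Path, sidecar: bool = True) -> None:
    path = Path(path)
    frames = []
    meta: dict[str, dict] = {}
    for tr in traces:
        df = pd.DataFrame(
            {
                "trace_id": tr.trace_id,
                "frame": np.arange(len(tr)),
                "time_s": tr.times,
                "donor": tr.donor,
                "acceptor": tr.acceptor,
            }
        )
        if tr.efficiency is not None:
            df["efficiency"] = tr.efficiency
        frames.append(df)
        meta[tr.trace_id] = {
            "frame_dt": tr.frame_dt,
            "bleach_frame": tr.bleach_frame,
            "metadata": _jsonable(tr.metadata),
        }
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    if sidecar:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_traces(path: str | Path, frame_dt: float = 0.1) -> list[FretTrace]:
    """Read a TSV trace table (tolerating extra columns) + optional sidecar."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"trace_id", "frame", "donor", "acceptor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    out = []
    for tid, g in df.groupby("trace_id", sort=False):
        g = g.sort_values("frame")
        m = meta.get(str(tid), {})
        bleach = m.get("bleach_frame")
        out.append(
            FretTrace(
                trace_id=str(tid),
                frame_dt=float(m.get("frame_dt", frame_dt)),
                donor=g["donor"].to_numpy(float),
                acceptor=g["acceptor"].to_numpy(float),
                efficiency=g["efficiency"].to_numpy(float) if "efficiency" in g else None,
                bleach_frame=None if bleach is None else int(bleach),
                metadata=m.get("metadata", {}),
            )
        )
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
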
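"""Spot detection, dual-view channel pairing, and aperture photometry.

A minimal single-molecule localization/extraction stage for dual-view
image stacks: molecules are detected as local maxima of a Gaussian-
smoothed detection image (the average of the first frames, where spots
are brightest), donor/acceptor views are registered by a fixed known
translation and paired by greedy nearest-neighbour matching, and
intensity traces are read out by circular-aperture photometry with a
local-annulus background estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .traces import FretTrace

logger = logging.getLogger(__name__)

__all__ = [
    "SpotSet",
    "detect_spots",
    "pair_channels",
    "extract_trace",
    "extract_paired_traces",
    "read_stack",
    "write_stack",
]


@dataclass
class SpotSet:
    """Detected coordinates per channel and their pairing."""

    donor_coords: np.ndarray                 # (n, 2) sub-pixel (x, y)
    acceptor_coords: np.ndarray
    pairing: list = field(default_factory=list)  # (donor_idx, acceptor_idx)
    detection_frame: int = 0
    aperture_radius: float = 3.0
    annulus: tuple[float, float] = (5.0, 7.0)

    def __post_init__(self) -> None:
        d_idx = [p[0] for p in self.pairing]
        a_idx = [p[1] for p in self.pairing]
        if len(set(d_idx)) != len(d_idx) or len(set(a_idx)) != len(a_idx):
            raise ValueError("paired indices must be unique")
        if not self.aperture_radius < self.annulus[0]:
            raise ValueError("aperture must be smaller than the annulus inner radius")


def detect_spots(
    frame: np.ndarray,
    z_threshold: float = 5.0,
    min_separation: float = 5.0,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Detect diffraction-limited spots in a single image.

    Local maxima of the Gaussian-smoothed frame exceeding
    background + z_threshold * noise are kept (background and noise from
    the robust median/MAD statistics of the smoothed frame, so bright
    spots do not inflate their own threshold), non-maximum-suppressed
    within ``min_separation`` pixels, and refined to sub-pixel (x, y) by
    background-subtracted center-of-mass in a 5x5 window, re-centered
    once.  Returns an (n, 2) array; empty is allowed.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2 or not np.all(np.isfinite(img)):
        raise ValueError("frame must be a finite 2-D image")
    smooth = ndimage.gaussian_filter(img, smooth_sigma)
    bg = float(np.median(smooth))
    noise = 1.4826 * float(np.median(np.abs(smooth - bg)))
    thr = bg + z_threshold * max(noise, 1e-12)
    size = max(int(round(min_separation)) | 1, 3)
    is_max = (smooth == ndimage.maximum_filter(smooth, size=size)) & (smooth > thr)
    ys, xs = np.nonzero(is_max)
    # non-maximum suppression across remaining candidates (brightest first)
    order = np.argsort(smooth[ys, xs])[::-1]
    kept: list[tuple[float, float]] = []
    for i in order:
        y, x = ys[i], xs[i]
        if any((x - kx) ** 2 + (y - ky) ** 2 < min_separation**2 for kx, ky in kept):
            continue
        kept.append((float(x), float(y)))
    img_bg = img - float(np.median(img))
    h, w = img.shape
    coords = []
    for x, y in kept:
        for _ in range(2):  # center-of-mass, re-centered once
            x0 = min(max(int(round(x)), 2), w - 3)
            y0 = min(max(int(round(y)), 2), h - 3)
            win = np.clip(img_bg[y0 - 2: y0 + 3, x0 - 2: x0 + 3], 0, None)
            if win.sum() <= 0:
                break
            yy, xx = np.mgrid[y0 - 2: y0 + 3, x0 - 2: x0 + 3]
            x = float((win * xx).sum() / win.sum())
            y = float((win * yy).sum() / win.sum())
        coords.append((x, y))
    return np.asarray(coords, dtype=float).reshape(-1, 2)


def pair_channels(
    donor_spots: np.ndarray,
    acceptor_spots: np.ndarray,
    offset: tuple[float, float] = (0.0, 0.0),
    tolerance: float = 2.0,
) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour pairing of the two views.

    Acceptor positions are matched against donor positions shifted by the
    known channel ``offset``; matches farther than ``tolerance`` pixels
    are dropped (counted in the log), and ambiguous matches (two
    acceptor candidates within tolerance of the same donor and within
    1 px of each other) drop both.
    """
    donor_spots = np.asarray(donor_spots, dtype=float).reshape(-1, 2)
    acceptor_spots = np.asarray(acceptor_spots, dtype=float).reshape(-1, 2)
    if len(donor_spots) == 0 or len(acceptor_spots) == 0:
        return []
    predicted = donor_spots + np.asarray(offset)
    dists = np.linalg.norm(predicted[:, None, :] - acceptor_spots[None, :, :], axis=2)
    pairing: list[tuple[int, int]] = []
    used_a: set[int] = set()
    n_dropped = 0
    for di in np.argsort(dists.min(axis=1)):
        row = dists[di].copy()
        row[list(used_a)] = np.inf
        ai = int(np.argmin(row))
        if row[ai] > tolerance:
            n_dropped += 1
            continue
        inside = np.nonzero(row <= tolerance)[0]
        ambiguous = any(
            o != ai and np.linalg.norm(acceptor_spots[o] - acceptor_spots[ai]) < 1.0
            for o in inside
        )
        if ambiguous:
            n_dropped += 1
            logger.warning("ambiguous match for donor %d: dropped", di)
            continue
        used_a.add(ai)
        pairing.append((int(di), ai))
    if n_dropped:
        logger.info("pair_channels: %d spots unmatched/dropped", n_dropped)
    return sorted(pairing)


def _disk_masks(shape, x, y, r_aperture, r_in, r_out):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    return d2 <= r_aperture**2, (d2 >= r_in**2) & (d2 <= r_out**2)


def extract_trace(
    stack: np.ndarray,
    coordinate: tuple[float, float],
    aperture_radius: float = 3.0,
    annulus: tuple[float, float] = (5.0, 7.0),
) -> np.ndarray:
    """Aperture photometry of one spot through an image stack.

    Per frame: summed intensity inside the aperture minus the annulus
    median times the aperture pixel count.  A spot whose aperture is
    clipped by the frame edge is rejected (raises; caller logs/skips).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, h, w)")
    x, y = coordinate
    h, w = stack.shape[1:]
    if not (aperture_radius <= x <= w - 1 - aperture_radius
            and aperture_radius <= y <= h - 1 - aperture_radius):
        raise ValueError(f"aperture at ({x:.1f}, {y:.1f}) clipped by frame edge")
    ap, ann = _disk_masks((h, w), x, y, aperture_radius, *annulus)
    n_ap = ap.sum()
    flat = stack.reshape(len(stack), -1)
    signal = flat[:, ap.ravel()].sum(axis=1)
    background = np.median(flat[:, ann.ravel()], axis=1)
    return signal - background * n_ap


def extract_paired_traces(
    donor_stack: np.ndarray,
    acceptor_stack: np.ndarray,
    offset: tuple[float, float] = (0.0, 0.0),
    frame_dt: float = 0.1,
    n_detect_frames: int = 10,
    z_threshold: float = 5.0,
    min_separation: float = 5.0,
    tolerance: float = 2.0,
    aperture_radius: float = 3.0,
    annulus: tuple[float, float] = (5.0, 7.0),
) -> tuple[list[FretTrace], SpotSet]:
    """Full extraction: detect on the first-frames average of each view,
    pair the channels, and read out one trace per matched molecule."""
    det_d = donor_stack[:n_detect_frames].mean(axis=0)
    det_a = acceptor_stack[:n_detect_frames].mean(axis=0)
    spots_d = detect_spots(det_d, z_threshold, min_separation)
    spots_a = detect_spots(det_a, z_threshold, min_separation)
    pairing = pair_channels(spots_d, spots_a, offset=offset, tolerance=tolerance)
    spotset = SpotSet(spots_d, spots_a, pairing, aperture_radius=aperture_radius,
                      annulus=annulus)
    traces: list[FretTrace] = []
    for m, (di, ai) in enumerate(pairing):
        try:
            donor = extract_trace(donor_stack, tuple(spots_d[di]), aperture_radius, annulus)
            acceptor = extract_trace(acceptor_stack, tuple(spots_a[ai]), aperture_radius, annulus)
        except ValueError as exc:
            logger.warning("molecule %d rejected: %s", m, exc)
            continue
        traces.append(
            FretTrace(
                trace_id=f"mol-{m:03d}",
                frame_dt=frame_dt,
                donor=donor,
                acceptor=acceptor,
                metadata={"donor_xy": spots_d[di].tolist(),
                          "acceptor_xy": spots_a[ai].tolist()},
            )
        )
    return traces, spotset


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))
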
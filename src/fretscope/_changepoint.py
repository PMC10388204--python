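"""Mean-shift changepoint primitives.

Both the photobleach detector and the distance-step detector reduce to
locating abrupt shifts in the mean of a noisy series.  The exact single
changepoint is found by an O(n) scan over all split positions using
cumulative sums; multiple changepoints use binary segmentation with a
penalty on the cost reduction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["best_single_shift", "binary_segmentation"]


def _split_costs(x: np.ndarray, min_seg: int) -> tuple[np.ndarray, np.ndarray]:
    """SSE of a two-segment mean fit for every admissible split position.

    Returns (splits, costs): splits are candidate first-index-of-second-
    segment positions; costs the total within-segment sum of squares.
    """
    n = len(x)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    t = np.arange(min_seg, n - min_seg + 1)  # split positions
    s1, s2 = c1[t - 1], c2[t - 1]
    sse_left = s2 - s1 * s1 / t
    nr = n - t
    sse_right = (c2[-1] - s2) - (c1[-1] - s1) ** 2 / nr
    return t, sse_left + sse_right


def best_single_shift(
    x: np.ndarray, min_seg: int = 2
) -> tuple[int | None, float, float]:
    """Best single mean-shift changepoint of a series.

    Maximizes the two-segment Gaussian likelihood (equivalently minimizes
    the pooled within-segment SSE).  Returns ``(split, shift, z)`` where
    ``split`` is the first index of the second segment, ``shift`` the
    mean change (after - before) and ``z`` its magnitude standardized by
    the pooled within-segment standard deviation.  ``(None, 0, 0)`` if no
    admissible split exists.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_seg:
        return None, 0.0, 0.0
    t, costs = _split_costs(x, min_seg)
    i = int(np.argmin(costs))
    split = int(t[i])
    mu_l = float(np.mean(x[:split]))
    mu_r = float(np.mean(x[split:]))
    pooled_sd = float(np.sqrt(max(costs[i] / n, 1e-300)))
    shift = mu_r - mu_l
    return split, shift, abs(shift) / pooled_sd


def binary_segmentation(
    x: np.ndarray, penalty: float, min_seg: int = 2
) -> list[int]:
    """Binary-segmentation mean-shift changepoints, sorted ascending.

    Recursively splits the segment at the position that most reduces the
    within-segment SSE, accepting a split only if the reduction exceeds
    ``penalty``.  ``penalty`` is on the SSE scale: a natural choice is
    ``c * sigma**2 * log(n)`` with c around 3-10.
    """
    x = np.asarray(x, dtype=float)
    found: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * min_seg:
            return
        mu = seg.mean()
        sse0 = float(np.sum((seg - mu) ** 2))
        t, costs = _split_costs(seg, min_seg)
        i = int(np.argmin(costs))
        if sse0 - costs[i] <= penalty:
            return
        split = lo + int(t[i])
        recurse(lo, split)
        found.append(split)
        recurse(split, hi)

    recurse(0, len(x))
    return sorted(found)
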
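"""Independent brute-force oracles used by the tests.

Deliberately naive: double loops, angle sampling, exhaustive enumeration.
They share no code path with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

from memnano.core import PointPattern, Region


def circle_fraction_by_sampling(
    center: tuple[float, float], radius: float, region: Region, n_angles: int = 200_000
) -> float:
    """Fraction of a circle inside the rectangle by dense angle sampling."""
    theta = (np.arange(n_angles) + 0.5) * (2.0 * np.pi / n_angles)
    x = center[0] + radius * np.cos(theta)
    y = center[1] + radius * np.sin(theta)
    inside = (x >= 0) & (x <= region.width) & (y >= 0) & (y <= region.height)
    return inside.mean()


def edge_weight_py(
    cx: float, cy: float, r: float, width: float, height: float
) -> float:
    """Pure-Python re-derivation of the rectangle edge-correction weight.

    Independent of the vectorized implementation: works directly from the
    four per-edge cap angles and the adjacent-corner overlaps.
    """

    def cap(d: float) -> float:  # half-angle of the cap outside one edge
        return math.acos(max(-1.0, min(1.0, d / r)))

    pl, pr = cap(cx), cap(width - cx)
    pb, pt = cap(cy), cap(height - cy)
    exterior = 2.0 * (pl + pr + pb + pt)
    for a, b in ((pl, pb), (pl, pt), (pr, pb), (pr, pt)):
        exterior -= max(0.0, a + b - math.pi / 2.0)
    p = 1.0 - exterior / (2.0 * math.pi)
    if p <= 0.0:
        raise ValueError("circle entirely outside the region")
    return 1.0 / p


def ripley_k_naive(
    pattern: PointPattern, radii: np.ndarray, corrected: bool = True
) -> np.ndarray:
    """O(n^2) double-loop K estimator with per-pair edge weights."""
    pts = pattern.points
    n = pts.shape[0]
    width, height = pattern.region.width, pattern.region.height
    area = pattern.region.area
    k = np.zeros(len(radii))
    for i in range(n):
        xi, yi = float(pts[i, 0]), float(pts[i, 1])
        for j in range(n):
            if i == j:
                continue
            d = math.hypot(xi - pts[j, 0], yi - pts[j, 1])
            if d > radii[-1]:
                continue
            w = edge_weight_py(xi, yi, d, width, height) if corrected else 1.0
            for ri, r in enumerate(radii):
                if d <= r:
                    k[ri] += w
    return area / (n * (n - 1)) * k


def msd_pair_count_naive(frames_list: list[np.ndarray], max_lag: int) -> int:
    """Number of admissible (t, t+l) pairs for l = 1..max_lag over all tracks."""
    count = 0
    for frames in frames_list:
        for a in range(len(frames)):
            for b in range(a + 1, len(frames)):
                if 1 <= frames[b] - frames[a] <= max_lag:
                    count += 1
    return count


def cac_breakpoint_naive(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive continuous two-segment fit; returns the best breakpoint."""
    best_ssr, best_xb = np.inf, None
    n = x.size
    for k in range(2, n - 2):
        xb = x[k]
        design = np.column_stack([np.ones(n), x, np.where(x > xb, x - xb, 0.0)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        ssr = float((((design @ coef) - y) ** 2).sum())
        if best_xb is None or ssr < best_ssr:
            best_ssr, best_xb = ssr, xb
    return best_xb
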
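"""Canny edge detection on the CIELAB luminance channel.

Pattern metrics are defined over binary edge maps, so the exact detector
dialect matters and is pinned here:

1. gradient = derivative-of-Gaussian at scale ``sigma`` (replicate padding);
2. gradient magnitude normalized by its maximum, so thresholds are
   fractions of the strongest edge response (the convention of the MATLAB
   Image Processing Toolbox detector the field uses);
3. non-maximum suppression with the gradient direction quantized to four
   sectors (0, 45, 90, 135 degrees) and interpolation-free neighbor
   comparison — strictly greater than the neighbor in the negative
   gradient direction, greater-or-equal in the positive one, so an ideal
   straight step yields a one-pixel-wide edge;
4. hysteresis linking (8-connectivity): weak pixels (>= low) survive only
   in components containing a strong pixel (>= high).

When only a high threshold is supplied the low threshold defaults to
0.4 * high, again following the toolbox convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

LOW_THRESHOLD_FACTOR = 0.4


@dataclass
class EdgeMap:
    """Binary edge raster plus the detector parameters that produced it."""

    edges: np.ndarray
    sigma: float
    high_threshold: float
    low_threshold: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=bool)
        if self.edges.ndim != 2:
            raise ValueError("edge map must be 2-D")
        if not (0 < self.low_threshold < self.high_threshold < 1):
            raise ValueError("thresholds must satisfy 0 < low < high < 1")


def gradient_magnitude_direction(L: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derivative-of-Gaussian gradient: (magnitude, d/drow, d/dcol)."""
    L = np.asarray(L, dtype=float)
    gr = ndimage.gaussian_filter(L, sigma, order=(1, 0), mode="nearest")
    gc = ndimage.gaussian_filter(L, sigma, order=(0, 1), mode="nearest")
    return np.hypot(gr, gc), gr, gc


def _nms(mag: np.ndarray, gr: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """Interpolation-free non-maximum suppression over 4 direction sectors."""
    H, W = mag.shape
    # pad with -inf so border pixels only compete with in-frame neighbors
    p = np.full((H + 2, W + 2), -np.inf)
    p[1:-1, 1:-1] = mag
    angle = np.degrees(np.arctan2(gr, gc)) % 180.0
    sector = np.zeros(mag.shape, dtype=np.uint8)
    sector[(angle >= 22.5) & (angle < 67.5)] = 1
    sector[(angle >= 67.5) & (angle < 112.5)] = 2
    sector[(angle >= 112.5) & (angle < 157.5)] = 3

    # neighbor offsets (negative-direction, positive-direction) per sector
    offs = {
        0: ((0, -1), (0, 1)),
        1: ((-1, -1), (1, 1)),
        2: ((-1, 0), (1, 0)),
        3: ((-1, 1), (1, -1)),
    }
    keep = np.zeros(mag.shape, dtype=bool)
    for s, ((dr1, dc1), (dr2, dc2)) in offs.items():
        n1 = p[1 + dr1 : 1 + dr1 + H, 1 + dc1 : 1 + dc1 + W]
        n2 = p[1 + dr2 : 1 + dr2 + H, 1 + dc2 : 1 + dc2 + W]
        sel = sector == s
        keep[sel] = (mag[sel] > n1[sel]) & (mag[sel] >= n2[sel])
    keep &= mag > 0
    return keep


def canny(
    L: np.ndarray,
    sigma: float = 3.0,
    high: float = 0.2,
    low: float | None = None,
) -> EdgeMap:
    """Detect edges in a luminance image.

    ``high`` and ``low`` are fractions of the maximum gradient magnitude;
    ``low`` defaults to 0.4 * high.  A constant image yields a valid
    all-false edge map.
    """
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("luminance image must be finite")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if low is None:
        low = LOW_THRESHOLD_FACTOR * high
    if not (0 < low < high < 1):
        raise ValueError("thresholds must satisfy 0 < low < high < 1")

    mag, gr, gc = gradient_magnitude_direction(L, sigma)
    peak = mag.max()
    if peak == 0:  # constant image: no gradient anywhere
        return EdgeMap(np.zeros(L.shape, dtype=bool), sigma, high, low)
    mag = mag / peak
    ridge = _nms(mag, gr, gc)
    strong = ridge & (mag >= high)
    weak = ridge & (mag >= low)
    labels, n = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return EdgeMap(np.zeros(L.shape, dtype=bool), sigma, high, low)
    keep_ids = np.unique(labels[strong])
    keep_ids = keep_ids[keep_ids > 0]
    edges = np.isin(labels, keep_ids)
    return EdgeMap(edges, sigma, high, low)


def edge_proportion(edge_map: EdgeMap, region: np.ndarray) -> float:
    """Fraction of region pixels flagged as edges.

    Raises ValueError on an empty region; callers record the metric as
    missing rather than zero.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != edge_map.edges.shape:
        raise ValueError("region and edge map dimensions differ")
    n = int(region.sum())
    if n == 0:
        raise ValueError("edge proportion undefined over an empty region")
    return float((edge_map.edges & region).sum()) / n
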
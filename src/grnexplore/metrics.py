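"""Diversity metrics: threshold coverage and binning coverage.

Threshold coverage measures the area of the union of epsilon-balls
centered on the discovered behavior points, after rescaling the behavior
space to the unit square, denominated by the area of the epsilon-padded
square (1+2*eps)^2.  Under this normalization four mutually disjoint
attractors at eps=0.05 cover exactly 4*pi*eps^2/(1+2*eps)^2 ~ 0.026,
which is the analytic ceiling for a system with four point attractors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["CoverageConfig", "threshold_coverage", "binning_coverage"]

MIN_EXTENT = 1e-6


@dataclass
class CoverageConfig:
    epsilon: float = 0.05
    box: Optional[np.ndarray] = None  # (2, d): row 0 = low, row 1 = high
    grid_resolution: int = 2000

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)


def _normalize(points: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if box is None:
        lo = points.min(axis=0)
        hi = points.max(axis=0)
    else:
        lo, hi = box[0], box[1]
    extent = np.maximum(hi - lo, MIN_EXTENT)
    return (points - lo) / extent


def threshold_coverage(points, config: Optional[CoverageConfig] = None) -> float:
    """Fraction of the padded unit square covered by eps-disks (2-D only).

    Deterministic grid integration: cell centers of a G x G grid over
    [-eps, 1+eps]^2 are tested against every disk.  Points are rescaled to
    the unit square first (shared normalization box via config.box when
    comparing point sets).
    """
    config = config or CoverageConfig()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        return 0.0
    points = points[np.all(np.isfinite(points), axis=1)]
    if points.size == 0:
        return 0.0
    if points.shape[1] != 2:
        raise ValueError("threshold coverage is supported in 2-D only")
    eps = config.epsilon
    G = config.grid_resolution
    pts = _normalize(points, config.box)
    h = (1.0 + 2.0 * eps) / G
    covered = np.zeros((G, G), dtype=bool)
    centers = -eps + (np.arange(G) + 0.5) * h
    r_cells = int(np.ceil(eps / h)) + 1
    eps2 = eps * eps
    for px, py in pts:
        cx = int(np.floor((px + eps) / h))
        cy = int(np.floor((py + eps) / h))
        x0, x1 = max(cx - r_cells, 0), min(cx + r_cells + 1, G)
        y0, y1 = max(cy - r_cells, 0), min(cy + r_cells + 1, G)
        if x0 >= x1 or y0 >= y1:
            continue
        dx2 = (centers[x0:x1] - px) ** 2
        dy2 = (centers[y0:y1] - py) ** 2
        covered[x0:x1, y0:y1] |= dx2[:, None] + dy2[None, :] <= eps2
    return float(covered.sum()) / (G * G)


def binning_coverage(points, bins_per_dim: int = 20, box: Optional[np.ndarray] = None) -> float:
    """Occupied-bin fraction on a per-axis rescaled grid (any dimension)."""
    if bins_per_dim < 1:
        raise ValueError("bins_per_dim must be >= 1")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        return 0.0
    points = points[np.all(np.isfinite(points), axis=1)]
    if points.size == 0:
        return 0.0
    pts = _normalize(points, box)
    idx = np.clip((pts * bins_per_dim).astype(int), 0, bins_per_dim - 1)
    occupied = len({tuple(row) for row in idx})
    return occupied / float(bins_per_dim ** points.shape[1])
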
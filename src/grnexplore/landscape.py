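"""Trajectory-based pseudopotential energy landscape.

All visited states of a set of trajectories are projected to a 2-D
behavior plane and histogrammed on a G x G grid; after adding a
pseudocount the cell probabilities P give the pseudopotential
U = -ln(P), optionally smoothed with a bicubic spline on the grid.
Attractors appear as local minima of U.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .dynamics import Trajectory

__all__ = ["EnergyLandscape", "estimate_energy_landscape"]


@dataclass
class EnergyLandscape:
    x_centers: np.ndarray
    y_centers: np.ndarray
    P: np.ndarray  # (G, G), rows indexed by x cell
    U: np.ndarray  # raw -ln(P)
    U_smooth: np.ndarray

    def local_minima(self) -> List[Tuple[int, int]]:
        """Grid cells strictly below all 8 neighbors (on the raw U)."""
        U = self.U
        G, H = U.shape
        out = []
        for i in range(G):
            for j in range(H):
                v = U[i, j]
                i0, j0 = max(i - 1, 0), max(j - 1, 0)
                nb = U[i0 : i + 2, j0 : j + 2]
                mask = np.ones(nb.shape, dtype=bool)
                mask[i - i0, j - j0] = False
                if nb[mask].size and (nb[mask] > v).all():
                    out.append((i, j))
        return out

    def to_table(self) -> np.ndarray:
        """(G*G, 4) rows of (x, y, P, U_smooth) for external rendering."""
        xs, ys = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return np.column_stack(
            [xs.ravel(), ys.ravel(), self.P.ravel(), self.U_smooth.ravel()]
        )


def estimate_energy_landscape(
    trajectories: Sequence[Trajectory],
    nodes: Tuple[int, int] = (0, 1),
    grid_size: int = 100,
    pseudocount: float = 0.5,
    box: Optional[np.ndarray] = None,
    smoothing: float = 0.0,
) -> EnergyLandscape:
    """Histogram trajectory states over the plane and return U = -ln(P).

    States are weighted uniformly across time points (full trajectories are
    histogrammed, no burn-in discard).  ``smoothing`` is the spline
    regularization factor (0 = interpolating, leaves grid values intact).
    """
    pts = [t.states[:, list(nodes)] for t in trajectories if t.valid]
    if not pts:
        raise ValueError("need at least one valid trajectory")
    X = np.vstack(pts)
    if box is None:
        lo = X.min(axis=0)
        hi = X.max(axis=0)
    else:
        box = np.asarray(box, dtype=float)
        lo, hi = box[0], box[1]
    extent = np.maximum(hi - lo, 1e-9)
    H, xe, ye = np.histogram2d(
        X[:, 0], X[:, 1], bins=grid_size,
        range=[[lo[0], lo[0] + extent[0]], [lo[1], lo[1] + extent[1]]],
    )
    H += pseudocount
    P = H / H.sum()
    U = -np.log(P)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    if grid_size >= 4:
        spline = RectBivariateSpline(xc, yc, U, s=smoothing)
        U_smooth = spline(xc, yc)
    else:
        U_smooth = U.copy()
    return EnergyLandscape(xc, yc, P, U, U_smooth)
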
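"""Trajectory classification and system curation filters.

A trajectory is *valid* if it contains no NaN and no negative values,
*settled* if there is no late time t >= settle_after with
|y(t) - y(T)| >= 0.02 * |y(T) - y(0)| on the target node, and *periodic*
(a sustained oscillation) if some non-DC bin of the unnormalized DFT of
the second half [T/2, T] has magnitude >= 40.

The fixed DFT threshold 40 is scale-bound: it is meaningful at the default
sampling (12,501 half-window points, where a 0.1-amplitude sine peaks at
0.1 * 12500 / 2 = 625).  The half-window length is therefore recorded in
the diagnostics of every classification.

System-level filters applied to a batch of rollouts from random initial
states (protocol: 50 states drawn uniformly from the intervention space):

* F1 — fails if >= 20% of trajectories are invalid, unsettled or periodic;
* F2 — fails if the endpoint range of either behavior axis is < 0.1;
* F3 — fails if the endpoints occupy <= 4 bins of a 20 x 20 binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "TrajectoryClass",
    "FilterResult",
    "classify_trajectory",
    "apply_system_filters",
    "is_sustained_oscillator",
]

SETTLE_FRACTION = 0.02
DFT_THRESHOLD = 40.0
F1_PROPORTION = 0.20
F2_MIN_RANGE = 0.1
F3_BINS = 20
F3_MIN_OCCUPIED = 4  # fail if occupied bins <= 4


@dataclass
class TrajectoryClass:
    valid: bool
    settled: bool
    periodic: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def passes(self) -> bool:
        return self.valid and self.settled and not self.periodic


def _second_half(y: np.ndarray) -> np.ndarray:
    return y[(y.shape[0] - 1) // 2 :]


def classify_trajectory(
    traj: Trajectory,
    node: int,
    settle_after: Optional[float] = None,
    settle_frac: float = SETTLE_FRACTION,
    dft_threshold: float = DFT_THRESHOLD,
) -> TrajectoryClass:
    """Classify one node's signal; never raises.

    ``settle_after`` defaults to 0.96 * T, i.e. 2400 s on the default
    2500 s horizon.
    """
    diagnostics: dict = {}
    y_all = traj.states
    finite = np.isfinite(y_all)
    valid = bool(finite.all() and (y_all[finite] >= 0).all())
    y = traj.states[:, node]
    T = traj.T
    if settle_after is None:
        settle_after = 0.96 * T
    settled = True
    periodic = False
    if valid:
        tail = traj.times >= settle_after
        scale = abs(y[-1] - y[0])
        dev = np.abs(y[tail] - y[-1])
        # zero net movement: only genuinely nonzero late deviation counts
        bad = dev >= settle_frac * scale if scale > 0 else dev > 0
        if bad.any():
            settled = False
            diagnostics["unsettled_t"] = float(traj.times[tail][bad][0])
        half = _second_half(y)
        spectrum = np.abs(np.fft.rfft(half))
        diagnostics["half_window_points"] = int(half.size)
        if spectrum.size > 1:
            k = 1 + int(np.argmax(spectrum[1:]))
            diagnostics["peak_bin"] = k
            diagnostics["peak_magnitude"] = float(spectrum[k])
            periodic = bool(spectrum[k] >= dft_threshold)
    else:
        settled = False
    return TrajectoryClass(valid, settled, periodic, diagnostics)


def is_sustained_oscillator(traj: Trajectory, node: int, **kwargs) -> bool:
    """True iff the trajectory is valid and passes the DFT periodicity test."""
    cls = classify_trajectory(traj, node, **kwargs)
    return cls.valid and cls.periodic


@dataclass
class FilterResult:
    passed: bool
    reason: Optional[str]  # F1 | F2 | F3 | None
    f1_proportion: float
    f2_ranges: Tuple[float, float]
    f3_occupied_bins: int


def apply_system_filters(
    trajectories: Sequence[Trajectory],
    node_pair: Tuple[int, int],
    settle_after: Optional[float] = None,
) -> FilterResult:
    """Apply the F1/F2/F3 database filters to a batch of rollouts."""
    i, j = node_pair
    n_bad = 0
    endpoints = []
    for traj in trajectories:
        ci = classify_trajectory(traj, i, settle_after=settle_after)
        cj = classify_trajectory(traj, j, settle_after=settle_after)
        if not (ci.passes and cj.passes):
            n_bad += 1
        if traj.valid:
            endpoints.append(traj.states[-1, [i, j]])
    prop = n_bad / len(trajectories) if trajectories else 1.0
    pts = np.array(endpoints) if endpoints else np.zeros((0, 2))
    if pts.shape[0]:
        ranges = tuple(float(r) for r in (pts.max(axis=0) - pts.min(axis=0)))
    else:
        ranges = (0.0, 0.0)
    occupied = 0
    if pts.shape[0]:
        lo = pts.min(axis=0)
        extent = np.maximum(pts.max(axis=0) - lo, 1e-12)
        idx = np.clip(((pts - lo) / extent * F3_BINS).astype(int), 0, F3_BINS - 1)
        occupied = len({tuple(r) for r in idx})
    if prop >= F1_PROPORTION:
        return FilterResult(False, "F1", prop, ranges, occupied)
    if min(ranges) < F2_MIN_RANGE:
        return FilterResult(False, "F2", prop, ranges, occupied)
    if occupied <= F3_MIN_OCCUPIED:
        return FilterResult(False, "F3", prop, ranges, occupied)
    return FilterResult(True, None, prop, ranges, occupied)
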
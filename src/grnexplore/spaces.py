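"""Intervention spaces and behavior-space encoders.

An *intervention* sets the controllable part of a rollout: either the
initial node states, or (for circuit engineering) the joint
(y0, W, B) parameter vector of a gene circuit.  A *behavior descriptor*
is the low-dimensional summary the explorer navigates: the trajectory
endpoint of a node pair, the amplitude spectrum of one node's signal, or
the (amplitude, frequency, offset) triple of an oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "InterventionSpace",
    "BehaviorSpace",
    "BehaviorDescriptor",
    "build_intervention_space",
    "encode_endpoint",
    "encode_fourier",
    "extract_oscillation_descriptor",
    "encode",
    "descriptor_distances",
]

#: number of low-frequency amplitude bins kept for the Fourier goal space
FOURIER_BINS = 256


@dataclass
class InterventionSpace:
    """Axis-aligned box of admissible interventions."""

    low: np.ndarray
    high: np.ndarray
    kind: str = "initial-state"  # or "circuit-parameters"

    def __post_init__(self):
        self.low = np.asarray(self.low, dtype=float)
        self.high = np.asarray(self.high, dtype=float)
        if self.low.shape != self.high.shape:
            raise ValueError("low/high shape mismatch")
        if np.any(self.low > self.high):
            raise ValueError("low must be <= high elementwise")

    @property
    def dim(self) -> int:
        return self.low.size

    def sample(self, rng: np.random.Generator, size: Optional[int] = None) -> np.ndarray:
        if size is None:
            return rng.uniform(self.low, self.high)
        return rng.uniform(self.low, self.high, size=(size, self.dim))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.low, self.high)


@dataclass
class BehaviorSpace:
    """Descriptor encoder specification.

    kind = "endpoint"   : (y_i(T), y_j(T)) for the node pair ``nodes``
    kind = "fourier"    : first ``n_bins`` amplitude bins of the DFT of the
                          settled half-window of node ``nodes[0]``; catalog
                          distance is the mean absolute spectral difference
    kind = "oscillation": (A, omega, b) of node ``nodes[0]``
    """

    kind: str = "endpoint"
    nodes: Tuple[int, ...] = (0, 1)
    n_bins: int = FOURIER_BINS

    @property
    def dim(self) -> int:
        if self.kind == "endpoint":
            return 2
        if self.kind == "fourier":
            return self.n_bins
        if self.kind == "oscillation":
            return 3
        raise ValueError(f"unknown behavior space kind {self.kind!r}")


@dataclass
class BehaviorDescriptor:
    values: np.ndarray
    space_id: str = "endpoint"
    missing: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def build_intervention_space(default_traj: Trajectory, r: float = 20.0) -> InterventionSpace:
    """Box around the default time course: [min/r, r*max] per node.

    The default scale factor r=20 brackets the values each node visits in
    the unperturbed reference rollout.
    """
    if not default_traj.valid:
        raise ValueError("default trajectory is invalid; cannot derive bounds")
    lo = default_traj.states.min(axis=0) / r
    hi = default_traj.states.max(axis=0) * r
    lo = np.maximum(lo, 0.0)
    return InterventionSpace(lo, hi, kind="initial-state")


def _half_window(traj: Trajectory, node: int) -> np.ndarray:
    """Second half [T/2, T] of one node's signal (transients excluded)."""
    y = traj.states[:, node]
    return y[(y.shape[0] - 1) // 2 :]


def encode_endpoint(traj: Trajectory, nodes: Sequence[int]) -> BehaviorDescriptor:
    i, j = nodes
    if not traj.valid:
        return BehaviorDescriptor(np.full(2, np.nan), "endpoint", missing=True)
    return BehaviorDescriptor(traj.states[-1, [i, j]].copy(), "endpoint")


def encode_fourier(traj: Trajectory, node: int, n_bins: int = FOURIER_BINS) -> BehaviorDescriptor:
    """Amplitude spectrum (unnormalized DFT) of the settled half-window."""
    if not traj.valid:
        return BehaviorDescriptor(np.full(n_bins, np.nan), "fourier", missing=True)
    y = _half_window(traj, node)
    amp = np.abs(np.fft.rfft(y))
    out = np.zeros(n_bins)
    m = min(n_bins, amp.size)
    out[:m] = amp[:m]
    return BehaviorDescriptor(out, "fourier")


def extract_oscillation_descriptor(traj: Trajectory, node: int) -> BehaviorDescriptor:
    """(A, omega, b) on the settled half-window.

    A is half the peak-to-peak range; omega (Hz, cycles per second on the
    dt grid) is the location of the maximal non-DC amplitude bin, refined
    by parabolic interpolation on a Hann-windowed spectrum (ties broken
    toward lower frequency); b is the signal mean, taken over an integer
    number of estimated periods to suppress partial-cycle bias.  A
    constant signal reports omega = 0 by convention.
    """
    if not traj.valid:
        return BehaviorDescriptor(np.full(3, np.nan), "oscillation", missing=True)
    y = _half_window(traj, node)
    b = float(y.mean())
    A = float((y.max() - y.min()) / 2.0)
    dt = float(traj.times[1] - traj.times[0]) if traj.times.size > 1 else 1.0
    if A == 0.0 or y.size < 8:
        return BehaviorDescriptor(np.array([A, 0.0, b]), "oscillation")
    yc = (y - y.mean()) * np.hanning(y.size)
    amp = np.abs(np.fft.rfft(yc))
    k = 1 + int(np.argmax(amp[1:]))
    kf = float(k)
    if 1 <= k < amp.size - 1 and amp[k] > 0:
        with np.errstate(divide="ignore"):
            la, lb, lc = np.log(amp[k - 1 : k + 2])
        denom = la - 2.0 * lb + lc
        if np.isfinite(denom) and denom < 0:
            kf = k + 0.5 * (la - lc) / denom
    omega = kf / (y.size * dt)
    n_per = int(np.floor((y.size - 1) * dt * omega))
    if n_per >= 1:
        m = int(round(n_per / omega / dt)) + 1
        if 2 <= m <= y.size:
            b = float(y[:m].mean())
    return BehaviorDescriptor(np.array([A, omega, b]), "oscillation")


def encode(space: BehaviorSpace, traj: Trajectory) -> BehaviorDescriptor:
    """Dispatch a trajectory through the encoder ``space`` describes."""
    if space.kind == "endpoint":
        return encode_endpoint(traj, space.nodes)
    if space.kind == "fourier":
        return encode_fourier(traj, space.nodes[0], space.n_bins)
    if space.kind == "oscillation":
        return extract_oscillation_descriptor(traj, space.nodes[0])
    raise ValueError(f"unknown behavior space kind {space.kind!r}")


def descriptor_distances(space: BehaviorSpace, Z: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Distances from each row of Z to z under the space's metric.

    Euclidean for endpoint/oscillation spaces; mean absolute spectral
    difference for Fourier spaces.
    """
    Z = np.atleast_2d(Z)
    if space.kind == "fourier":
        return np.mean(np.abs(Z - z), axis=1)
    return np.sqrt(np.sum((Z - z) ** 2, axis=1))
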
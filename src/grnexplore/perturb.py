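"""Trajectory-conditioned perturbation families.

Three stressor families probe the robustness of a goal-reaching rollout,
each *conditioned* on the unperturbed reference trajectory so magnitudes
are meaningful for the system at hand:

* noise  — i.i.d. Gaussian kicks on all nodes, std ``sigma_n`` times the
  per-node extent of the reference, applied every ``p_n`` seconds within a
  window (default 80 s from t=0);
* push   — ``n_p`` instantaneous displacements of the behavior-plane
  coordinates at uniformly sampled transient times, each of magnitude
  ``m_p`` times the extent, in a uniformly random direction;
* wall   — ``n_w`` hard barrier segments of length ``l_w`` times the plane
  extent, centered at uniform fractions of the reference path length and
  oriented perpendicular to the local motion direction.

The default evaluation grid has s=18 sub-families (6 per family, including
the duplicated noise pair (0.005, 5) of the reference protocol) with r=3
random replicates each, for P = 54 perturbations per goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _kernels
from .dynamics import (
    GeneCircuitModel,
    OdeModel,
    RolloutConfig,
    Trajectory,
    simulate_gene_circuit,
    simulate_ode,
)

__all__ = [
    "PerturbationSpec",
    "PerturbationGrid",
    "make_default_grid",
    "sample_perturbation",
    "apply_perturbation",
    "settling_time",
]

NOISE_SUBFAMILIES = [
    (0.001, 5.0),
    (0.005, 5.0),
    (0.1, 5.0),
    (0.005, 10.0),
    (0.005, 5.0),
    (0.005, 1.0),
]
# printed sextuples read as magnitudes {0.05,0.1,0.15} with one event and
# counts {1,2,3} with magnitude 0.1 (fractional counts are meaningless)
PUSH_SUBFAMILIES = [(0.05, 1), (0.1, 1), (0.15, 1), (0.1, 1), (0.1, 2), (0.1, 3)]
WALL_SUBFAMILIES = [(0.05, 1), (0.1, 1), (0.15, 1), (0.1, 1), (0.1, 2), (0.1, 3)]

DEFAULT_NOISE_WINDOW = 80.0


@dataclass
class PerturbationSpec:
    """One realized perturbation instance (replayable)."""

    family: str  # noise | push | wall
    params: dict
    coords: Tuple[int, ...]
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_vectors: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    walls: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    reference_extent: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "params": self.params,
                "coords": list(self.coords),
                "event_times": np.asarray(self.event_times).tolist(),
                "event_vectors": np.asarray(self.event_vectors).tolist(),
                "walls": np.asarray(self.walls).tolist(),
                "reference_extent": np.asarray(self.reference_extent).tolist(),
                "degenerate": self.degenerate,
            }
        )

    @staticmethod
    def from_json(s: str) -> "PerturbationSpec":
        d = json.loads(s)
        ev = np.asarray(d["event_vectors"], dtype=float)
        if ev.size == 0:
            ev = ev.reshape(0, 0)
        walls = np.asarray(d["walls"], dtype=float)
        if walls.size == 0:
            walls = walls.reshape(0, 4)
        return PerturbationSpec(
            family=d["family"],
            params=d["params"],
            coords=tuple(d["coords"]),
            event_times=np.asarray(d["event_times"], dtype=float),
            event_vectors=ev,
            walls=walls,
            reference_extent=np.asarray(d["reference_extent"], dtype=float),
            degenerate=d["degenerate"],
        )


@dataclass
class PerturbationGrid:
    subfamilies: List[Tuple[str, dict]]
    replicates: int = 3

    @property
    def n_subfamilies(self) -> int:
        return len(self.subfamilies)

    @property
    def total(self) -> int:
        return self.n_subfamilies * self.replicates


def make_default_grid() -> PerturbationGrid:
    """The s=18 sub-family grid (6 noise, 6 push, 6 wall), r=3."""
    subs: List[Tuple[str, dict]] = []
    for sn, pn in NOISE_SUBFAMILIES:
        subs.append(("noise", {"sigma": sn, "period": pn}))
    for mp, np_ in PUSH_SUBFAMILIES:
        subs.append(("push", {"magnitude": mp, "count": np_}))
    for lw, nw in WALL_SUBFAMILIES:
        subs.append(("wall", {"length": lw, "count": nw}))
    return PerturbationGrid(subs, replicates=3)


def settling_time(traj: Trajectory, frac: float = 0.02) -> float:
    """First time from which the state stays within frac of the total move.

    Defined as the first t with |y(t) - y(T)| < frac * |y(T) - y(0)| (vector
    norms); falls back to T if the trajectory never settles.
    """
    yT = traj.states[-1]
    scale = float(np.linalg.norm(yT - traj.states[0]))
    if scale == 0.0:
        return 0.0
    d = np.linalg.norm(traj.states - yT, axis=1)
    idx = np.nonzero(d < frac * scale)[0]
    return float(traj.times[idx[0]]) if idx.size else float(traj.times[-1])


def _unit_vector(dim: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=dim)
    nrm = np.linalg.norm(v)
    while nrm == 0.0:
        v = rng.normal(size=dim)
        nrm = np.linalg.norm(v)
    return v / nrm


def sample_perturbation(
    family: str,
    params: dict,
    reference: Trajectory,
    coords: Sequence[int],
    rng: np.random.Generator,
    noise_window: float = DEFAULT_NOISE_WINDOW,
) -> PerturbationSpec:
    """Sample one concrete perturbation conditioned on ``reference``."""
    if not reference.valid:
        raise ValueError("reference trajectory is invalid")
    coords = tuple(coords)
    n = reference.n
    extent = reference.states.max(axis=0) - reference.states.min(axis=0)
    degenerate = bool(np.all(extent == 0.0))
    T = reference.T

    if family == "noise":
        period = float(params["period"])
        window = float(params.get("window", noise_window))
        times = np.arange(period, min(window, T) + 1e-9, period)
        vecs = rng.normal(size=(times.size, n)) * (params["sigma"] * extent)
        return PerturbationSpec(
            "noise", dict(params), coords, times, vecs,
            reference_extent=extent, degenerate=degenerate,
        )

    if family == "push":
        count = int(params["count"])
        t_settle = max(settling_time(reference), reference.times[1] if reference.times.size > 1 else 0.0)
        times = np.sort(rng.uniform(0.0, t_settle, size=count))
        vecs = np.zeros((count, n))
        for k in range(count):
            u = _unit_vector(len(coords), rng)
            vecs[k, list(coords)] = params["magnitude"] * extent[list(coords)] * u
        return PerturbationSpec(
            "push", dict(params), coords, times, vecs,
            reference_extent=extent, degenerate=degenerate,
        )

    if family == "wall":
        count = int(params["count"])
        plane = reference.states[:, list(coords)]
        seg = np.diff(plane, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        total = cum[-1]
        scale = float(np.linalg.norm(extent[list(coords)]))
        half = 0.5 * params["length"] * scale
        walls = np.zeros((count, 4))
        fracs = rng.uniform(0.0, 1.0, size=count)
        for k, f in enumerate(fracs):
            if total == 0.0 or half == 0.0:
                c = plane[0]
                d = np.array([1.0, 0.0])
            else:
                target = f * total
                i = min(int(np.searchsorted(cum, target, side="right")) - 1, seg.shape[0] - 1)
                i = max(i, 0)
                rem = target - cum[i]
                d = seg[i] / seglen[i] if seglen[i] > 0 else np.array([1.0, 0.0])
                c = plane[i] + rem * d
            perp = np.array([-d[1], d[0]])
            walls[k, :2] = c - half * perp
            walls[k, 2:] = c + half * perp
        return PerturbationSpec(
            "wall", dict(params), coords,
            walls=walls, reference_extent=extent, degenerate=degenerate,
        )

    raise ValueError(f"unknown perturbation family {family!r}")


def _events_to_steps(spec: PerturbationSpec, config: RolloutConfig):
    steps = np.round(np.asarray(spec.event_times) / config.dt).astype(np.int64)
    steps = np.clip(steps, 1, config.n_steps)
    order = np.argsort(steps, kind="stable")
    vecs = np.asarray(spec.event_vectors, dtype=float)
    if vecs.size == 0:
        vecs = np.zeros((0, 1))
    return steps[order], vecs[order]


def apply_perturbation(
    model: Union[GeneCircuitModel, OdeModel],
    y0: np.ndarray,
    spec: PerturbationSpec,
    config: Optional[RolloutConfig] = None,
) -> Trajectory:
    """Re-run a rollout from the same initial state with ``spec`` active.

    Noise/push displacements are added after the scheduled step's update;
    walls act as hard constraints in the 2-D behavior plane (crossing steps
    are projected back, sliding along the wall is allowed).
    """
    config = config or RolloutConfig()
    y0 = np.asarray(y0, dtype=float)
    wall_i, wall_j = (spec.coords + (0, 1))[:2]
    walls = np.asarray(spec.walls, dtype=float).reshape(-1, 4)
    wall_eps = 1e-9 * max(1.0, float(np.max(np.abs(spec.reference_extent))) if spec.reference_extent.size else 1.0)

    if isinstance(model, GeneCircuitModel):
        steps, vecs = _events_to_steps(spec, config)
        if vecs.shape[1] != model.n:
            vecs = np.zeros((steps.size, model.n))
        a = config.dt / model.tau
        clamp_vals = np.full(config.n_steps + 1, np.nan)
        states = _kernels.gene_circuit_rollout_perturbed(
            model.W, model.B, a, y0, config.n_steps,
            steps, vecs, walls, wall_i, wall_j, wall_eps, -1, clamp_vals,
        )
        return Trajectory.from_states(config.times(), states)

    # generic ODE path: hook-based displacements + python wall projection
    steps, vecs = _events_to_steps(spec, config)
    ev = {int(s): vecs[k] for k, s in enumerate(steps)}
    prev_plane = [np.array([y0[wall_i], y0[wall_j]], dtype=float)]

    def hook(step, t, y):
        y = y.copy()
        if step in ev and ev[step].size == y.size:
            y = y + ev[step]
        if walls.shape[0] > 0 and np.all(np.isfinite(y)):
            px, py = _kernels._resolve_walls(
                prev_plane[0][0], prev_plane[0][1], y[wall_i], y[wall_j], walls, wall_eps
            )
            y[wall_i] = px
            y[wall_j] = py
        prev_plane[0] = np.array([y[wall_i], y[wall_j]])
        return y

    return simulate_ode(model, y0, config, hooks=[hook])
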
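"""Stimuli-based setpoint-reset intervention search.

Given a set of undesired steady states, find a stepwise clamp schedule on
one node (default: a new clamp level every 10 s for 100 s, then free
evolution) that drives all of them to a target point in the behavior
plane, robustly under the perturbation battery.  Candidate clamp levels
are drawn log-uniformly in [0.1x, 10x] of the start states' clamp-node
level, and the schedule with the lowest mean endpoint-to-target distance
wins; plain random search suffices on the fixtures this targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import _kernels
from .dynamics import (
    GeneCircuitModel,
    OdeModel,
    RolloutConfig,
    Trajectory,
    simulate_ode,
)
from .perturb import PerturbationGrid, apply_perturbation, sample_perturbation

__all__ = ["ClampSchedule", "evaluate_reset", "search_reset_intervention"]


@dataclass
class ClampSchedule:
    node: int
    values: np.ndarray
    interval: float = 10.0
    duration: float = 100.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n_expected = int(round(self.duration / self.interval))
        if self.values.size != n_expected:
            raise ValueError(
                f"duration/interval = {n_expected} values expected, got {self.values.size}"
            )
        if np.any(self.values < 0):
            raise ValueError("clamp values must be nonnegative")

    def value_at(self, t: float) -> Optional[float]:
        """Clamp level active at time t, or None outside the window."""
        if t >= self.duration:
            return None
        k = min(int(t // self.interval), self.values.size - 1)
        return float(self.values[k])

    def per_step_values(self, config: RolloutConfig) -> np.ndarray:
        """(n_steps+1,) clamp levels, NaN where the clamp is inactive."""
        times = config.times()
        out = np.full(times.size, np.nan)
        active = times < self.duration
        idx = np.minimum((times[active] // self.interval).astype(int), self.values.size - 1)
        out[active] = self.values[idx]
        return out


def _clamped_rollout(
    model: Union[GeneCircuitModel, OdeModel],
    y0: np.ndarray,
    schedule: ClampSchedule,
    config: RolloutConfig,
    spec=None,
) -> Trajectory:
    clamp_vals = schedule.per_step_values(config)
    if isinstance(model, GeneCircuitModel):
        if spec is None:
            steps = np.zeros(0, dtype=np.int64)
            vecs = np.zeros((0, model.n))
            walls = np.zeros((0, 4))
            ci, cj = 0, 1 if model.n > 1 else 0
            eps = 1e-9
        else:
            from .perturb import _events_to_steps

            steps, vecs = _events_to_steps(spec, config)
            if vecs.shape[1] != model.n:
                vecs = np.zeros((steps.size, model.n))
            walls = np.asarray(spec.walls, dtype=float).reshape(-1, 4)
            ci, cj = (spec.coords + (0, 1))[:2]
            eps = 1e-9
        a = config.dt / model.tau
        states = _kernels.gene_circuit_rollout_perturbed(
            model.W, model.B, a, np.asarray(y0, dtype=float), config.n_steps,
            steps, vecs, walls, ci, cj, eps, schedule.node, clamp_vals,
        )
        return Trajectory.from_states(config.times(), states)

    ev = {}
    if spec is not None:
        from .perturb import _events_to_steps

        steps, vecs = _events_to_steps(spec, config)
        ev = {int(s): vecs[k] for k, s in enumerate(steps)}

    def hook(step, t, y):
        y = y.copy()
        if step in ev and ev[step].size == y.size:
            y = y + ev[step]
        v = schedule.value_at(t)
        if v is not None:
            y[schedule.node] = v
        return y

    return simulate_ode(model, y0, config, hooks=[hook])


def evaluate_reset(
    model: Union[GeneCircuitModel, OdeModel],
    start_states: Sequence[np.ndarray],
    schedule: ClampSchedule,
    target: np.ndarray,
    coords: Sequence[int] = (0, 1),
    config: Optional[RolloutConfig] = None,
    battery: Optional[PerturbationGrid] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean distance of post-intervention endpoints to the target setpoint.

    With ``battery`` given, each start state is additionally re-run under
    every sampled perturbation of the grid (conditioned on its clamped,
    unperturbed trajectory); invalid rollouts are skipped and counted out.
    Without a battery the score is deterministic.
    """
    config = config or RolloutConfig()
    target = np.asarray(target, dtype=float)
    coords = tuple(coords)
    dists = []
    for y0 in start_states:
        ref = _clamped_rollout(model, np.asarray(y0, dtype=float), schedule, config)
        if ref.valid:
            dists.append(float(np.linalg.norm(ref.states[-1, list(coords)] - target)))
        if battery is not None:
            if rng is None:
                raise ValueError("battery evaluation needs an rng")
            for family, params in battery.subfamilies:
                for _ in range(battery.replicates):
                    spec = sample_perturbation(family, params, ref, coords, rng)
                    traj = _clamped_rollout(model, np.asarray(y0, dtype=float), schedule, config, spec)
                    if traj.valid:
                        dists.append(
                            float(np.linalg.norm(traj.states[-1, list(coords)] - target))
                        )
    if not dists:
        return float("inf")
    return float(np.mean(dists))


def search_reset_intervention(
    model: Union[GeneCircuitModel, OdeModel],
    start_states: Sequence[np.ndarray],
    target: np.ndarray,
    node: int,
    candidate_count: int,
    rng: np.random.Generator,
    coords: Sequence[int] = (0, 1),
    config: Optional[RolloutConfig] = None,
    interval: float = 10.0,
    duration: float = 100.0,
    battery: Optional[PerturbationGrid] = None,
) -> ClampSchedule:
    """Random search over clamp schedules; returns the argmin-score one.

    Clamp levels are sampled log-uniformly in [0.1x, 10x] of the mean
    clamp-node level of the start states ("near the current steady
    states").
    """
    if candidate_count < 1:
        raise ValueError("candidate_count must be >= 1")
    config = config or RolloutConfig()
    n_vals = int(round(duration / interval))
    base = float(np.mean([abs(s[node]) for s in start_states]))
    if base == 0.0:
        base = 1.0
    best, best_score = None, np.inf
    for _ in range(candidate_count):
        values = base * 10.0 ** rng.uniform(-1.0, 1.0, size=n_vals)
        schedule = ClampSchedule(node, values, interval, duration)
        score = evaluate_reset(
            model, start_states, schedule, target, coords, config, battery, rng
        )
        if score < best_score:
            best_score, best = score, schedule
    return best
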
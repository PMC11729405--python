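"""Random-search and curiosity-driven (IMGEP) exploration loops.

The intrinsically-motivated goal exploration process (IMGEP) bootstraps
with ``N_init`` uniform interventions, then iterates: sample a goal
uniformly in the bounding box of already-reached goals scaled by 1.3,
pick the intervention whose reached goal is nearest the sampled goal, and
mutate it with a per-dimension Gaussian step of std 0.1 * (high - low),
clipped to the intervention box.  The result is a behavioral catalog
H = {(i_k, o_k, z_k)} to which robustness tests later attach perturbation
records (u_p, o_p, z_p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from .dynamics import (
    GeneCircuitModel,
    OdeModel,
    RolloutConfig,
    Trajectory,
    simulate_gene_circuit,
    simulate_ode,
)
from .perturb import PerturbationSpec
from .spaces import BehaviorSpace, InterventionSpace, descriptor_distances, encode

__all__ = [
    "System",
    "PerturbationRecord",
    "BehavioralCatalog",
    "ImgepConfig",
    "run_random_search",
    "sample_goal",
    "select_intervention_for_goal",
    "run_imgep",
]

GOAL_BOX_FLOOR = 1e-6


@dataclass
class System:
    """A (model, intervention space, behavior space) tuple plus rollout config.

    For ``intervention_space.kind == "initial-state"`` the intervention is
    the initial state vector; for ``"circuit-parameters"`` it is the
    concatenation (y0, W.flat, B) applied to a gene-circuit template whose
    tau is kept.
    """

    model: Union[GeneCircuitModel, OdeModel]
    intervention_space: InterventionSpace
    behavior_space: BehaviorSpace
    config: RolloutConfig = field(default_factory=RolloutConfig)
    store_trajectories: bool = True

    def interpret(self, intervention: np.ndarray):
        """Return (model, y0) realized for one intervention vector."""
        if self.intervention_space.kind == "initial-state":
            return self.model, np.asarray(intervention, dtype=float)
        if not isinstance(self.model, GeneCircuitModel):
            raise ValueError("circuit-parameters interventions need a gene circuit")
        n = self.model.n
        x = np.asarray(intervention, dtype=float)
        y0 = x[:n]
        W = x[n : n + n * n].reshape(n, n)
        B = x[n + n * n :]
        return GeneCircuitModel(W, B, self.model.tau), y0

    def rollout(self, intervention: np.ndarray) -> Trajectory:
        model, y0 = self.interpret(intervention)
        if isinstance(model, GeneCircuitModel):
            return simulate_gene_circuit(model, y0, self.config)
        return simulate_ode(model, y0, self.config)

    def encode(self, traj: Trajectory) -> np.ndarray:
        return encode(self.behavior_space, traj).values


@dataclass
class PerturbationRecord:
    spec: PerturbationSpec
    descriptor: np.ndarray
    valid: bool
    trajectory: Optional[Trajectory] = None


class BehavioralCatalog:
    """Append-only history of (intervention, observation, behavior) tuples."""

    def __init__(self, space: BehaviorSpace, provenance: Optional[dict] = None):
        self.space = space
        self.interventions: List[np.ndarray] = []
        self.descriptors: List[np.ndarray] = []
        self.valid: List[bool] = []
        self.trajectories: List[Optional[Trajectory]] = []
        self.perturbations: List[List[PerturbationRecord]] = []
        self.provenance = provenance or {}
        # incremental buffer of valid finite descriptors (hot path of the
        # IMGEP nearest-goal queries)
        self._vbuf: Optional[np.ndarray] = None
        self._vcount = 0
        self._vidx: List[int] = []

    def __len__(self) -> int:
        return len(self.interventions)

    def append(
        self,
        intervention: np.ndarray,
        descriptor: np.ndarray,
        valid: bool,
        trajectory: Optional[Trajectory] = None,
    ) -> int:
        descriptor = np.asarray(descriptor, dtype=float)
        self.interventions.append(np.asarray(intervention, dtype=float))
        self.descriptors.append(descriptor)
        self.valid.append(bool(valid))
        self.trajectories.append(trajectory)
        self.perturbations.append([])
        k = len(self.interventions) - 1
        if valid and np.all(np.isfinite(descriptor)):
            if self._vbuf is None:
                self._vbuf = np.empty((16, descriptor.size))
            elif self._vcount == self._vbuf.shape[0]:
                grown = np.empty((2 * self._vbuf.shape[0], self._vbuf.shape[1]))
                grown[: self._vcount] = self._vbuf
                self._vbuf = grown
            self._vbuf[self._vcount] = descriptor
            self._vidx.append(k)
            self._vcount += 1
        return k

    def intervention_matrix(self) -> np.ndarray:
        return np.array(self.interventions)

    def descriptor_matrix(self) -> np.ndarray:
        return np.array(self.descriptors)

    def valid_mask(self) -> np.ndarray:
        return np.array(self.valid, dtype=bool)

    def valid_descriptors(self) -> Tuple[np.ndarray, np.ndarray]:
        """(indices, descriptor rows) of valid records with finite descriptors."""
        if self._vcount == 0:
            return np.zeros(0, dtype=int), np.zeros((0, self.space.dim))
        return np.asarray(self._vidx), self._vbuf[: self._vcount]

    def nearest_valid(self, goal: np.ndarray) -> int:
        """Catalog index of the valid record nearest to ``goal`` in Z."""
        idx, Z = self.valid_descriptors()
        if idx.size == 0:
            raise ValueError("catalog has no valid records")
        d = descriptor_distances(self.space, Z, np.asarray(goal, dtype=float))
        return int(idx[np.argmin(d)])


@dataclass
class ImgepConfig:
    N: int = 450
    N_init: Optional[int] = None  # default: 10% of N
    box_scale: float = 1.3
    step_frac: float = 0.1

    def resolved_n_init(self) -> int:
        n0 = self.N_init if self.N_init is not None else max(1, round(0.1 * self.N))
        if not 1 <= n0 <= self.N:
            raise ValueError("need 1 <= N_init <= N")
        return n0


def _record(system: System, catalog: BehavioralCatalog, intervention: np.ndarray) -> None:
    traj = system.rollout(intervention)
    z = system.encode(traj)
    valid = traj.valid and bool(np.all(np.isfinite(z)))
    catalog.append(
        intervention, z, valid, traj if system.store_trajectories else None
    )


def run_random_search(
    system: System, N: int, rng: np.random.Generator
) -> BehavioralCatalog:
    """Uniform screening: N interventions i ~ U(I)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    catalog = BehavioralCatalog(system.behavior_space, {"strategy": "random", "N": N})
    for _ in range(N):
        _record(system, catalog, system.intervention_space.sample(rng))
    return catalog


def sample_goal(
    catalog: BehavioralCatalog, box_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draw in the reached-goal bounding box scaled about its center.

    Degenerate axes (a single reached goal, or zero spread) are floored at
    1e-6 of the axis scale so the first goal-directed iteration is defined.
    """
    _, Z = catalog.valid_descriptors()
    if Z.shape[0] == 0:
        raise ValueError("no valid records yet; increase N_init")
    lo = Z.min(axis=0)
    hi = Z.max(axis=0)
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo) * box_scale
    floor = GOAL_BOX_FLOOR * np.maximum(1.0, np.abs(center))
    half = np.maximum(half, floor)
    return rng.uniform(center - half, center + half)


def select_intervention_for_goal(
    goal: np.ndarray,
    catalog: BehavioralCatalog,
    space: InterventionSpace,
    step_frac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Nearest reached goal's intervention plus a local Gaussian step."""
    k = catalog.nearest_valid(goal)
    base = catalog.interventions[k]
    step = rng.normal(0.0, 1.0, size=space.dim) * step_frac * (space.high - space.low)
    return space.clip(base + step)


def run_imgep(
    system: System, config: ImgepConfig, rng: np.random.Generator
) -> BehavioralCatalog:
    """Curiosity-driven exploration with budget ``config.N``.

    Three named RNG substreams (bootstrap, goal sampling, policy steps) are
    spawned from ``rng`` so each component is independently reproducible.
    With N_init = N the loop degenerates to random search on the bootstrap
    stream.
    """
    n_init = config.resolved_n_init()
    boot_rng, goal_rng, step_rng = rng.spawn(3)
    catalog = BehavioralCatalog(
        system.behavior_space,
        {"strategy": "imgep", "N": config.N, "N_init": n_init,
         "box_scale": config.box_scale, "step_frac": config.step_frac},
    )
    for _ in range(n_init):
        _record(system, catalog, system.intervention_space.sample(boot_rng))
    for _ in range(config.N - n_init):
        if catalog._vcount == 0:
            _record(system, catalog, system.intervention_space.sample(boot_rng))
            continue
        goal = sample_goal(catalog, config.box_scale, goal_rng)
        intervention = select_intervention_for_goal(
            goal, catalog, system.intervention_space, config.step_frac, step_rng
        )
        _record(system, catalog, intervention)
    return catalog
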
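"""Robustness battery, sensitivity scoring and versatility-robustness curves.

Sensitivity of one goal state z is the mean, over the perturbation
battery, of the Euclidean displacement of the perturbed endpoint z_p from
z, normalized by the extent of the unperturbed trajectory in the behavior
plane (Euclidean norm of the per-axis ranges).  Low sensitivity = robust
goal.  The versatility-robustness curve reports, for each sensitivity
threshold, the threshold coverage of the goals whose mean wall sensitivity
is below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .explore import BehavioralCatalog, PerturbationRecord, System
from .metrics import CoverageConfig, threshold_coverage
from .perturb import PerturbationGrid, apply_perturbation, sample_perturbation
from .spaces import encode

__all__ = [
    "SensitivityEntry",
    "SensitivityReport",
    "select_representative_subset",
    "run_robustness_battery",
    "compute_sensitivity",
    "versatility_robustness_curve",
]


def select_representative_subset(
    catalog: BehavioralCatalog,
    K: Optional[int] = None,
    draws: int = 500,
    epsilon: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sample K-subsets of the valid records ``draws`` times, keep the most
    diverse one (maximal threshold coverage).  Default K = N/10.
    """
    rng = rng or np.random.default_rng()
    idx, Z = catalog.valid_descriptors()
    if K is None:
        K = max(1, len(catalog) // 10)
    if K > idx.size:
        raise ValueError(f"K={K} exceeds the {idx.size} valid records")
    if K == idx.size:
        return idx.copy()
    box = np.vstack([Z.min(axis=0), Z.max(axis=0)])
    cfg = CoverageConfig(epsilon=epsilon, box=box, grid_resolution=500)
    best, best_cov = None, -1.0
    for _ in range(draws):
        pick = rng.choice(idx.size, size=K, replace=False)
        cov = threshold_coverage(Z[pick], cfg)
        if cov > best_cov:
            best_cov, best = cov, pick
    return idx[np.sort(best)]


def run_robustness_battery(
    system: System,
    catalog: BehavioralCatalog,
    subset: Sequence[int],
    grid: PerturbationGrid,
    rng: np.random.Generator,
    store_trajectories: bool = False,
) -> BehavioralCatalog:
    """Attach P = s*r perturbed rollouts to each selected record.

    Each perturbation is conditioned on the record's unperturbed
    trajectory and re-runs the rollout from the same intervention.
    """
    coords = tuple(system.behavior_space.nodes[:2])
    for k in subset:
        reference = catalog.trajectories[k]
        if reference is None:
            reference = system.rollout(catalog.interventions[k])
        if not reference.valid:
            continue
        model, y0 = system.interpret(catalog.interventions[k])
        for family, params in grid.subfamilies:
            for _ in range(grid.replicates):
                spec = sample_perturbation(family, params, reference, coords, rng)
                traj = apply_perturbation(model, y0, spec, system.config)
                z_p = encode(system.behavior_space, traj).values
                catalog.perturbations[k].append(
                    PerturbationRecord(
                        spec, z_p, traj.valid and bool(np.all(np.isfinite(z_p))),
                        traj if store_trajectories else None,
                    )
                )
    return catalog


@dataclass
class SensitivityEntry:
    index: int
    mean: float
    per_family: Dict[str, float]
    n_invalid: int
    absolute_units: bool = False  # True when the reference extent was zero


@dataclass
class SensitivityReport:
    entries: List[SensitivityEntry] = field(default_factory=list)

    def median(self) -> float:
        return float(np.median([e.mean for e in self.entries])) if self.entries else np.nan


def _behavior_extent(system: System, catalog: BehavioralCatalog, k: int) -> float:
    traj = catalog.trajectories[k]
    if traj is None:
        traj = system.rollout(catalog.interventions[k])
    plane = traj.states[:, list(system.behavior_space.nodes[:2])]
    ranges = plane.max(axis=0) - plane.min(axis=0)
    return float(np.linalg.norm(ranges))


def compute_sensitivity(
    system: System, catalog: BehavioralCatalog, k: int
) -> SensitivityEntry:
    """Mean normalized endpoint displacement for record k's battery.

    Invalid perturbed rollouts are excluded from the mean and counted
    separately (a failed rollout is a solver artifact, not an endpoint).
    Zero-extent references report absolute distances with a flag.
    """
    records = catalog.perturbations[k]
    z = np.asarray(catalog.descriptors[k], dtype=float)
    extent = _behavior_extent(system, catalog, k)
    absolute = extent == 0.0
    denom = 1.0 if absolute else extent
    fam_d: Dict[str, List[float]] = {}
    dists, n_invalid = [], 0
    for rec in records:
        if not rec.valid:
            n_invalid += 1
            continue
        d = float(np.linalg.norm(np.asarray(rec.descriptor) - z)) / denom
        dists.append(d)
        fam_d.setdefault(rec.spec.family, []).append(d)
    if not dists:
        raise ValueError(f"record {k} has no valid perturbed rollouts")
    return SensitivityEntry(
        index=k,
        mean=float(np.mean(dists)),
        per_family={f: float(np.mean(v)) for f, v in fam_d.items()},
        n_invalid=n_invalid,
        absolute_units=absolute,
    )


def versatility_robustness_curve(
    system: System,
    catalog: BehavioralCatalog,
    subset: Sequence[int],
    thresholds: Sequence[float],
    epsilon: float = 0.05,
    family: str = "wall",
) -> List[Tuple[float, float]]:
    """(threshold, robust coverage) pairs; monotone nondecreasing.

    A goal counts as robustly achieved at threshold x when its mean
    sensitivity to the chosen family (walls by default) is <= x.
    """
    entries = [compute_sensitivity(system, catalog, k) for k in subset]
    Z = catalog.descriptor_matrix()[list(subset)]
    _, allZ = catalog.valid_descriptors()
    box = np.vstack([allZ.min(axis=0), allZ.max(axis=0)])
    cfg = CoverageConfig(epsilon=epsilon, box=box, grid_resolution=500)
    out = []
    for x in thresholds:
        keep = [
            i
            for i, e in enumerate(entries)
            if e.per_family.get(family, e.mean) <= x
        ]
        cov = threshold_coverage(Z[keep], cfg) if keep else 0.0
        out.append((float(x), cov))
    return out
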
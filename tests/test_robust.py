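from itertools import combinations

import numpy as np
import pytest

from grnexplore.dynamics import OdeModel, RolloutConfig
from grnexplore.explore import BehavioralCatalog, PerturbationRecord, System, run_random_search
from grnexplore.metrics import CoverageConfig, threshold_coverage
from grnexplore.perturb import PerturbationGrid, PerturbationSpec, make_default_grid
from grnexplore.robust import (
    compute_sensitivity,
    run_robustness_battery,
    select_representative_subset,
    versatility_robustness_curve,
)
from grnexplore.spaces import BehaviorSpace, InterventionSpace


def attractor_system(c=(0.4, 0.6), T=60.0):
    """dy/dt = -(y - c): globally attracting fixed point at c."""
    c = np.array(c)
    model = OdeModel(2, lambda y, t: -(y - c))
    space = InterventionSpace(np.zeros(2), np.ones(2))
    return System(model, space, BehaviorSpace(nodes=(0, 1)), RolloutConfig(T=T, dt=0.1))


def toy_catalog(points):
    catalog = BehavioralCatalog(BehaviorSpace())
    for p in points:
        catalog.append(np.asarray(p, dtype=float), np.asarray(p, dtype=float), True)
    return catalog


class TestRepresentativeSubset:
    def test_k_equals_n_returns_all(self, rng):
        catalog = toy_catalog(rng.uniform(0, 1, (8, 2)))
        subset = select_representative_subset(catalog, K=8, rng=rng)
        assert sorted(subset) == list(range(8))

    def test_matches_exhaustive_best_for_small_n(self, rng):
        pts = rng.uniform(0, 1, (5, 2))
        catalog = toy_catalog(pts)
        subset = select_representative_subset(catalog, K=2, draws=200, rng=rng)
        box = np.vstack([pts.min(axis=0), pts.max(axis=0)])
        cfg = CoverageConfig(epsilon=0.05, box=box, grid_resolution=500)
        best = max(
            threshold_coverage(pts[list(c)], cfg) for c in combinations(range(5), 2)
        )
        assert threshold_coverage(pts[list(subset)], cfg) == pytest.approx(best)

    def test_k_larger_than_valid_records_raises(self, rng):
        catalog = toy_catalog(rng.uniform(0, 1, (3, 2)))
        with pytest.raises(ValueError):
            select_representative_subset(catalog, K=4, rng=rng)


class TestBattery:
    def test_empty_grid_is_noop(self, rng):
        system = attractor_system()
        catalog = run_random_search(system, 3, rng)
        run_robustness_battery(system, catalog, [0, 1, 2], PerturbationGrid([], 3), rng)
        assert all(len(p) == 0 for p in catalog.perturbations)

    def test_default_grid_adds_54_records_per_goal(self, rng):
        system = attractor_system(T=20.0)
        catalog = run_random_search(system, 2, rng)
        run_robustness_battery(system, catalog, [0], make_default_grid(), rng)
        assert len(catalog.perturbations[0]) == 54
        assert len(catalog.perturbations[1]) == 0

    def test_global_attractor_absorbs_pushes(self, rng):
        system = attractor_system(T=60.0)
        catalog = run_random_search(system, 1, rng)
        grid = PerturbationGrid([("push", {"magnitude": 0.5, "count": 2})], 3)
        run_robustness_battery(system, catalog, [0], grid, rng)
        z = catalog.descriptors[0]
        for rec in catalog.perturbations[0]:
            assert np.linalg.norm(rec.descriptor - z) < 1e-3


class TestSensitivity:
    def attach(self, catalog, k, descriptors, family="push"):
        for d in descriptors:
            spec = PerturbationSpec(family=family, params={}, coords=(0, 1))
            catalog.perturbations[k].append(
                PerturbationRecord(spec, np.asarray(d, dtype=float), True)
            )

    def test_identical_endpoints_give_zero(self, rng):
        system = attractor_system()
        catalog = run_random_search(system, 1, rng)
        self.attach(catalog, 0, [catalog.descriptors[0]] * 5)
        assert compute_sensitivity(system, catalog, 0).mean == 0.0

    def test_displacement_over_extent(self, rng):
        system = attractor_system(T=60.0)
        catalog = run_random_search(system, 1, rng)
        z = catalog.descriptors[0]
        traj = catalog.trajectories[0]
        ranges = traj.states.max(axis=0) - traj.states.min(axis=0)
        extent = np.linalg.norm(ranges)
        d = 0.05
        self.attach(catalog, 0, [z + np.array([d, 0.0])])
        entry = compute_sensitivity(system, catalog, 0)
        assert entry.mean == pytest.approx(d / extent, rel=1e-9)

    def test_affine_rescaling_invariance(self, rng):
        # scaling both Z axes by c scales numerator and denominator alike
        system = attractor_system(T=60.0)
        catalog = run_random_search(system, 1, rng)
        z = catalog.descriptors[0]
        self.attach(catalog, 0, [z + np.array([0.03, -0.02])])
        base = compute_sensitivity(system, catalog, 0).mean

        c = 7.0
        catalog2 = BehavioralCatalog(BehaviorSpace())
        traj = catalog.trajectories[0]
        from grnexplore.dynamics import Trajectory

        scaled_traj = Trajectory.from_states(traj.times, c * traj.states)
        catalog2.append(catalog.interventions[0], c * z, True, scaled_traj)
        self.attach(catalog2, 0, [c * (z + np.array([0.03, -0.02]))])
        scaled = compute_sensitivity(system, catalog2, 0).mean
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_invalid_rollouts_excluded_not_imputed(self, rng):
        system = attractor_system(T=60.0)
        catalog = run_random_search(system, 1, rng)
        z = catalog.descriptors[0]
        self.attach(catalog, 0, [z + np.array([0.1, 0.0])])
        spec = PerturbationSpec(family="push", params={}, coords=(0, 1))
        catalog.perturbations[0].append(
            PerturbationRecord(spec, np.full(2, np.nan), False)
        )
        entry = compute_sensitivity(system, catalog, 0)
        assert entry.n_invalid == 1
        assert entry.mean > 0  # the NaN record did not drag the mean to 0/NaN

    def test_median_between_min_and_max(self, rng):
        system = attractor_system(T=60.0)
        catalog = run_random_search(system, 5, rng)
        means = []
        for k in range(5):
            z = catalog.descriptors[k]
            self.attach(catalog, k, [z + rng.normal(0, 0.02, 2) for _ in range(4)])
            means.append(compute_sensitivity(system, catalog, k).mean)
        assert min(means) <= np.median(means) <= max(means)


class TestVersatilityRobustness:
    def build(self, rng, sensitivities):
        system = attractor_system(T=20.0)
        catalog = run_random_search(system, len(sensitivities), rng)
        for k, s in enumerate(sensitivities):
            traj = catalog.trajectories[k]
            ranges = traj.states.max(axis=0) - traj.states.min(axis=0)
            extent = np.linalg.norm(ranges)
            z = catalog.descriptors[k]
            spec = PerturbationSpec(family="wall", params={}, coords=(0, 1))
            catalog.perturbations[k].append(
                PerturbationRecord(spec, z + np.array([s * extent, 0.0]), True)
            )
        return system, catalog

    def test_curve_monotone_and_limits(self, rng):
        system, catalog = self.build(rng, [0.01, 0.2, 0.5, 0.9])
        curve = versatility_robustness_curve(
            system, catalog, [0, 1, 2, 3], thresholds=[0.0, 0.1, 0.3, 1.0, np.inf]
        )
        covs = [c for _, c in curve]
        assert covs == sorted(covs)
        assert covs[0] == 0.0  # nothing survives threshold 0
        # threshold -> inf: plain diversity of the subset
        _, allZ = catalog.valid_descriptors()
        box = np.vstack([allZ.min(axis=0), allZ.max(axis=0)])
        cfg = CoverageConfig(epsilon=0.05, box=box, grid_resolution=500)
        assert covs[-1] == pytest.approx(threshold_coverage(allZ, cfg))
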
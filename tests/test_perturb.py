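import numpy as np
import pytest

from grnexplore.dynamics import (
    GeneCircuitModel,
    OdeModel,
    RolloutConfig,
    simulate_gene_circuit,
    simulate_ode,
)
from grnexplore.perturb import (
    NOISE_SUBFAMILIES,
    PerturbationSpec,
    apply_perturbation,
    make_default_grid,
    sample_perturbation,
)

from conftest import make_trajectory


def reference_circuit(rng=None):
    model = GeneCircuitModel(
        np.array([[2.0, -3.0], [1.0, 0.5]]), np.array([0.5, -0.5]), np.ones(2)
    )
    y0 = np.array([0.2, 0.8])
    cfg = RolloutConfig(T=100, dt=0.1)
    return model, y0, cfg, simulate_gene_circuit(model, y0, cfg)


class TestGrid:
    def test_default_grid_dimensions(self):
        grid = make_default_grid()
        assert grid.n_subfamilies == 18
        assert grid.replicates == 3
        assert grid.total == 54

    def test_noise_subfamilies_as_printed_with_duplicate(self):
        assert NOISE_SUBFAMILIES == [
            (0.001, 5.0), (0.005, 5.0), (0.1, 5.0),
            (0.005, 10.0), (0.005, 5.0), (0.005, 1.0),
        ]
        fams = [f for f, _ in make_default_grid().subfamilies]
        assert fams.count("noise") == fams.count("push") == fams.count("wall") == 6


class TestSampling:
    def test_noise_kick_std_matches_scaled_extent(self, rng):
        ref = make_trajectory(np.column_stack([np.linspace(0, 2, 100), np.linspace(0, 4, 100)]))
        kicks = []
        for _ in range(1500):
            spec = sample_perturbation("noise", {"sigma": 0.1, "period": 1.0}, ref, (0, 1), rng)
            kicks.append(spec.event_vectors)
        kicks = np.vstack(kicks)
        np.testing.assert_allclose(kicks.std(axis=0), [0.1 * 2, 0.1 * 4], rtol=0.05)

    def test_conditioning_scales_with_reference_extent(self, rng):
        base = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 1, 50)])
        s1 = sample_perturbation(
            "push", {"magnitude": 0.1, "count": 3}, make_trajectory(base), (0, 1),
            np.random.default_rng(7),
        )
        s2 = sample_perturbation(
            "push", {"magnitude": 0.1, "count": 3}, make_trajectory(2 * base), (0, 1),
            np.random.default_rng(7),
        )
        np.testing.assert_allclose(s2.event_vectors, 2 * s1.event_vectors)

    def test_same_seed_is_reproducible(self):
        ref = make_trajectory(
            np.column_stack([np.linspace(0, 1, 60), 0.5 + 0.5 * np.cos(np.linspace(0, 3, 60))])
        )
        a = sample_perturbation("wall", {"length": 0.1, "count": 2}, ref, (0, 1), np.random.default_rng(3))
        b = sample_perturbation("wall", {"length": 0.1, "count": 2}, ref, (0, 1), np.random.default_rng(3))
        assert np.array_equal(a.walls, b.walls)

    def test_degenerate_reference_flagged_with_zero_magnitude(self, rng):
        ref = make_trajectory(np.full((50, 2), 0.5))
        spec = sample_perturbation("noise", {"sigma": 0.1, "period": 5.0}, ref, (0, 1), rng)
        assert spec.degenerate
        np.testing.assert_allclose(spec.event_vectors, 0)

    def test_wall_segment_length_and_count(self, rng):
        ref = make_trajectory(np.column_stack([np.linspace(0, 1, 100), np.zeros(100)]))
        spec = sample_perturbation("wall", {"length": 0.1, "count": 3}, ref, (0, 1), rng)
        assert spec.walls.shape == (3, 4)
        lengths = np.linalg.norm(spec.walls[:, 2:] - spec.walls[:, :2], axis=1)
        np.testing.assert_allclose(lengths, 0.1 * 1.0, rtol=1e-9)  # extent norm = 1


class TestApplication:
    @pytest.mark.parametrize(
        "family,params",
        [
            ("noise", {"sigma": 0.0, "period": 5.0}),
            ("push", {"magnitude": 0.0, "count": 2}),
            ("wall", {"length": 0.0, "count": 2}),
        ],
    )
    def test_zero_magnitude_is_noop(self, family, params, rng):
        model, y0, cfg, ref = reference_circuit()
        spec = sample_perturbation(family, params, ref, (0, 1), rng)
        pert = apply_perturbation(model, y0, spec, cfg)
        np.testing.assert_allclose(pert.states, ref.states, atol=1e-7)

    def test_perturbed_rollout_reuses_initial_state(self, rng):
        model, y0, cfg, ref = reference_circuit()
        spec = sample_perturbation("push", {"magnitude": 0.2, "count": 1}, ref, (0, 1), rng)
        pert = apply_perturbation(model, y0, spec, cfg)
        np.testing.assert_allclose(pert.states[0], y0)

    def test_wall_blocks_linear_flow(self):
        # flow toward (1, 0.5) behind a full-width vertical wall at x=0.5
        model = OdeModel(2, lambda y, t: np.array([1.0 - y[0], 0.5 - y[1]]))
        cfg = RolloutConfig(T=20, dt=0.1)
        ref = simulate_ode(model, np.array([0.0, 0.5]), cfg)
        spec = PerturbationSpec(
            family="wall", params={"length": 1.0, "count": 1}, coords=(0, 1),
            walls=np.array([[0.5, -5.0, 0.5, 5.0]]),
            reference_extent=np.array([1.0, 0.0]),
        )
        pert = apply_perturbation(model, np.array([0.0, 0.5]), spec, cfg)
        assert pert.valid
        assert np.all(pert.states[:, 0] <= 0.5 + 1e-6)
        assert pert.states[-1, 0] > 0.4  # pressed up against the wall

    def test_wall_never_creates_nan_and_no_teleport(self, rng):
        for _ in range(25):
            W = rng.uniform(-10, 10, (2, 2))
            model = GeneCircuitModel(W, rng.uniform(-3, 3, 2), np.ones(2))
            y0 = rng.uniform(0, 1, 2)
            cfg = RolloutConfig(T=30, dt=0.1)
            ref = simulate_gene_circuit(model, y0, cfg)
            spec = sample_perturbation("wall", {"length": 0.5, "count": 2}, ref, (0, 1), rng)
            pert = apply_perturbation(model, y0, spec, cfg)
            assert np.all(np.isfinite(pert.states))
            steps = np.linalg.norm(np.diff(pert.states, axis=0), axis=1)
            assert steps.max() < 1.0  # continuity: no teleportation

    def test_spec_json_roundtrip(self, rng):
        _, _, _, ref = reference_circuit()
        spec = sample_perturbation("push", {"magnitude": 0.1, "count": 2}, ref, (0, 1), rng)
        back = PerturbationSpec.from_json(spec.to_json())
        np.testing.assert_allclose(back.event_vectors, spec.event_vectors)
        np.testing.assert_allclose(back.event_times, spec.event_times)
        assert back.family == spec.family
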
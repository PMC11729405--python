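import numpy as np
import pytest

from grnexplore.bench_osc import (
    OptimizerConfig,
    OscillatorTarget,
    _adam,
    _cma_es,
    _loss_and_grad,
    make_circuit_space,
    oscillation_loss,
    optimize_circuit,
    run_benchmark,
    sample_oscillator_target,
    unpack_intervention,
)
from grnexplore.dynamics import RolloutConfig
from grnexplore.spaces import InterventionSpace

from conftest import make_trajectory

FAST = RolloutConfig(T=100.0, dt=0.1)


class TestTargetSampling:
    def test_wave_support_inside_unit_interval(self, rng):
        for _ in range(2000):
            t = sample_oscillator_target(rng)
            assert 0.1 <= t.A <= 0.5
            assert t.b - t.A >= 0 and t.b + t.A <= 1
            assert 0 < t.omega < 1

    def test_omega_beta_moment(self, rng):
        omegas = [sample_oscillator_target(rng).omega for _ in range(100_000)]
        assert np.mean(omegas) == pytest.approx(2 / (2 + 8), rel=0.02)


class TestLoss:
    def test_exact_target_wave_gives_zero(self):
        target = OscillatorTarget(0.2, 0.05, 0.5)
        t = np.arange(1001) * 0.1
        traj = make_trajectory(target.wave(t))
        assert oscillation_loss(traj, 0, target) == 0.0

    def test_constant_offset_loss_is_half_amplitude_energy(self):
        # y = b vs target: L = A^2 sum cos^2 ~ A^2 M / 2
        target = OscillatorTarget(0.3, 0.0731, 0.5)
        M = 20001
        t = np.arange(M) * 0.1
        traj = make_trajectory(np.full(M, target.b))
        L = oscillation_loss(traj, 0, target)
        assert L == pytest.approx(target.A**2 * M / 2, rel=0.01)

    def test_invalid_trajectory_is_infinite(self):
        target = OscillatorTarget(0.2, 0.05, 0.5)
        traj = make_trajectory(np.array([0.1, np.nan, 0.3]))
        assert oscillation_loss(traj, 0, target) == float("inf")


class TestOptimizers:
    def test_space_dimensions(self):
        space = make_circuit_space(3)
        assert space.dim == 3 * 3 + 2 * 3  # n^2 + 2n
        y0, W, B = unpack_intervention(space.low, 3)
        assert y0.shape == (3,) and W.shape == (3, 3) and B.shape == (3,)

    def test_bptt_gradient_matches_finite_differences(self, rng):
        cfg = RolloutConfig(T=1.0, dt=0.1)  # 10-step unroll
        target = OscillatorTarget(0.2, 0.05, 0.5)
        wave = target.wave(cfg.times())
        x = rng.uniform(-0.5, 0.5, 15)
        _, g = _loss_and_grad(x, 3, cfg, wave)
        h = 1e-6
        for k in range(15):
            e = np.zeros(15)
            e[k] = h
            lp, _ = _loss_and_grad(x + e, 3, cfg, wave)
            lm, _ = _loss_and_grad(x - e, 3, cfg, wave)
            assert g[k] == pytest.approx((lp - lm) / (2 * h), rel=1e-3, abs=1e-6)

    def test_adam_solves_convex_surrogate(self, rng):
        # wiring check: minimize sum (x - c)^2 directly
        c = np.array([0.3, -0.7, 1.2])
        space = InterventionSpace(np.full(3, -2.0), np.full(3, 2.0))
        cfg = OptimizerConfig(method="adam", lr=0.05, standard_betas=True)
        x = space.sample(rng)
        m = np.zeros(3)
        v = np.zeros(3)
        b1, b2 = cfg.betas()
        for t in range(1, 2000):
            g = 2 * (x - c)
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            x = space.clip(x - cfg.lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + cfg.adam_eps))
        np.testing.assert_allclose(x, c, atol=1e-3)

    def test_adam_rollout_loss_decreases(self, rng):
        target = OscillatorTarget(0.2, 0.05, 0.5)
        space = make_circuit_space(3)
        cfg = OptimizerConfig(method="adam", budget=50)
        xs, losses = _adam(target, space, cfg, FAST, rng, 3)
        assert len(losses) == 50
        assert min(losses) <= losses[0]

    def test_cma_es_minimizes_sphere(self, rng):
        space = InterventionSpace(np.full(4, -3.0), np.full(4, 3.0))
        c = np.array([1.0, -1.0, 0.5, 2.0])
        xs, losses = _cma_es(lambda x: float(np.sum((x - c) ** 2)), space, 1500, rng)
        best = xs[int(np.argmin(losses))]
        np.testing.assert_allclose(best, c, atol=0.05)

    def test_budget_respected_and_catalog_complete(self, rng):
        target = OscillatorTarget(0.2, 0.05, 0.5)
        space = make_circuit_space(3)
        for method in ("random", "imgep", "cmaes"):
            _, losses, catalog = optimize_circuit(
                target, space, OptimizerConfig(method=method, budget=30), rng, FAST
            )
            assert len(catalog) == 30
            assert len(losses) == 30

    def test_zero_budget_rejected(self, rng):
        target = OscillatorTarget(0.2, 0.05, 0.5)
        with pytest.raises(ValueError):
            optimize_circuit(
                target, make_circuit_space(3), OptimizerConfig(budget=0), rng, FAST
            )


class TestBenchmark:
    def test_zero_budget_empty_report(self, rng):
        report = run_benchmark(OscillatorTarget(0.2, 0.05, 0.5), rng, budget=0)
        assert report.results == []

    def test_imgep_finds_more_oscillators_than_random(self):
        # reduced-budget replicate of the severalfold enrichment
        counts = {"random": 0, "imgep": 0}
        for seed in range(3):
            rng = np.random.default_rng(seed)
            target = sample_oscillator_target(rng)
            report = run_benchmark(
                target, rng, methods=("random", "imgep"), budget=150,
                rollout_config=RolloutConfig(T=500.0, dt=0.1), finetune=False,
            )
            counts["random"] += report.by_method("random").n_oscillators
            counts["imgep"] += report.by_method("imgep").n_oscillators
        assert counts["imgep"] > counts["random"]

    def test_finetune_never_increases_best_loss(self, rng):
        target = sample_oscillator_target(rng)
        report = run_benchmark(
            target, rng, methods=("random",), budget=40,
            rollout_config=FAST, finetune=True,
        )
        res = report.by_method("random")
        assert res.finetuned_loss <= res.best_loss

    def test_coverage_curve_nondecreasing(self, rng):
        target = sample_oscillator_target(rng)
        report = run_benchmark(
            target, rng, methods=("random",), budget=60,
            rollout_config=RolloutConfig(T=500.0, dt=0.1), finetune=False,
        )
        covs = [c for _, c in report.by_method("random").coverage_curve]
        assert covs == sorted(covs)
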
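"""Gene-network model rollouts.

Two model classes are supported:

* :class:`GeneCircuitModel` — the transcriptional gene-circuit
  parameterization (W, B, tau) with the *discrete* explicit update

      y[t+1] = (dt/tau) * sigmoid(W y[t] + B) + (1 - dt/tau) * y[t]

* :class:`OdeModel` — an arbitrary rate-function contract
  ``rate_fn(y, t) -> dy/dt`` integrated adaptively (LSODA) between the
  uniform output grid points.

Both produce a :class:`Trajectory` on a uniform grid with T/dt + 1 points
(25,001 for the default T=2500 s, dt=0.1 s).  Non-finite or negative states
flag the trajectory invalid; nothing raises mid-rollout, because the
curation pipeline must be able to count failed rollouts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import odeint

from . import _kernels

__all__ = [
    "GeneCircuitModel",
    "OdeModel",
    "RolloutConfig",
    "Trajectory",
    "simulate_gene_circuit",
    "simulate_ode",
    "sample_random_gene_circuit",
    "continuous_analog",
]


@dataclass
class RolloutConfig:
    """Rollout horizon and solver settings.

    Defaults follow the study conventions: T=2500 s horizon at dt=0.1 s
    output steps (25,001 points including t0), absolute tolerance 1e-6,
    relative tolerance 1e-12 and at most 1000 internal solver steps per
    output interval.  A longer T=25000 horizon is used when building
    intervention bounds from a default time course (see
    :func:`grnexplore.spaces.build_intervention_space`).
    """

    T: float = 2500.0
    dt: float = 0.1
    atol: float = 1e-6
    rtol: float = 1e-12
    max_steps: int = 1000

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray
    contains_nan: bool = False
    contains_negative: bool = False

    @property
    def valid(self) -> bool:
        return not (self.contains_nan or self.contains_negative)

    @property
    def n(self) -> int:
        return self.states.shape[1]

    @property
    def T(self) -> float:
        return float(self.times[-1])

    @staticmethod
    def from_states(
        times: np.ndarray, states: np.ndarray, neg_tol: float = 1e-6
    ) -> "Trajectory":
        """Wrap states, flagging NaN and negative values.

        Negatives within ``neg_tol`` (the default solver atol) are treated
        as numerical zero, not invalid concentrations.
        """
        finite = np.isfinite(states)
        has_nan = not finite.all()
        has_neg = bool((states[finite] < -neg_tol).any())
        return Trajectory(times, states, has_nan, has_neg)


@dataclass
class GeneCircuitModel:
    """(W, B, tau) transcriptional gene circuit.

    ``W`` is the n x n interaction matrix (zero entries encode absent
    edges), ``B`` the per-node bias and ``tau`` the per-node time constant
    in seconds (a scalar broadcasts).
    """

    W: np.ndarray
    B: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim == 0:
            tau = np.full(self.B.shape[0], float(tau))
        self.tau = tau
        if self.W.shape != (self.n, self.n):
            raise ValueError(f"W must be ({self.n}, {self.n}), got {self.W.shape}")
        if not np.all(self.tau > 0):
            raise ValueError("all tau must be positive")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W must be finite")

    @property
    def n(self) -> int:
        return self.B.shape[0]

    def to_json(self, path=None, metadata: Optional[dict] = None):
        doc = {
            "W": self.W.tolist(),
            "B": self.B.tolist(),
            "tau": self.tau.tolist(),
            "metadata": metadata or {},
        }
        if path is None:
            return json.dumps(doc)
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @staticmethod
    def from_json(src) -> "GeneCircuitModel":
        if isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
            doc = json.loads(src)
        else:
            with open(src) as fh:
                doc = json.load(fh)
        return GeneCircuitModel(
            np.asarray(doc["W"]), np.asarray(doc["B"]), np.asarray(doc["tau"])
        )


@dataclass
class OdeModel:
    """Generic ODE network: ``rate_fn(y, t) -> dy/dt`` plus metadata."""

    n: int
    rate_fn: Callable[[np.ndarray, float], np.ndarray]
    default_y0: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.default_y0 is None:
            self.default_y0 = np.zeros(self.n)
        self.default_y0 = np.asarray(self.default_y0, dtype=float)


Hook = Callable[[int, float, np.ndarray], np.ndarray]


def simulate_gene_circuit(
    model: GeneCircuitModel,
    y0: np.ndarray,
    config: Optional[RolloutConfig] = None,
    hooks: Optional[Sequence[Hook]] = None,
) -> Trajectory:
    """Roll out the discrete gene-circuit update.

    Hooks, if given, are callables ``hook(step, t, y) -> y`` applied after
    each state update, in sequence order (convention: perturbation hooks
    before clamp hooks).  Without hooks the compiled kernel is used.
    """
    config = config or RolloutConfig()
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (model.n,):
        raise ValueError(f"y0 must have length {model.n}")
    a = config.dt / model.tau
    if np.any(a > 1.0 + 1e-12):
        raise ValueError("dt/tau must be <= 1 for the explicit update")
    times = config.times()
    if hooks is None:
        states = _kernels.gene_circuit_rollout(model.W, model.B, a, y0, config.n_steps)
        return Trajectory.from_states(times, states)
    states = np.empty((config.n_steps + 1, model.n))
    y = y0.copy()
    states[0] = y
    for t in range(config.n_steps):
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-(model.W @ y + model.B)))
        y = a * s + (1.0 - a) * y
        for hook in hooks:
            y = hook(t + 1, times[t + 1], y)
        states[t + 1] = y
        if not np.all(np.isfinite(y)):
            states[t + 2 :] = np.nan
            break
    return Trajectory.from_states(times, states)


def simulate_ode(
    model: OdeModel,
    y0: np.ndarray,
    config: Optional[RolloutConfig] = None,
    hooks: Optional[Sequence[Hook]] = None,
) -> Trajectory:
    """Adaptive integration sampled on the uniform output grid.

    With hooks the integration restarts at every output step so state
    overwrites (perturbations, clamps) are respected by the solver.
    """
    config = config or RolloutConfig()
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (model.n,):
        raise ValueError(f"y0 must have length {model.n}")
    times = config.times()

    def f(y, t):
        return np.asarray(model.rate_fn(y, t), dtype=float)

    kw = dict(
        rtol=config.rtol, atol=config.atol, mxstep=config.max_steps, full_output=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if hooks is None:
            try:
                states = odeint(f, y0, times, **kw)
            except Exception:
                states = np.full((times.size, model.n), np.nan)
                states[0] = y0
            return Trajectory.from_states(times, states)
        states = np.empty((times.size, model.n))
        y = y0.copy()
        states[0] = y
        for t in range(times.size - 1):
            try:
                seg = odeint(f, y, [times[t], times[t + 1]], **kw)
                y = seg[-1]
            except Exception:
                y = np.full(model.n, np.nan)
            for hook in hooks:
                y = hook(t + 1, times[t + 1], y)
            states[t + 1] = y
            if not np.all(np.isfinite(y)):
                states[t + 2 :] = np.nan
                break
    return Trajectory.from_states(times, states)


def sample_random_gene_circuit(
    n: int, in_degrees: Sequence[int], rng: np.random.Generator
) -> GeneCircuitModel:
    """Random circuit: nonzero W ~ U[-30,30], B ~ U[-10,10], tau ~ U[1,15].

    Row i of W gets exactly ``in_degrees[i]`` nonzero entries at columns
    chosen uniformly without replacement.
    """
    in_degrees = list(in_degrees)
    if len(in_degrees) != n:
        raise ValueError("in_degrees must have length n")
    W = np.zeros((n, n))
    for i, k in enumerate(in_degrees):
        if not 0 <= k <= n:
            raise ValueError(f"in-degree {k} for node {i} not in [0, {n}]")
        cols = rng.choice(n, size=k, replace=False)
        W[i, cols] = rng.uniform(-30.0, 30.0, size=k)
    B = rng.uniform(-10.0, 10.0, size=n)
    tau = rng.uniform(1.0, 15.0, size=n)
    return GeneCircuitModel(W, B, tau)


def continuous_analog(model: GeneCircuitModel) -> OdeModel:
    """Continuous-time analog dy/dt = (sigmoid(Wy+B) - y) / tau.

    Shares fixed points with the discrete update; used for cross-checking
    the two simulators.
    """

    def rate(y, t):
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-(model.W @ y + model.B)))
        return (s - y) / model.tau

    return OdeModel(n=model.n, rate_fn=rate, metadata={"kind": "gene-circuit-ode"})
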
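import numpy as np
import pytest

from grnexplore.dynamics import (
    GeneCircuitModel,
    RolloutConfig,
    Trajectory,
)
from grnexplore.explore import System
from grnexplore.spaces import BehaviorSpace, InterventionSpace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(y, dt=0.1):
    """Wrap a 1-D or (M, n) signal into a Trajectory on a uniform grid."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    times = np.arange(y.shape[0]) * dt
    return Trajectory.from_states(times, y)


@pytest.fixture
def toggle_switch():
    """2-node cross-repression circuit with two symmetric attractors.

    Node 0 high forces node 1 low and vice versa; both (high, low) and
    (low, high) are stable under the discrete update.
    """
    W = np.array([[0.0, -6.0], [-6.0, 0.0]])
    B = np.array([3.0, 3.0])
    return GeneCircuitModel(W, B, np.ones(2))


class AnalyticSystem(System):
    """System whose rollout is a closed-form I -> Z mapping (no ODE).

    The trajectory is two identical states equal to the mapped endpoint,
    so the endpoint encoder reads the mapping value directly.  Used to
    build fixtures with controlled redundancy.
    """

    def __init__(self, mapping, intervention_space, behavior_space=None):
        super().__init__(
            model=None,
            intervention_space=intervention_space,
            behavior_space=behavior_space or BehaviorSpace(kind="endpoint", nodes=(0, 1)),
            config=RolloutConfig(T=1.0, dt=1.0),
        )
        self.mapping = mapping

    def rollout(self, intervention):
        z = np.asarray(self.mapping(np.asarray(intervention, dtype=float)), dtype=float)
        states = np.vstack([z, z])
        return Trajectory.from_states(np.array([0.0, 1.0]), states)


@pytest.fixture
def redundant_system():
    """90% of the intervention box maps to one endpoint, 10% to a spread.

    Interventions with i[0] < 0.9 all reach (0.45, 0.45); the remaining
    slab fans out across the behavior square, so uniform screening wastes
    most of its budget on the redundant region.
    """

    def mapping(i):
        if i[0] < 0.9:
            return np.array([0.45, 0.45])
        return np.array([(i[0] - 0.9) * 10.0, i[1]])

    space = InterventionSpace(np.zeros(2), np.ones(2))
    return AnalyticSystem(mapping, space)
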
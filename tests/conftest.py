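import numpy as np
import pytest

from sptstates.config import SimulationConfig
from sptstates import linking, simulate
from sptstates.linking import StepTrace


@pytest.fixture(scope="session")
def default_config():
    """Reference three-state regime at a size small enough for unit tests."""
    return SimulationConfig(seed=42, n_particles=300)


@pytest.fixture(scope="session")
def default_traces(default_config):
    traj = simulate.simulate_trajectories(default_config)
    traj = linking.filter_tracks(traj, min_steps=10)
    return linking.all_step_traces(traj, default_config.frame_interval)


def sample_gamma_hmm(n_traces, mean_len, pi, A, shapes, scales, rng, t=0.081):
    """Data drawn exactly from a gamma-emission HMM (well-specified oracle)."""
    pi = np.asarray(pi, float)
    A = np.asarray(A, float)
    traces = []
    paths = []
    for i in range(n_traces):
        n = max(2, int(rng.geometric(1.0 / mean_len)))
        s = rng.choice(len(pi), p=pi)
        rs, ss = [], []
        for _ in range(n):
            rs.append(rng.gamma(shapes[s], scales[s]))
            ss.append(s)
            s = rng.choice(len(pi), p=A[s])
        traces.append(StepTrace(i, np.array(rs), t))
        paths.append(np.array(ss))
    return traces, paths
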
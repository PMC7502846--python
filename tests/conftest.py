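import numpy as np
import pytest

from kellerdfc.simulate import (
    BenchmarkScenario,
    TrueCoefficientTrajectory,
    simulate_benchmark,
    simulate_var1,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_replicate():
    """One default 5-node benchmark draw (trajectory + simulated series)."""
    traj, Y = simulate_benchmark(BenchmarkScenario(seed=3))
    return traj, Y


@pytest.fixture(scope="session")
def static_var_series():
    """Stationary 4-node VAR with two fixed couplings (no dynamics)."""
    p, T = 4, 200
    A = np.zeros((T, p, p))
    A[:, np.arange(p), np.arange(p)] = 0.6
    A[:, 0, 1] = 0.6
    A[:, 2, 3] = 0.5
    support = np.zeros((T, p, p), bool)
    support[:, 0, 1] = support[:, 1, 0] = True
    support[:, 2, 3] = support[:, 3, 2] = True
    traj = TrueCoefficientTrajectory(A=A, support=support)
    Y = simulate_var1(traj, seed=99)
    return traj, Y
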
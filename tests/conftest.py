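import logging

import numpy as np
import pytest

from survsel.data import SimulationConfig, SurvivalDataset, simulate_dataset

logging.getLogger("survsel").setLevel(logging.ERROR)


@pytest.fixture
def three_events() -> SurvivalDataset:
    """Times 1,2,3, all events, one inert covariate: risk sets of sizes 3,2,1."""
    return SurvivalDataset([1, 2, 3], [1, 1, 1], [[0.0], [0.0], [0.0]], ["x1"])


@pytest.fixture
def small_informative() -> tuple[SurvivalDataset, np.ndarray]:
    """n=120, p=6, two strong features; light censoring."""
    cfg = SimulationConfig(
        n=120, p=6, n_informative=2, beta_magnitude=1.5, censor_rate=0.2,
        correlation=0.0, seed=42,
    )
    return simulate_dataset(cfg)


def random_survival_instance(
    rng: np.random.Generator, n_max: int = 10, p_max: int = 3, allow_ties: bool = False
) -> SurvivalDataset:
    """Small random dataset for brute-force oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    p = int(rng.integers(1, p_max + 1))
    if allow_ties:
        times = rng.integers(1, max(3, n // 2) + 1, size=n).astype(float)
    else:
        times = rng.uniform(0.5, 10.0, size=n)
        while len(np.unique(times)) < n:
            times = rng.uniform(0.5, 10.0, size=n)
    events = rng.integers(0, 2, size=n)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    X = rng.standard_normal((n, p))
    return SurvivalDataset(times, events, X, [f"x{j}" for j in range(p)])
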
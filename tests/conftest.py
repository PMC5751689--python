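import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nirsnet as nn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def sine_recording():
    """Three channels: 0.2 Hz sinusoid, constant, 0.1 Hz + 2 Hz mixture."""
    fs, n = 10.0, 1000
    t = np.arange(n) / fs
    data = np.stack(
        [
            np.sin(2 * np.pi * 0.2 * t),
            np.full(n, 3.0),
            np.sin(2 * np.pi * 0.1 * t) + np.sin(2 * np.pi * 2.0 * t),
        ]
    )
    return nn.Recording("probe", data, fs, ["slow", "const", "mix"])


@pytest.fixture
def four_node_corr():
    """4-node correlation matrix whose |r| upper triangle is
    {0.9, 0.8, 0.7, 0.6, 0.5, 0.4} (pairs in a fixed layout)."""
    r = np.eye(4)
    vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.4}
    for (i, j), v in vals.items():
        r[i, j] = r[j, i] = v
    return nn.CorrelationMatrix(r, list("abcd"))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic cohort with the default planted effects (8+8)."""
    spec = nn.CohortSpec(n_patients=8, n_controls=8, seed=5)
    recordings, manifest, truth = nn.simulate_cohort(spec)
    return spec, recordings, manifest, truth


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> nn.AdjacencyMatrix:
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = (a | a.T).astype(np.uint8)
    return nn.AdjacencyMatrix(edges=a, threshold=0.0)
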
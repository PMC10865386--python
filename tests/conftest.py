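import numpy as np
import pytest

from pdmdc import PopulationSpec, ResponseTensor, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_tensor(rng):
    """A 5-metabolite, 6-time, 3-individual, 2-diet random tensor."""
    values = rng.normal(1.0, 0.5, size=(5, 6, 3, 2))
    return ResponseTensor(
        values,
        [f"m{k}" for k in range(5)],
        range(6),
        [f"i{k}" for k in range(3)],
        ["dietA", "dietB"],
    )


@pytest.fixture
def noiseless_population():
    """Single-cluster, zero-noise linear population: the generator's
    output is exactly explained by one LDS per individual."""
    spec = PopulationSpec(M=10, T=8, I=3, D=5, S_true=3, l=2,
                          noise_sd=0.0, within_cluster_cv=0.0,
                          baseline_sd=0.0, seed=7)
    return generate_population(spec)


def random_stable_system(rng, M, l, radius=0.8):
    """A random stable (A, B) pair for oracle-driven recovery tests."""
    A = rng.standard_normal((M, M))
    A *= radius / np.max(np.abs(np.linalg.eigvals(A)))
    B = rng.standard_normal((M, l))
    return A, B
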
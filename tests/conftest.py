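import numpy as np
import pytest

from mtgs import (
    BreedingConfig,
    GeneticValues,
    SyntheticSpec,
    example1_fixture,
    maize_like,
    simulate_effects,
    simulate_founders,
    simulate_recomb_map,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def example1():
    return example1_fixture()


@pytest.fixture(scope="session")
def example1_normalized():
    """The worked-example individual values, used directly as normalized
    values (they already lie strictly inside (0, 1))."""
    ex = example1_fixture()
    return GeneticValues(
        ex.values.individual_ids, ex.values.trait_ids, ex.values.values,
        is_normalized=True,
    )


@pytest.fixture(scope="session")
def tiny_trio():
    """Small synthetic founders + effects + map for pipeline tests."""
    spec = SyntheticSpec(
        n_founders=20, n_chromosomes=2, loci_per_chromosome=25,
        n_traits=2, rho=0.3,
    )
    g = np.random.default_rng(7)
    founders = simulate_founders(spec, g)
    effects = simulate_effects(spec, g)
    rmap = simulate_recomb_map(spec, g)
    return founders, effects, rmap, spec


def random_instance(rng, n_max=10, S_max=3, K_max=3):
    """A random normalized-values instance for enumeration-based checks."""
    n = int(rng.integers(3, n_max + 1))
    K = int(rng.integers(2, K_max + 1))
    S = int(rng.integers(1, min(S_max, n) + 1))
    vals = rng.uniform(0.05, 0.95, size=(n, K))
    Vn = GeneticValues([f"i{i}" for i in range(n)], [f"t{k}" for k in range(K)],
                       vals, is_normalized=True)
    w = rng.uniform(0.1, 2.0, size=K)
    return Vn, w, S
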
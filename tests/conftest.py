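import networkx as nx
import numpy as np
import pytest

from coexnet import SyntheticSpec, simulate_datasets


def random_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    """Small random graph (possibly disconnected) for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    return g


@pytest.fixture(scope="session")
def planted_triple():
    """Three 300-gene datasets sharing 5 planted 20-gene modules."""
    spec = SyntheticSpec(
        n_genes=300,
        n_datasets=3,
        samples_per_dataset=(30, 30, 30),
        shared_modules=(20,) * 5,
        private_modules_per_dataset=((20,), (20,), (20,)),
        within_module_corr=0.85,
        seed=42,
    )
    datasets, module_map = simulate_datasets(spec)
    return spec, datasets, module_map
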
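import numpy as np
import pandas as pd
import pytest

from nest import WeightedGeneNetwork
from nest.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def triangle_net() -> WeightedGeneNetwork:
    """The worked 3-gene example: A-B 0.5, A-C 1.0, B-C 0.2."""
    return WeightedGeneNetwork.from_edges(
        [("A", "B", 0.5), ("A", "C", 1.0), ("B", "C", 0.2)]
    )


@pytest.fixture
def triangle_values() -> pd.Series:
    return pd.Series({"A": 1.0, "B": 2.0, "C": -1.0})


@pytest.fixture(scope="session")
def default_dataset():
    """The standard planted-module benchmark (500 genes, 3 active modules)."""
    return generate_dataset(SyntheticSpec(seed=0))


def random_instance(rng: np.random.Generator, n_genes: int):
    """A small random weighted network plus a value vector, for oracle checks."""
    genes = [f"g{i}" for i in range(n_genes)]
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < 0.1:
                edges.append((genes[i], genes[j], float(rng.uniform(0.05, 1.0))))
    net = WeightedGeneNetwork.from_edges(edges, nodes=genes)
    values = pd.Series(rng.normal(size=n_genes), index=genes)
    return net, values
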
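import numpy as np
import pytest

from driver_irw import DirectedNetwork


def random_digraph(rng: np.random.Generator, n: int, p: float) -> DirectedNetwork:
    """Erdos-Renyi directed graph over named nodes, no self-loops."""
    genes = [f"v{i:03d}" for i in range(n)]
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    edges = [(genes[i], genes[j]) for i, j in zip(*np.nonzero(mask))]
    return DirectedNetwork.from_edges(genes, edges)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def diamond_net() -> DirectedNetwork:
    """4 nodes, edges n1->n2, n1->n3, n2->n3, n3->n1; n4 isolated."""
    return DirectedNetwork.from_edges(
        ["n1", "n2", "n3", "n4"],
        [("n1", "n2"), ("n1", "n3"), ("n2", "n3"), ("n3", "n1")],
    )


@pytest.fixture
def path3() -> DirectedNetwork:
    return DirectedNetwork.from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def cycle3() -> DirectedNetwork:
    return DirectedNetwork.from_edges(
        ["a", "b", "c"], [("a", "b"), ("b", "c"), ("c", "a")]
    )
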
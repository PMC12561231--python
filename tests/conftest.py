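import numpy as np
import pytest

from htinet import HeteroGraph, SynthConfig, generate, make_toy_graph


@pytest.fixture(scope="session")
def toy_graph() -> HeteroGraph:
    return make_toy_graph()


@pytest.fixture(scope="session")
def small_synth():
    """One deterministic small planted-structure graph shared across tests."""
    return generate(SynthConfig(seed=11))


def random_hetero_graph(rng: np.random.Generator, max_per_type: int = 12, density: float = 0.3) -> HeteroGraph:
    """A random typed graph over all six relations (used by oracles)."""
    g = HeteroGraph()
    counts = {t: int(rng.integers(1, max_per_type + 1)) for t in "HEIT"}
    for t, n in counts.items():
        for i in range(n):
            g.add_node(t, f"{t}{i + 1}")
    for rel, (a, b) in {
        "H-I": ("H", "I"),
        "H-E": ("H", "E"),
        "I-T": ("I", "T"),
        "H-T": ("H", "T"),
        "H-H": ("H", "H"),
        "T-T": ("T", "T"),
    }.items():
        sym = a == b
        for i in range(counts[a]):
            for j in range(counts[b]):
                if sym and j <= i:
                    continue
                if rng.random() < density:
                    g.add_edge(rel, f"{a}{i + 1}", f"{b}{j + 1}")
    g.validate()
    return g
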
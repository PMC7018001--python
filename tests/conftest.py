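import numpy as np
import pytest

import qubomod as qm


@pytest.fixture(scope="session")
def zachary() -> qm.Graph:
    return qm.load_benchmark("zachary")


@pytest.fixture(scope="session")
def zachary_B(zachary) -> qm.ModularityMatrix:
    return qm.modularity_matrix(zachary)


@pytest.fixture(scope="session")
def lesmiserables() -> qm.Graph:
    return qm.load_benchmark("lesmiserables")


@pytest.fixture
def triangle() -> qm.Graph:
    return qm.Graph.from_edges([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
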
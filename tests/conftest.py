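import numpy as np
import pytest

from netaggr import (
    GeneratorConfig,
    example1_network,
    example3_network,
    generate_clustered_network,
)


@pytest.fixture(scope="session")
def ex1():
    """The 8-node, 2-area worked-example network."""
    return example1_network()


@pytest.fixture(scope="session")
def ex3():
    """The 3-node heterogeneous pinning worked-example network."""
    return example3_network()


@pytest.fixture
def clustered_net():
    """Deterministic generated 3-area clustered network (seed 11)."""
    return generate_clustered_network(
        GeneratorConfig(
            sizes=(5, 5, 5),
            internal_min_degree=2,
            external_per_node_max=1,
            external_per_area_max=2,
            seed=11,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
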
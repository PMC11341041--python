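import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240822)


@pytest.fixture
def small_spec():
    from boldgraph.simulate import SimulationSpec
    return SimulationSpec(n_group1=4, n_group2=4, n_volumes=60, n_rois=8,
                          planted_edges=[(0, 4, 0.3)], rng_seed=7)
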
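import numpy as np
import pytest

from dendrorelax.topology import DendrimerSpec, DendrimerTopology, Family, build_topology


@pytest.fixture
def dumbbell():
    return DendrimerTopology(
        beads=[(0, 0, "X", 1.0), (1, 1, "X", 1.0)],
        edges=[(0, 1)],
        terminal_ids=[1],
    )


@pytest.fixture
def g2_trifunctional():
    return build_topology(
        DendrimerSpec(
            family=Family.GENERIC,
            core_functionality=3,
            branch_functionality=3,
            generation=2,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
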
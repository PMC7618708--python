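import numpy as np
import pytest

from polterm.synthetic_data import ElementMap, ReadSimSpec, simulate_reads


class ScriptedRng:
    """Deterministic draw source for forcing single stepper outcomes.

    Values are consumed in the order the stepper requests them:
    initiation draw (attempt ticks only), per-polymerase move draws,
    per-polymerase termination draws.
    """

    def __init__(self, values):
        self.values = list(values)

    def random(self, size=None):
        if size is None:
            return self.values.pop(0)
        return np.array([self.values.pop(0) for _ in range(int(size))])


@pytest.fixture
def scripted_rng():
    return ScriptedRng


@pytest.fixture(scope="session")
def element_map():
    return ElementMap()


@pytest.fixture(scope="session")
def synthetic_replicates(element_map):
    """Two modest synthetic CRAC libraries used by several test modules."""
    spec = ReadSimSpec(n_reads=12_000, n_replicates=2, seed=3)
    return simulate_reads(spec, element_map), spec
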
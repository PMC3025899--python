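import numpy as np
import pytest

from haplogeo.seqio import PopulationMap, SequenceAlignment
from haplogeo.synthetic import make_reference_fixture


@pytest.fixture(scope="session")
def reference():
    return make_reference_fixture()


@pytest.fixture
def toy_alignment():
    """Five 10-bp sequences: three identical, one 1-step off, one 2-step."""
    return SequenceAlignment(
        [
            ("s1", "ACGTACGTAC"),
            ("s2", "ACGTACGTAC"),
            ("s3", "ACGTACGTAC"),
            ("s4", "ACGTACGTAT"),
            ("s5", "ACGTACGAAT"),
        ]
    )


@pytest.fixture
def toy_popmap():
    return PopulationMap(
        sample_to_pop={"s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "B"},
        pop_to_site={"A": (39.5, 106.8, 1100.0), "B": (40.2, 107.0, 1100.0)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
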
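import logging

import numpy as np
import pytest

from rhmap import io
from rhmap.simulate import study_preset, simulate_panel

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def reference_bins():
    bins, _ = io.load_reference_tables()
    return bins


@pytest.fixture(scope="session")
def reference_contigs():
    _, contigs = io.load_reference_tables()
    return contigs


@pytest.fixture(scope="session")
def preset_panel():
    """One study-condition synthetic panel shared across tests."""
    return simulate_panel(study_preset(seed=11))


@pytest.fixture
def tiny_matrix():
    """4 lines x 3 markers with one missing call."""
    calls = np.array(
        [
            [1, 1, 0],
            [1, 0, 0],
            [1, 1, 1],
            [-1, 1, 1],
        ],
        dtype=np.int8,
    )
    return io.GenotypeMatrix(["L1", "L2", "L3", "L4"], ["mA", "mB", "mC"], calls)
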
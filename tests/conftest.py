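import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from morphoedit import GenParams, Node, build_morphology, generate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# the detection checks log warnings (e.g. skipped zero-length segments)
# that are expected while exercising broken fixtures
logging.getLogger("morphoedit").setLevel(logging.ERROR)


def mk(records):
    """Build a morphology from (id, type, (x, y, z), radius, parent) tuples."""
    return build_morphology(
        [Node(i, t, np.array(p, dtype=float), r, par) for i, t, p, r, par in records]
    )


@pytest.fixture
def clean_morph():
    return generate(GenParams(seed=0))


@pytest.fixture
def soma_chain():
    """One soma point plus an unbranched 5-node basal chain."""
    recs = [(1, 1, (0, 0, 0), 5.0, -1)]
    prev = 1
    for k in range(5):
        recs.append((2 + k, 3, (6.0 + 3 * k, 0, 0), 1.0, prev))
        prev = 2 + k
    return mk(recs)


@pytest.fixture
def forked():
    """3-node chain whose last node has two 2-node children."""
    return mk(
        [
            (1, 1, (0, 0, 0), 5.0, -1),
            (2, 3, (6, 0, 0), 1.0, 1),
            (3, 3, (9, 0, 0), 1.0, 2),
            (4, 3, (12, 0, 0), 1.0, 3),
            (5, 3, (15, 3, 0), 0.9, 4),
            (6, 3, (18, 6, 0), 0.8, 5),
            (7, 3, (15, -3, 0), 0.9, 4),
            (8, 3, (18, -6, 0), 0.8, 7),
        ]
    )
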
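import numpy as np
import pytest

from mosaicsim import ContactLog, generate_fixture


@pytest.fixture
def toy_contact_log() -> ContactLog:
    """Hand-written three-pair log with known durations."""
    events = [
        (0.0, 5.0, 0, 1),
        (6.0, 8.0, 0, 1),    # pair (0,1): total duration 7
        (1.0, 4.0, 1, 2),    # pair (1,2): total duration 3
        (2.0, 3.0, 0, 2),    # pair (0,2): total duration 1 -> ln 1 = 0
    ]
    return ContactLog(events=events, n_nodes=3, horizon=10.0)


@pytest.fixture
def random_contact_log() -> ContactLog:
    return generate_fixture("contact-log",
                            {"n_nodes": 8, "horizon": 60.0}, seed=2)
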
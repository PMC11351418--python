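import zlib

import numpy as np
import pytest

from liftopt import body
from liftopt.posture import with_reference_angles


@pytest.fixture(scope="session")
def subject():
    """The 1.70 m / 68.75 kg reference subject."""
    return body.build_human_model(1.7, 68.75)


@pytest.fixture(scope="session")
def task(subject):
    """The packaged box-lifting task with synthesized reference postures."""
    return with_reference_angles(subject, body.LiftingTask())


@pytest.fixture
def rng(request):
    # per-test generator seeded from a stable digest of the test id:
    # reproducible across runs and independent of collection order
    seed = zlib.crc32(request.node.name.encode()) % 2**31
    return np.random.default_rng(seed)
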
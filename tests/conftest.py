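import numpy as np
import pytest

from uromark.types import MethylationCalls


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sample():
    return MethylationCalls.from_records(
        "s1",
        [
            ("chr1", 100, 5, 5),
            ("chr1", 150, 10, 0),
            ("chr1", 220, 0, 12),
            ("chr2", 50, 3, 9),
        ],
    )
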
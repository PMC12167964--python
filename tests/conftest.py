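import time

import pytest

from reefcarb import experiments


@pytest.fixture(scope="session")
def ensemble():
    """The full nine-member ensemble at default configuration, run once."""
    t0 = time.perf_counter()
    result = experiments.run_ensemble()
    result.wall_time_s = time.perf_counter() - t0
    return result
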
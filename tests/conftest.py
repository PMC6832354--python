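import numpy as np
import pytest

from eagdc import SimConfig, Trace, generate, simulate_benchmark_trace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def type2_trace():
    """Noise-free odour trace (pure response train) at the 100 Hz pipeline rate."""
    return simulate_benchmark_trace(
        3, 0.5, condition="noise_off_odour",
        drift_step=0.0, drift_bound=0.0, hum_amp=0.0,
    )


@pytest.fixture(scope="session")
def type4_trace():
    """Full noise + odour benchmark trace at the 100 Hz pipeline rate."""
    return simulate_benchmark_trace(7, 0.5)


@pytest.fixture
def short_trace():
    return Trace([0.0, -0.2, -0.6, -0.6], fs=100.0)
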
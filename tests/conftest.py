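import numpy as np
import pytest

from bonecc import (
    FxLMSConfig,
    HeadConfig,
    PathPair,
    TimeSignal,
    estimate_ctc_filter,
    generate_paths,
    generate_transducer_pair,
)

RATE = 16000.0


@pytest.fixture(scope="session")
def head_paths() -> PathPair:
    """Default synthetic head (seed 0)."""
    return generate_paths(HeadConfig(seed=0))


@pytest.fixture(scope="session")
def transducer_pair():
    return generate_transducer_pair(0, RATE)


@pytest.fixture(scope="session")
def converged_ctc(head_paths):
    """One converged FxLMS run on the default head, shared across tests
    (10 s of band-limited noise)."""
    return estimate_ctc_filter(head_paths, FxLMSConfig(duration_s=10.0, seed=1))


@pytest.fixture(scope="session")
def delta_anti_paths() -> PathPair:
    """Exactly-solvable fixture: crosstalk path is the negated secondary
    path, with a memoryless (unit-impulse) secondary path."""
    d = np.zeros(512)
    d[0] = 1.0
    return PathPair(
        h_primary=TimeSignal(-d, RATE),
        h_secondary=TimeSignal(d, RATE),
    )


def spectrum(taps: np.ndarray, n_fft: int = 4096, rate: float = RATE):
    """Frequency axis and complex spectrum of a tap sequence."""
    f = np.fft.rfftfreq(n_fft, 1.0 / rate)
    return f, np.fft.rfft(taps, n_fft)
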
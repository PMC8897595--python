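import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_site_count(sequence: str, motif: str) -> int:
    """Position-by-position sliding-window oracle for motif counting."""
    k = len(motif)
    return sum(sequence[i : i + k] == motif for i in range(len(sequence) - k + 1))
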
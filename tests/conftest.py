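import sys
from pathlib import Path

import numpy as np
import pytest

# make shared oracle helpers importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def staircase(n_frames, step_frames, step_height, start_level=100.0):
    """Piecewise-constant bleaching profile with steps at the given frames."""
    level = np.full(n_frames, float(start_level))
    for t in step_frames:
        level[t:] -= step_height
    return level


def separated_step_times(rng, k, n_frames=250, lo=10, hi=None, min_separation=10):
    """k step times, uniformly drawn subject to a minimum separation."""
    hi = hi if hi is not None else n_frames - 10
    while True:
        t = np.sort(rng.integers(lo, hi, k))
        if k <= 1 or np.all(np.diff(t) >= min_separation):
            return t
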
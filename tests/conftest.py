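import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


class ScriptedRNG:
    """Replays a fixed flat sequence of uniforms through the Generator API."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=np.float64)
        self.pos = 0

    def random(self, n=None):
        if n is None:
            out = self.values[self.pos]
            self.pos += 1
            return float(out)
        out = self.values[self.pos : self.pos + n]
        if out.size < n:
            raise RuntimeError("scripted RNG exhausted")
        self.pos += n
        return out.copy()


@pytest.fixture
def scripted_rng_factory():
    return ScriptedRNG


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
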
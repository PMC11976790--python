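import numpy as np
import pytest
from hypothesis import settings

from microswim import Action, Colloid, SystemParams

settings.register_profile("det", derandomize=True)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


class CountingForceFunction:
    """Instrumented stub: zero actions, counts calls, optional kill slice."""

    def __init__(self, kill_at=None):
        self.calls = 0
        self.kill_at = kill_at
        self.kill_switch = False

    def calc_action(self, colloids):
        if self.kill_at is not None and self.calls == self.kill_at:
            self.kill_switch = True
        self.calls += 1
        return [Action() for _ in colloids]


@pytest.fixture
def counting_ff():
    return CountingForceFunction


def make_colloids(n, d=2, spacing=3.0, ptype=0):
    out = []
    for i in range(n):
        pos = np.full(d, 10.0) + spacing * i * np.eye(d)[0]
        e = np.zeros(d)
        e[0] = 1.0
        out.append(Colloid(i, ptype, pos, e))
    return out


@pytest.fixture
def simple_params():
    return SystemParams(dimension=2, box_length=100.0, temperature=0.0, dt=0.01, boundary="open")
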
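import numpy as np
import pytest

from kymotrace import synth
from kymotrace.io import Trajectory


@pytest.fixture()
def tether():
    return synth.TetherModel()


@pytest.fixture()
def tether_with_beads():
    return synth.TetherModel(bead_margin_px=5)


@pytest.fixture()
def static_trajectory():
    return Trajectory(
        id=0,
        channel="eGFP",
        times_s=np.arange(50) * 0.25,
        positions_um=np.full(50, 5.0),
    )


def make_random_trajectory(rng, n=None, dt=0.25):
    n = n or rng.integers(2, 201)
    return Trajectory(
        id=0,
        channel="eGFP",
        times_s=np.arange(n) * dt,
        positions_um=rng.normal(5.0, 0.5, size=n),
    )


def brute_force_msd(x):
    """Independent O(N^2) oracle for the time-averaged MSD."""
    n_samples = len(x)
    out = []
    for n in range(1, n_samples):
        acc = 0.0
        for i in range(n_samples - n):
            acc += (x[i + n] - x[i]) ** 2
        out.append(acc / (n_samples - n))
    return out
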
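import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crownbind.itc import SequentialParams
from crownbind.synth import kcl_protocol

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def protocol():
    """The KCl titration protocol (4 uL discarded + 28 x 10 uL)."""
    return kcl_protocol()


@pytest.fixture(scope="session")
def kcl_truth():
    """Stepwise truth for the KCl experiment."""
    return SequentialParams(k1=119.0, k2=17.2, dh1=-4.12, dh2=-6.76)


def bisect_free_ligand(lt, mt, k1, k2, iters=200):
    """Independent plain-bisection oracle for the two-site mass balance."""

    def f(l):
        zeta = 1.0 + k1 * l + k1 * k2 * l * l
        return l + mt * (k1 * l + 2.0 * k1 * k2 * l * l) / zeta - lt

    lo, hi = 0.0, lt
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def enumerate_fractions(l, k1, k2):
    """Occupancy fractions from explicit 3-state Boltzmann weights."""
    w = np.array([1.0, k1 * l, k1 * k2 * l * l])
    return w / w.sum()
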
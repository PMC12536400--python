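import numpy as np
import pytest

from permeakit import (
    LangevinSpec,
    Profile1D,
    ThermoConditions,
    WPmfSpec,
    make_w_pmf,
    simulate_langevin,
)
from permeakit import tetracycline as tcx


@pytest.fixture
def tc310():
    return ThermoConditions(temperature=310.0, pH=6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def w_pmf():
    """Default W-shaped PMF (barrier 4.5, wells -4.9 at +-14 A)."""
    return make_w_pmf(WPmfSpec())


@pytest.fixture(scope="session")
def tc_like():
    """Profile-based TC stand-in calibrated to the published permeabilities."""
    return tcx.tc_like_species()


def constant_profile(value, kind, lo=-25.0, hi=25.0, n=201):
    z = np.linspace(lo, hi, n)
    return Profile1D(z=z, values=np.full(n, float(value)), kind=kind)


@pytest.fixture(scope="session")
def flat_trajectory():
    """1e6-step free diffusion at D = 50 A^2/ns between reflecting walls."""
    flat = constant_profile(0.0, "pmf")
    d = constant_profile(50.0, "diffusivity")
    return simulate_langevin(
        LangevinSpec(potential=flat, diffusivity=d, dt=0.0025, n_steps=1_000_000, seed=42)
    )
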
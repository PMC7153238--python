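"""Shared fixtures: small simulated worlds reused across test modules.

Session scope keeps the expensive mixed-model fits to a handful; every
fixture is fully seeded so the suite is deterministic.
"""

import pytest

import lawbend as lb


@pytest.fixture(scope="session")
def strong_config() -> lb.SimulationConfig:
    """A clearly bent world: visible slope breaks at (-12, 12), 20 states."""
    return lb.SimulationConfig(
        n_states=20,
        stdm_range=(-24, 24),
        beta1=0.02,
        gamma1=-0.04,
        gamma2=0.03,
        tau1=-12,
        tau2=12,
        dispersion=0.3,
        sigma_b=0.35,
        seed=20240917,
    )


@pytest.fixture(scope="session")
def strong_cells(strong_config):
    cells, laws = lb.simulate_surveillance(strong_config)
    return cells[cells["classification"] == "incident"].reset_index(drop=True)


@pytest.fixture(scope="session")
def strong_fit(strong_cells):
    """Polished fit at the true knots of ``strong_config``."""
    fit = lb.fit_piecewise_model(strong_cells, lb.KnotPair(-12, 12))
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def flat_config() -> lb.SimulationConfig:
    """No trend, no random intercepts: the stationary null world."""
    return lb.SimulationConfig(
        n_states=12,
        stdm_range=(-18, 18),
        beta1=0.0,
        gamma1=0.0,
        gamma2=0.0,
        tau1=-6,
        tau2=6,
        dispersion=0.2,
        sigma_b=0.0,
        seed=99,
    )


@pytest.fixture(scope="session")
def flat_cells(flat_config):
    cells, _ = lb.simulate_surveillance(flat_config)
    return cells[cells["classification"] == "incident"].reset_index(drop=True)
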
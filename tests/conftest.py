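"""Shared fixtures: presets and (expensive) resident attractors."""

from dataclasses import replace

import pytest

import evocycles as ec


@pytest.fixture(scope="session")
def fig2b():
    return ec.load_preset("fig2b")


@pytest.fixture(scope="session")
def fig2c():
    return ec.load_preset("fig2c")


@pytest.fixture(scope="session")
def fig4():
    return ec.load_preset("fig4")


@pytest.fixture(scope="session")
def baseline_params():
    """Constant-environment parameter set of the worked seasonal example (amp = 0)."""
    return ec.EpiParams(a0=10.0, q0=0.5, b=1.0, alpha=1.0, gamma=1.0, beta=0.2)


@pytest.fixture(scope="session")
def fig2b_attractor(fig2b):
    cyc, _ = ec.compute_attractor(fig2b.variant, fig2b.epi, fig2b.tradeoff)
    return cyc


@pytest.fixture(scope="session")
def fig4_attractor(fig4):
    cyc, _ = ec.compute_attractor(fig4.variant, fig4.epi, fig4.tradeoff)
    return cyc


@pytest.fixture(scope="session")
def gamma0_attractor(fig2b):
    """Seasonal cycle with recovery switched off (unstructured mutant regime)."""
    p = replace(fig2b.epi, gamma=0.0)
    cyc, _ = ec.compute_attractor("seasonal", p, fig2b.tradeoff)
    return p, cyc
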
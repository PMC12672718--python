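"""Shared fixtures: small synthetic networks, catalogs and protocols."""

import numpy as np
import pytest

import optolobe as ol
from optolobe.network_model import CellTypeCatalog, SignedConnectome, tile_network
from optolobe.protocol import StimulusProtocol


@pytest.fixture(scope="session")
def single_neuron_net():
    """An isolated, synapse-free single-type network (one gated lamina cell)."""
    cat = CellTypeCatalog(
        names=("A",),
        is_photoreceptor=np.array([True]),
        is_lamina=np.array([True]),
        e_leak_mv=np.array([-50.0]),
        is_gated=np.array([True]),
    )
    conn = SignedConnectome(intra=np.zeros((1, 1)), inter=np.zeros((1, 1)), catalog=cat)
    return tile_network(conn, 1)


@pytest.fixture
def passive_single_params():
    return ol.ModelParameters(
        gains=ol.GainParameters(inp_gain=np.zeros(1), out_gain=np.zeros(1))
    )


@pytest.fixture
def gated_single_params():
    gate = ol.GateParams(
        g_max=np.array([10.0]), v_mid=-60.0, slope=-0.2, tau_midv=-60.0, e_rev=-30.0
    )
    return ol.ModelParameters(
        gains=ol.GainParameters(inp_gain=np.zeros(1), out_gain=np.zeros(1)), gate=gate
    )


def step_protocol(amplitude_pa, t_on_s=0.5, t_off_s=None, duration_s=2.0, dt_s=0.01):
    """Current-step protocol for the single-type network."""
    return StimulusProtocol(
        target_types=("A",),
        target_column=0,
        amplitude_pa=amplitude_pa,
        t_on_s=t_on_s,
        t_off_s=duration_s if t_off_s is None else t_off_s,
        duration_s=duration_s,
        dt_s=dt_s,
    )


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small passive synthetic experiment (4 types, 3 columns)."""
    spec = ol.SynthSpec(
        n_types=4, n_columns=3, density=0.5, inter_density=0.3,
        n_photoreceptors=1, n_lamina=2, n_gated=0, seed=3,
    )
    return ol.make_fixture(spec)


@pytest.fixture(scope="session")
def tiny_gated_fixture():
    """Small gated synthetic experiment (4 types, 3 columns, 2 gated)."""
    spec = ol.SynthSpec(
        n_types=4, n_columns=3, density=0.5, inter_density=0.3,
        n_photoreceptors=1, n_lamina=2, n_gated=2, seed=3,
    )
    return ol.make_fixture(spec)


@pytest.fixture(scope="session")
def reference_catalog_connectome():
    """Reference-scale synthetic connectome: 65 types, 8 photoreceptors,
    5 gated lamina types."""
    spec = ol.SynthSpec(seed=0)
    return ol.gen_connectome(spec)
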
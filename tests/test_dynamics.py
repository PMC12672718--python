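"""Membrane and gate dynamics: closed forms, phenomenology, convergence."""

import numpy as np
import pytest

import optolobe as ol
from optolobe.dynamics import (
    NeuronPhysiology,
    SimulationDivergedError,
    gate_steady_state,
    gate_time_constant,
    step_gate,
    synaptic_conductances,
)

from conftest import step_protocol


def gate(g_max=10.0, v_mid=-50.0, slope=-0.2, tau_midv=-60.0, e_rev=-30.0):
    return ol.GateParams(
        g_max=np.array([g_max]), v_mid=v_mid, slope=slope, tau_midv=tau_midv, e_rev=e_rev
    )


class TestSynapticConductances:
    def test_all_at_threshold_gives_zero(self, tiny_fixture):
        net = tiny_fixture.net
        v = np.full(net.n_neurons, -50.0)
        ge, gi = synaptic_conductances(v, tiny_fixture.params.gains, net)
        assert np.all(ge == 0) and np.all(gi == 0)

    def test_zero_input_gain_annihilates(self, tiny_fixture):
        net = tiny_fixture.net
        gains = ol.GainParameters(
            inp_gain=np.zeros(net.n_types), out_gain=np.ones(net.n_types)
        )
        v = np.full(net.n_neurons, -30.0)
        ge, gi = synaptic_conductances(v, gains, net)
        assert np.all(ge == 0) and np.all(gi == 0)

    def test_hand_summed_single_connection(self):
        """One excitatory synapse: g = inp * M * out * (V_pre - trld)+ = 5 nS."""
        from optolobe.network_model import CellTypeCatalog, SignedConnectome, tile_network

        cat = CellTypeCatalog(
            names=("pre", "post"),
            is_photoreceptor=np.array([True, False]),
            is_lamina=np.zeros(2, bool),
            e_leak_mv=np.full(2, -50.0),
        )
        intra = np.array([[0, 0], [10, 0]])  # pre (col 0) -> post (row 1)
        net = tile_network(SignedConnectome(intra=intra, inter=np.zeros((2, 2)), catalog=cat), 1)
        gains = ol.GainParameters(inp_gain=np.array([1.0, 1.0]), out_gain=np.array([0.05, 1.0]))
        v = np.array([-40.0, -50.0])
        ge, gi = synaptic_conductances(v, gains, net)
        assert ge[1] == pytest.approx(1 * 10 * 0.05 * 10)  # 5 nS
        assert np.all(gi == 0)

    def test_shape_mismatch_rejected(self, tiny_fixture):
        with pytest.raises(ValueError):
            synaptic_conductances(np.zeros(3), tiny_fixture.params.gains, tiny_fixture.net)


class TestGateMath:
    def test_half_activation_at_v_mid(self):
        p = gate(g_max=10.0)
        assert gate_steady_state(p.v_mid, p) == pytest.approx(5.0)

    def test_hyperpolarization_activation_value(self):
        """slope=-0.2, V_mid=-50, V=-70: 10/(1+e^-4) ~ 9.82 nS."""
        p = gate(g_max=10.0, v_mid=-50.0, slope=-0.2)
        assert gate_steady_state(-70.0, p) == pytest.approx(10 / (1 + np.exp(-4)), rel=1e-9)
        assert gate_steady_state(-70.0, p) == pytest.approx(9.82, abs=0.005)

    def test_disabled_gate_is_zero_everywhere(self):
        p = gate(g_max=0.0)
        v = np.linspace(-100, 20, 25)
        assert np.all(gate_steady_state(v, p) == 0)

    def test_steady_state_bounded(self):
        p = gate(g_max=7.0, slope=-0.9)
        v = np.linspace(-200, 200, 101)
        g = gate_steady_state(v, p)
        assert np.all((g >= 0) & (g <= 7.0))

    def test_time_constant_peak_value(self):
        p = gate(tau_midv=-60.0)
        assert gate_time_constant(-60.0, p) == pytest.approx(0.85)

    @pytest.mark.parametrize("delta", [1.0, 7.5, 22.0, 60.0])
    def test_time_constant_even_symmetry(self, delta):
        p = gate(tau_midv=-55.0)
        left = gate_time_constant(p.tau_midv - delta, p)
        right = gate_time_constant(p.tau_midv + delta, p)
        assert left == pytest.approx(right, rel=1e-12)

    def test_time_constant_far_from_peak(self):
        p = gate(tau_midv=-60.0)
        expected = 0.1 + 1.5 / (np.exp(6) + np.exp(-6))
        assert gate_time_constant(0.0, p) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.1037, abs=2e-4)


class TestStepGate:
    def test_fixed_point(self):
        p = gate()
        g_inf = gate_steady_state(-70.0, p)
        assert step_gate(g_inf, -70.0, 0.01, p) == pytest.approx(g_inf)

    def test_exponential_relaxation_over_one_tau(self):
        """At fixed V, the gap to steady state shrinks to 1/e after tau."""
        p = gate()
        v = -75.0
        tau = gate_time_constant(v, p)
        g_inf = gate_steady_state(v, p)
        g = 0.0
        dt = tau / 2000
        for _ in range(2000):
            g = step_gate(g, v, dt, p)
        gap = abs(g - g_inf) / g_inf
        assert gap == pytest.approx(np.exp(-1), rel=5e-3)

    def test_euler_matches_fine_step_reference(self):
        p = gate()
        v = -68.0
        coarse = fine = 2.0
        for _ in range(10):
            coarse = step_gate(coarse, v, 0.02, p)
        for _ in range(1000):
            fine = step_gate(fine, v, 0.0002, p)
        assert coarse == pytest.approx(fine, rel=0.05)

    def test_oversized_step_rejected(self):
        with pytest.raises(ValueError, match="Euler"):
            step_gate(1.0, -60.0, 0.2, gate())


class TestSimulate:
    def test_equilibrium_without_stimulus(self, single_neuron_net, passive_single_params):
        proto = step_protocol(0.0)
        v = ol.simulate(single_neuron_net, passive_single_params, proto)
        assert np.allclose(v, -50.0)

    def test_passive_rc_closed_form(self, single_neuron_net, passive_single_params):
        """20 pA into C=40 pF, g=1 nS: V -> E_leak + 20 mV with tau = 40 ms."""
        proto = step_protocol(20.0, t_on_s=0.0, duration_s=0.4, dt_s=0.001)
        v = ol.simulate(single_neuron_net, passive_single_params, proto)[0]
        t = proto.times_s * 1e3  # ms
        analytic = -50.0 + 20.0 * (1 - np.exp(-t / 40.0))
        # explicit Euler at dt=1 ms stays within 1% of the step amplitude
        assert np.max(np.abs(v - analytic)) < 0.01 * 20.0

    def test_sag_and_rebound(self, single_neuron_net, gated_single_params):
        proto = step_protocol(-20.0, t_on_s=1.0, t_off_s=2.0, duration_s=4.0)
        v = ol.simulate(single_neuron_net, gated_single_params, proto)[0]
        on, off = proto.onset_index, proto.offset_index
        baseline = v[on - 1]
        k_min = on + int(np.argmin(v[on:off]))
        assert k_min < off - 1, "voltage minimum must occur before step offset (sag)"
        assert v[off - 1] > v[k_min] + 1.0, "membrane relaxes back up during the step"
        assert v[on:off].min() < baseline - 5.0
        assert v[off:].max() > baseline + 0.5, "post-offset rebound overshoots baseline"

    def test_zero_gain_traces_equal_isolated(self, tiny_gated_fixture):
        fx = tiny_gated_fixture
        params = ol.ModelParameters(
            gains=ol.GainParameters(
                inp_gain=np.zeros(fx.net.n_types),
                out_gain=fx.params.gains.out_gain,
            ),
            gate=fx.params.gate,
        )
        v = ol.simulate(fx.net, params, fx.proto)
        # every trace equals the fully isolated (synapse-free) trace
        from optolobe.network_model import TiledNetwork

        zero = np.zeros_like(fx.net.m_exc)
        isolated_net = TiledNetwork(
            n_columns=fx.net.n_columns, m_exc=zero, m_inh=zero, catalog=fx.net.catalog
        )
        v_iso = ol.simulate(isolated_net, params, fx.proto)
        assert np.allclose(v, v_iso)

    def test_reversal_potential_bracketing(self, tiny_gated_fixture):
        fx = tiny_gated_fixture
        from optolobe.protocol import build_stimulus

        proto = build_stimulus(fx.connectome.catalog, fx.net.n_columns, amplitude_pa=0.0)
        v = ol.simulate(fx.net, fx.params, proto)
        phys = NeuronPhysiology()
        lo = min(phys.e_inh_mv, fx.net.catalog.e_leak_mv.min(), fx.params.gate.e_rev)
        hi = max(phys.e_exc_mv, fx.net.catalog.e_leak_mv.max(), fx.params.gate.e_rev)
        settled = v[:, -50:]
        assert np.all(settled >= lo - 1e-6) and np.all(settled <= hi + 1e-6)

    def test_integrator_consistency_under_dt_halving(self, tiny_gated_fixture):
        fx = tiny_gated_fixture
        from optolobe.protocol import build_stimulus

        final = {}
        for dt in (0.01, 0.005):
            proto = build_stimulus(fx.connectome.catalog, fx.net.n_columns, dt_s=dt)
            v = ol.simulate(fx.net, fx.params, proto)
            final[dt] = v[:, -1]
        assert np.max(np.abs(final[0.01] - final[0.005])) < 0.5  # mV, first-order

    def test_exponential_euler_agrees_with_euler(self, tiny_fixture):
        fx = tiny_fixture
        v_e = ol.simulate(fx.net, fx.params, fx.proto, method="euler")
        v_x = ol.simulate(fx.net, fx.params, fx.proto, method="exponential")
        # schemes differ during fast transients but settle to the same state
        assert np.max(np.abs(v_e[:, -20:] - v_x[:, -20:])) < 0.5

    def test_divergence_raises_with_step_index(self, tiny_fixture):
        fx = tiny_fixture
        huge = ol.ModelParameters(
            gains=ol.GainParameters(
                inp_gain=np.full(fx.net.n_types, 100.0),
                out_gain=np.full(fx.net.n_types, 100.0),
            )
        )
        with pytest.raises(SimulationDivergedError) as err:
            ol.simulate(fx.net, huge, fx.proto)
        assert err.value.step > 0

    def test_conductances_non_negative_along_trajectory(self, tiny_gated_fixture):
        fx = tiny_gated_fixture
        v = ol.simulate(fx.net, fx.params, fx.proto)
        for k in range(0, v.shape[1], 20):
            ge, gi = synaptic_conductances(v[:, k], fx.params.gains, fx.net)
            assert np.all(ge >= 0) and np.all(gi >= 0)
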
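"""Cost function, parameter vector, gradients, and the optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import optolobe as ol
from optolobe.fitting import (
    FitConfig,
    _draw_initial,
    _EvalContext,
    _value_and_grad,
    cost,
    default_gain_range,
    evaluate,
    fit,
)
from optolobe.parameters import (
    ablate_gate,
    constrained_vector,
    n_parameters,
    params_to_vector,
    softplus,
    softplus_inv,
    vector_to_params,
)


class TestCost:
    def test_perfect_fit_is_zero(self):
        d = np.random.default_rng(0).normal(size=(2, 3, 10))
        assert cost(d, d) == 0.0

    def test_null_model_normalizes_to_one(self):
        d = np.random.default_rng(1).normal(size=(2, 3, 10))
        assert cost(np.zeros_like(d), d) == pytest.approx(1.0)

    def test_doubled_model_also_costs_one(self):
        d = np.random.default_rng(2).normal(size=(2, 3, 10))
        assert cost(2 * d, d) == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cost(np.zeros((1, 2, 3)), np.zeros((1, 2, 4)))

    def test_zero_data_power_rejected(self):
        with pytest.raises(ValueError, match="power"):
            cost(np.ones((1, 1, 2)), np.zeros((1, 1, 2)))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_summation_order(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(3, 2, 8))
        d = rng.normal(size=(3, 2, 8))
        perm = rng.permutation(3)
        assert cost(m, d) == pytest.approx(cost(m[perm], d[perm]), rel=1e-12)


class TestParameterVector:
    def test_reference_counts_130_and_138(self, reference_catalog_connectome):
        cat = reference_catalog_connectome.catalog
        assert n_parameters(cat, gate_enabled=False) == 130
        assert n_parameters(cat, gate_enabled=True) == 138

    def test_round_trip(self, tiny_gated_fixture):
        params = tiny_gated_fixture.params
        cat = tiny_gated_fixture.connectome.catalog
        z = params_to_vector(params)
        back = vector_to_params(z, cat, gate_enabled=True, e_rev=params.gate.e_rev)
        assert np.allclose(constrained_vector(back), constrained_vector(params))

    def test_wrong_length_rejected(self, tiny_fixture):
        cat = tiny_fixture.connectome.catalog
        with pytest.raises(ValueError, match="length"):
            vector_to_params(np.zeros(3), cat, gate_enabled=False)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(1e-6, 1e4))
    def test_softplus_inverse_round_trip(self, y):
        assert softplus(softplus_inv(y)) == pytest.approx(y, rel=1e-9)

    def test_non_negativity_by_construction(self, tiny_gated_fixture):
        cat = tiny_gated_fixture.connectome.catalog
        rng = np.random.default_rng(0)
        z = rng.normal(scale=10, size=n_parameters(cat, True))
        p = vector_to_params(z, cat, gate_enabled=True)
        assert np.all(p.gains.inp_gain >= 0) and np.all(p.gains.out_gain >= 0)
        assert np.all(p.gate.g_max >= 0)


@pytest.mark.parametrize("gate_enabled", [False, True])
def test_gradient_matches_finite_differences(gate_enabled, tiny_fixture, tiny_gated_fixture):
    """Analytic reverse-mode gradient vs central differences, < 1e-3 relative."""
    fx = tiny_gated_fixture if gate_enabled else tiny_fixture
    ctx = _EvalContext.build(fx.net, fx.proto, fx.targets, gate_enabled=gate_enabled)
    cfg = FitConfig(rounds=((1, 0.1),), n_restarts=1, gate_enabled=gate_enabled)
    z = _draw_initial(np.random.default_rng(7), fx.net, cfg)
    _, g = _value_and_grad(z, ctx)
    h = 1e-5
    for i in range(z.size):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        cp, _ = _value_and_grad(zp, ctx)
        cm, _ = _value_and_grad(zm, ctx)
        fd = (cp - cm) / (2 * h)
        # floor guards coordinates whose gradient is below the FD noise floor
        scale = max(abs(fd), abs(g[i]), 1e-8)
        assert abs(g[i] - fd) / scale < 1e-3, f"coordinate {i}"


class TestEvaluate:
    def test_self_consistency_zero_cost(self, tiny_fixture):
        fx = tiny_fixture
        assert evaluate(fx.params, fx.net, fx.proto, fx.targets) == pytest.approx(0.0, abs=1e-20)

    def test_zero_gains_cost_one(self, tiny_fixture):
        fx = tiny_fixture
        n = fx.net.n_types
        params = ol.ModelParameters(gains=ol.GainParameters(np.zeros(n), np.zeros(n)))
        assert evaluate(params, fx.net, fx.proto, fx.targets) == pytest.approx(1.0)

    def test_disabled_gate_is_inert(self, tiny_fixture):
        fx = tiny_fixture
        gated = ol.ModelParameters(
            gains=fx.params.gains,
            gate=ol.GateParams(
                g_max=np.zeros(fx.connectome.catalog.n_gated),
                v_mid=-60.0, slope=-0.2, tau_midv=-60.0,
            ),
        )
        c0 = evaluate(fx.params, fx.net, fx.proto, fx.targets)
        c1 = evaluate(gated, fx.net, fx.proto, fx.targets)
        assert c1 == pytest.approx(c0, abs=1e-12)

    def test_matches_public_pipeline(self, tiny_gated_fixture):
        """evaluate() agrees with the composed simulate/filter/extract/cost route."""
        fx = tiny_gated_fixture
        c_eval = evaluate(fx.params, fx.net, fx.proto, fx.targets)
        tensor = ol.measure_receptive_fields(fx.net, fx.params, fx.proto)
        c_pipe = cost(tensor.restrict(fx.targets.type_names), fx.targets)
        assert c_eval == pytest.approx(c_pipe, rel=1e-12)


class TestFit:
    def test_deterministic_under_fixed_seed(self, tiny_fixture):
        fx = tiny_fixture
        cfg = FitConfig(rounds=((40, 0.1), (40, 0.01)), n_restarts=1, base_seed=5)
        a = fit(fx.net, fx.proto, fx.targets, cfg)[0]
        b = fit(fx.net, fx.proto, fx.targets, cfg)[0]
        assert a.final_cost == b.final_cost
        assert np.array_equal(a.cost_trajectory, b.cost_trajectory)

    def test_results_sorted_by_cost(self, tiny_fixture):
        fx = tiny_fixture
        cfg = FitConfig(rounds=((30, 0.1),), n_restarts=3, base_seed=0)
        res = fit(fx.net, fx.proto, fx.targets, cfg)
        costs = [r.final_cost for r in res]
        assert costs == sorted(costs)

    def test_cost_decreases_from_initialization(self, tiny_fixture):
        fx = tiny_fixture
        cfg = FitConfig(rounds=((150, 0.1),), n_restarts=1, base_seed=2, log_every=10)
        r = fit(fx.net, fx.proto, fx.targets, cfg)[0]
        assert r.final_cost < r.cost_trajectory[0, 1]

    def test_divergent_restart_flagged_failed(self, tiny_fixture):
        fx = tiny_fixture
        cfg = FitConfig(
            rounds=((10, 0.1),), n_restarts=2, base_seed=0, gain_range=(200.0, 500.0)
        )
        res = fit(fx.net, fx.proto, fx.targets, cfg)
        assert all(r.failed for r in res)
        assert all(r.final_cost == float("inf") for r in res)

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="non-increasing"):
            FitConfig(rounds=((10, 0.01), (10, 0.1)))
        with pytest.raises(ValueError):
            FitConfig(n_restarts=0)

    def test_reference_schedule_defaults(self):
        cfg = FitConfig()
        assert cfg.rounds == ((10000, 0.1), (10000, 0.01), (10000, 0.001))
        assert cfg.n_restarts == 20

    def test_default_gain_range_scales_with_connectivity(self, tiny_fixture):
        lo, hi = default_gain_range(tiny_fixture.net)
        assert 0 < lo < hi
        w = float(np.mean((tiny_fixture.net.m_exc + tiny_fixture.net.m_inh).sum(axis=1)))
        assert hi / lo == pytest.approx(9.0)
        assert np.sqrt(lo * hi) == pytest.approx(1 / np.sqrt(w * 30.0), rel=1e-9)


class TestAblateGate:
    def test_gains_untouched_and_gmax_zeroed(self, tiny_gated_fixture):
        p = tiny_gated_fixture.params
        a = ablate_gate(p)
        assert np.array_equal(a.gains.inp_gain, p.gains.inp_gain)
        assert np.array_equal(a.gains.out_gain, p.gains.out_gain)
        assert np.all(a.gate.g_max == 0)
        assert a.gate.v_mid == p.gate.v_mid

    def test_idempotent(self, tiny_gated_fixture):
        a = ablate_gate(tiny_gated_fixture.params)
        b = ablate_gate(a)
        assert np.array_equal(constrained_vector(a), constrained_vector(b))

    def test_requires_gate(self, tiny_fixture):
        with pytest.raises(ValueError):
            ablate_gate(tiny_fixture.params)
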
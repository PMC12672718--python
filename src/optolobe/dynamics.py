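"""Conductance-based single-compartment dynamics with an optional H-gate.

Every neuron obeys a current-balance equation: the capacitive current equals
the sum of excitatory synaptic, inhibitory synaptic, leak and gate currents
(plus any injected stimulus current),

    -C_m dV_i/dt = (V_i - E_exc) g_exc,i + (V_i - E_inh) g_inh,i
                   + (V_i - E_leak,i) g_leak + (V_i - E_rev) g_h,i - I_i .

Synaptic conductances are built from the tiled connectivity: each presynaptic
neuron's output is its voltage rectified at a fixed threshold, scaled by its
type's output gain; each postsynaptic neuron scales the weighted sum by its
type's input gain.  The H-gate conductance relaxes toward a logistic
steady-state activation with a bell-shaped voltage-dependent time constant
(in seconds; the membrane integrates in milliseconds, pF/nS = ms).

Integration is explicit (forward) Euler at the protocol resolution of 10 ms
by default; an exponential-Euler scheme is available for stiff synaptic
regimes and convergence checks.  Per step: synaptic conductances from V(t),
gate update from V(t), then the membrane update using the fresh gate value
(frozen-coefficient scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import TiledNetwork
from .parameters import GainParameters, GateParams, ModelParameters  # noqa: F401 (re-export)

__all__ = [
    "NeuronPhysiology",
    "GateParams",
    "GainParameters",
    "SimulationDivergedError",
    "synaptic_conductances",
    "gate_steady_state",
    "gate_time_constant",
    "step_gate",
    "simulate",
]

#: Minimum of the gate time-constant formula, in seconds.
TAU_GATE_FLOOR_S = 0.1


class SimulationDivergedError(RuntimeError):
    """Raised when a membrane trace becomes non-finite (unstable dynamics)."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"simulation diverged at step {step}")


@dataclass(frozen=True)
class NeuronPhysiology:
    """Shared passive membrane constants (per-type E_leak lives in the catalog).

    Defaults give an isolated passive membrane time constant of
    ``C_m / g_leak = 40 ms``.
    """

    c_m_pf: float = 40.0
    g_leak_ns: float = 1.0
    e_exc_mv: float = 10.0
    e_inh_mv: float = -70.0
    trld_mv: float = -50.0

    def __post_init__(self) -> None:
        if self.c_m_pf <= 0 or self.g_leak_ns <= 0:
            raise ValueError("C_m and g_leak must be positive")
        if not self.e_inh_mv < self.trld_mv < self.e_exc_mv:
            raise ValueError("require E_inh < trld < E_exc")

    @property
    def tau_m_ms(self) -> float:
        return self.c_m_pf / self.g_leak_ns


def synaptic_conductances(
    v: np.ndarray,
    gains: GainParameters,
    net: TiledNetwork,
    trld_mv: float = -50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Excitatory and inhibitory conductance of every neuron, in nS.

    ``g_exc[i] = inp_gain(i) * sum_j M_exc[i, j] out_gain(j) max(V_j - trld, 0)``
    and the same form with ``M_inh`` for ``g_inh``.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (net.n_neurons,):
        raise ValueError(f"expected {net.n_neurons} voltages, got {v.shape}")
    t = net.type_of_neuron
    out_n = gains.out_gain[t]
    inp_n = gains.inp_gain[t]
    s = out_n * np.maximum(v - trld_mv, 0.0)
    return inp_n * (net.m_exc @ s), inp_n * (net.m_inh @ s)


def gate_steady_state(v, p: GateParams):
    """Logistic steady-state gate conductance, bounded in ``[0, g_max]``.

    ``g_inf = g_max / (1 + exp((v_mid - v) * slope))``.  A negative slope
    yields activation by hyperpolarization (the H-current case).  ``v`` may be
    scalar or an array matching ``p.g_max`` (broadcasting applies).
    """
    x = np.clip((p.v_mid - np.asarray(v, dtype=float)) * p.slope, -60.0, 60.0)
    return p.g_max / (1.0 + np.exp(x))


def gate_time_constant(v, p: GateParams):
    """Bell-shaped voltage-dependent gate time constant, in seconds.

    ``tau = 1.5 / (e^x + e^-x) + 0.1`` with ``x = (tau_midv - v) * 0.1``;
    strictly positive, even about ``tau_midv`` where it peaks at 0.85 s.
    """
    x = np.clip((p.tau_midv - np.asarray(v, dtype=float)) * 0.1, -300.0, 300.0)
    return 1.5 / (np.exp(x) + np.exp(-x)) + TAU_GATE_FLOOR_S


def step_gate(g_h, v, dt_s: float, p: GateParams, method: str = "euler"):
    """Advance the gate conductance by one step of ``dt_s`` seconds.

    Relaxes ``g_h`` toward :func:`gate_steady_state` with rate
    ``1/gate_time_constant``.  Explicit Euler requires ``dt_s`` below the
    smallest attainable time constant (0.1 s); larger steps are rejected
    (use ``method="exponential"`` instead, which is unconditionally stable).
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    g_inf = gate_steady_state(v, p)
    tau = gate_time_constant(v, p)
    if method == "euler":
        if dt_s >= TAU_GATE_FLOOR_S:
            raise ValueError(
                f"dt = {dt_s} s exceeds the smallest gate time constant "
                f"({TAU_GATE_FLOOR_S} s); explicit Euler would be unstable"
            )
        return g_h + (dt_s / tau) * (g_inf - g_h)
    if method == "exponential":
        return g_inf + (g_h - g_inf) * np.exp(-dt_s / tau)
    raise ValueError(f"unknown method {method!r}")


def _per_neuron_arrays(net: TiledNetwork, params: ModelParameters, phys: NeuronPhysiology):
    """Broadcast per-type parameters to per-neuron vectors."""
    t = net.type_of_neuron
    inp_n = params.gains.inp_gain[t]
    out_n = params.gains.out_gain[t]
    e_leak_n = net.catalog.e_leak_mv[t]
    gmax_n = np.zeros(net.n_neurons)
    if params.gate is not None:
        gmax_type = np.zeros(net.n_types)
        gmax_type[net.catalog.gated_indices] = params.gate.g_max
        gmax_n = gmax_type[t]
    return inp_n, out_n, e_leak_n, gmax_n


def _integrate(
    net: TiledNetwork,
    params: ModelParameters,
    currents_pa: np.ndarray,
    dt_s: float,
    phys: NeuronPhysiology,
    method: str = "euler",
    record_gate: bool = False,
):
    """Core integrator.  Returns ``(v_hist, gh_hist)``, each ``(n_neurons, T)``.

    ``currents_pa[:, k]`` is the injected current over ``[k dt, (k+1) dt)``;
    trace sample ``k`` is the state at time ``k dt`` (sample 0 = initial
    condition).  ``gh_hist`` is ``None`` unless ``record_gate`` (or a gate is
    present and recording is needed for backpropagation).
    """
    n, t_steps = currents_pa.shape
    if n != net.n_neurons:
        raise ValueError("current matrix does not match network size")
    dt_ms = dt_s * 1e3
    inp_n, out_n, e_leak_n, gmax_n = _per_neuron_arrays(net, params, phys)
    gate = params.gate

    v = e_leak_n.copy()
    gh = np.zeros(n)
    if gate is not None:
        x = np.clip((gate.v_mid - v) * gate.slope, -60.0, 60.0)
        gh = gmax_n / (1.0 + np.exp(x))

    v_hist = np.empty((n, t_steps))
    v_hist[:, 0] = v
    gh_hist = None
    if record_gate:
        gh_hist = np.empty((n, t_steps))
        gh_hist[:, 0] = gh

    m_exc, m_inh = net.m_exc, net.m_inh
    trld = phys.trld_mv
    gl = phys.g_leak_ns
    ee, ei = phys.e_exc_mv, phys.e_inh_mv
    c_m = phys.c_m_pf

    # overflow in a diverging trajectory is caught by the finiteness check,
    # so arithmetic warnings on the way there are noise
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(1, t_steps):
            s = out_n * np.maximum(v - trld, 0.0)
            ge = inp_n * (m_exc @ s)
            gi = inp_n * (m_inh @ s)
            if gate is not None:
                g_inf = gmax_n / (1.0 + np.exp(np.clip((gate.v_mid - v) * gate.slope, -60.0, 60.0)))
                xx = np.clip((gate.tau_midv - v) * 0.1, -300.0, 300.0)
                tau_ms = 1e3 * (1.5 / (np.exp(xx) + np.exp(-xx)) + TAU_GATE_FLOOR_S)
                if method == "exponential":
                    gh = g_inf + (gh - g_inf) * np.exp(-dt_ms / tau_ms)
                else:
                    gh = gh + (dt_ms / tau_ms) * (g_inf - gh)
            i_in = currents_pa[:, k - 1]
            if method == "exponential":
                g_tot = ge + gi + gl + gh
                v_inf = (ee * ge + ei * gi + e_leak_n * gl + gate.e_rev * gh + i_in) / g_tot \
                    if gate is not None else (ee * ge + ei * gi + e_leak_n * gl + i_in) / g_tot
                v = v_inf + (v - v_inf) * np.exp(-dt_ms * g_tot / c_m)
            else:
                f = (ee - v) * ge + (ei - v) * gi + (e_leak_n - v) * gl + i_in
                if gate is not None:
                    f = f + (gate.e_rev - v) * gh
                v = v + (dt_ms / c_m) * f
            if not np.all(np.isfinite(v)):
                raise SimulationDivergedError(k)
            v_hist[:, k] = v
            if record_gate:
                gh_hist[:, k] = gh
    return v_hist, gh_hist


def simulate(
    net: TiledNetwork,
    params: ModelParameters,
    stim,
    phys: NeuronPhysiology | None = None,
    method: str = "euler",
) -> np.ndarray:
    """Integrate the full network under a stimulus protocol.

    Parameters
    ----------
    net
        Tiled multi-column network.
    params
        Model parameters (gains, optional gate).
    stim
        Either a :class:`~optolobe.protocol.StimulusProtocol` (its per-neuron
        current matrix is built for ``net``) or a raw ``(n_neurons, T)``
        current array in pA paired with the protocol's ``dt``; in the latter
        case pass a tuple ``(currents, dt_s)``.
    phys
        Shared passive membrane constants; defaults to the reference values.
    method
        ``"euler"`` (default, the protocol's scheme) or ``"exponential"``.

    Returns
    -------
    numpy.ndarray
        Raw voltage traces, shape ``(n_neurons, T)``, in mV.
    """
    phys = phys or NeuronPhysiology()
    if isinstance(stim, tuple):
        currents, dt_s = stim
    else:
        currents = stim.current_matrix(net)
        dt_s = stim.dt_s
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    v_hist, _ = _integrate(net, params, np.asarray(currents, float), dt_s, phys, method)
    return v_hist
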
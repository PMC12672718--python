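"""Free-parameter containers and the unconstrained parameter vector.

The optimizable quantities of the circuit model are per-type input and output
gains plus, optionally, the hyperpolarization-activated (H) conductance
parameters: one maximal conductance per gated type and three shared voltage
parameters (half-activation voltage, slope, voltage of peak time constant).

Gains and maximal conductances are non-negative by construction: the
optimizer works on an unconstrained vector ``z`` and the physical values are
obtained through a softplus map.  With the reference catalog (65 types, 5
gated lamina types) the vector has 130 entries without the gate and 138 with
it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network_model import CellTypeCatalog

__all__ = [
    "GainParameters",
    "GateParams",
    "ModelParameters",
    "n_parameters",
    "softplus",
    "softplus_inv",
]


def softplus(x):
    """Numerically stable ``log(1 + exp(x))``."""
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    """Inverse of :func:`softplus` for strictly positive ``y``."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("softplus_inv requires strictly positive values")
    # y + log(1 - e^{-y}) is stable for both small and large y
    return y + np.log(-np.expm1(-y))


@dataclass(frozen=True)
class GainParameters:
    """Per-type input and output gains (non-negative, shared across columns)."""

    inp_gain: np.ndarray
    out_gain: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("inp_gain", "out_gain"):
            g = np.asarray(getattr(self, attr), dtype=float)
            if g.ndim != 1:
                raise ValueError(f"{attr} must be a 1-D per-type array")
            if np.any(~np.isfinite(g)) or np.any(g < 0):
                raise ValueError(f"{attr} must be finite and non-negative")
            object.__setattr__(self, attr, g)
        if self.inp_gain.shape != self.out_gain.shape:
            raise ValueError("inp_gain and out_gain must have equal length")

    @property
    def n_types(self) -> int:
        return self.inp_gain.size


@dataclass(frozen=True)
class GateParams:
    """Hyperpolarization-activated conductance parameters.

    ``g_max`` holds one maximal conductance (nS) per *gated* catalog type, in
    catalog order of the gated types.  ``v_mid`` (mV) and ``slope`` (1/mV,
    signed; negative = activated by hyperpolarization) shape the logistic
    steady-state activation; ``tau_midv`` (mV) is the voltage of the peak of
    the bell-shaped time constant.  ``e_rev`` (mV) is the gate's reversal
    potential (fixed, not optimized).
    """

    g_max: np.ndarray
    v_mid: float
    slope: float
    tau_midv: float
    e_rev: float = -30.0

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.g_max, dtype=float))
        if np.any(~np.isfinite(g)) or np.any(g < 0):
            raise ValueError("g_max must be finite and non-negative")
        object.__setattr__(self, "g_max", g)
        for attr in ("v_mid", "slope", "tau_midv", "e_rev"):
            v = float(getattr(self, attr))
            if not np.isfinite(v):
                raise ValueError(f"{attr} must be finite")
            object.__setattr__(self, attr, v)

    def validate(self) -> None:
        if np.any(self.g_max > 0) and self.slope == 0.0:
            raise ValueError("slope must be nonzero when any g_max > 0")


@dataclass(frozen=True)
class ModelParameters:
    """The full optimizable parameter set (the vector ``z``, constrained form).

    ``gate is None`` means the model has no voltage-gated conductance; an
    *ablated* model keeps its gate object but with all ``g_max`` zeroed.
    """

    gains: GainParameters
    gate: GateParams | None = None

    @property
    def gate_enabled(self) -> bool:
        return self.gate is not None

    def n_parameters(self) -> int:
        n = 2 * self.gains.n_types
        if self.gate is not None:
            n += self.gate.g_max.size + 3
        return n


def n_parameters(catalog: CellTypeCatalog, gate_enabled: bool) -> int:
    """Length of the free-parameter vector for a catalog."""
    n = 2 * catalog.n_types
    if gate_enabled:
        n += catalog.n_gated + 3
    return n


def params_to_vector(params: ModelParameters) -> np.ndarray:
    """Unconstrained vector: softplus-inverse gains (+ gate block if present).

    Layout: ``[raw_inp (n_types), raw_out (n_types), raw_g_max (n_gated),
    v_mid, slope, tau_midv]``.  Zero gains are clipped to a tiny positive
    value before inversion.
    """
    eps = 1e-12
    parts = [
        softplus_inv(np.maximum(params.gains.inp_gain, eps)),
        softplus_inv(np.maximum(params.gains.out_gain, eps)),
    ]
    if params.gate is not None:
        parts.append(softplus_inv(np.maximum(params.gate.g_max, eps)))
        parts.append(np.array([params.gate.v_mid, params.gate.slope, params.gate.tau_midv]))
    return np.concatenate(parts)


def vector_to_params(
    z: np.ndarray,
    catalog: CellTypeCatalog,
    gate_enabled: bool,
    e_rev: float = -30.0,
) -> ModelParameters:
    """Map an unconstrained vector back to constrained model parameters."""
    z = np.asarray(z, dtype=float)
    expected = n_parameters(catalog, gate_enabled)
    if z.shape != (expected,):
        raise ValueError(f"expected parameter vector of length {expected}, got {z.shape}")
    n = catalog.n_types
    gains = GainParameters(inp_gain=softplus(z[:n]), out_gain=softplus(z[n : 2 * n]))
    gate = None
    if gate_enabled:
        k = catalog.n_gated
        gate = GateParams(
            g_max=softplus(z[2 * n : 2 * n + k]),
            v_mid=float(z[2 * n + k]),
            slope=float(z[2 * n + k + 1]),
            tau_midv=float(z[2 * n + k + 2]),
            e_rev=e_rev,
        )
    return ModelParameters(gains=gains, gate=gate)


def constrained_vector(params: ModelParameters) -> np.ndarray:
    """Physical-scale parameter vector (gains, g_max, gate voltages).

    This is the vector on which cross-model Pearson correlations and
    parameter summaries are computed.
    """
    parts = [params.gains.inp_gain, params.gains.out_gain]
    if params.gate is not None:
        parts.append(params.gate.g_max)
        parts.append(np.array([params.gate.v_mid, params.gate.slope, params.gate.tau_midv]))
    return np.concatenate(parts)


def ablate_gate(params: ModelParameters) -> ModelParameters:
    """Zero every maximal gate conductance, leaving all else untouched.

    Models the experiment of switching off the H-current in a network whose
    parameters were optimized with the current present.  Idempotent.
    """
    if params.gate is None:
        raise ValueError("cannot ablate a model without a gate")
    return ModelParameters(
        gains=params.gains,
        gate=replace(params.gate, g_max=np.zeros_like(params.gate.g_max)),
    )
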
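"""Preparation of experimental (or synthetic) target response tensors.

Measured receptive fields typically arrive as normalized impulse responses
with no absolute voltage scale.  The pipeline converts them to step responses
by running time integration, rescales so the global peak magnitude equals a
chosen voltage (reference: 20 mV), and, for tonically active types such as
the first two lamina monopolar cells, adds a standing DC offset of a fixed
fraction of that type's peak (reference: 40%) to the post-onset samples.

Order matters and is enforced: integrate, normalize, then add DC.
Re-normalizing after the DC step would silently break the fraction-of-peak
semantics, so a prepared :class:`TargetSet` refuses it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .protocol import ResponseTensor

__all__ = [
    "TargetSet",
    "impulse_to_step",
    "normalize_targets",
    "add_dc",
    "prepare_target_set",
]


def impulse_to_step(values: np.ndarray, dt_s: float) -> np.ndarray:
    """Cumulative time integral along the last axis (running sum x dt).

    Converts impulse responses to step responses; linear, and commutes with
    any global rescaling.
    """
    return np.cumsum(np.asarray(values, float), axis=-1) * dt_s


def normalize_targets(
    values: np.ndarray, peak_mv: float = 20.0, per_type: bool = False
) -> tuple[np.ndarray, np.ndarray | float]:
    """Scale responses so the peak magnitude equals ``peak_mv``.

    By default one *global* factor is applied to every entry (preserving the
    relative amplitudes between cell types); ``per_type=True`` instead scales
    each type's sub-tensor independently.  Returns ``(scaled, factor)``.
    """
    if peak_mv <= 0:
        raise ValueError("peak_mv must be positive")
    v = np.asarray(values, float)
    if per_type:
        peaks = np.max(np.abs(v), axis=tuple(range(1, v.ndim)), keepdims=True)
        if np.any(peaks == 0):
            raise ValueError("cannot normalize an all-zero type response")
        factor = peak_mv / peaks
        return v * factor, factor.squeeze()
    peak = float(np.max(np.abs(v)))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero tensor")
    factor = peak_mv / peak
    return v * factor, factor


def add_dc(
    tensor: ResponseTensor, dc_types, dc_fraction: float
) -> ResponseTensor:
    """Add a standing offset to the step responses of selected types.

    For each listed type, a constant equal to ``dc_fraction`` times that
    type's peak post-onset response *magnitude* is added to every post-onset
    sample; pre-onset samples stay zero.  Other types are untouched.
    """
    if dc_fraction < 0:
        raise ValueError("dc_fraction must be >= 0")
    dc_types = tuple(dc_types)
    if not dc_types:
        raise ValueError("dc_types must be a nonempty subset of tensor types")
    values = tensor.values.copy()
    on = tensor.onset_index
    for name in dc_types:
        if name not in tensor.types:
            raise KeyError(f"unknown type {name!r}")
        i = tensor.types.index(name)
        peak = np.max(np.abs(values[i, :, on:]))
        values[i, :, on:] += dc_fraction * peak
    return replace(tensor, values=values)


@dataclass(frozen=True)
class TargetSet:
    """Prepared target tensor plus the preparation bookkeeping.

    ``tensor`` holds the (possibly noisy) target step responses in mV over
    the observed types only.  ``scale_factor`` records the normalization
    applied (``None`` for targets generated directly in mV).
    """

    tensor: ResponseTensor
    dc_types: tuple[str, ...] = ()
    dc_fraction: float = 0.0
    peak_mv: float | None = None
    scale_factor: float | np.ndarray | None = None
    dc_applied: bool = False

    @property
    def type_names(self) -> tuple[str, ...]:
        return self.tensor.types

    @property
    def n_types(self) -> int:
        return len(self.tensor.types)

    def normalized(self, *_args, **_kwargs):
        raise RuntimeError(
            "TargetSet is already prepared; re-normalizing after the DC "
            "offset would break the fraction-of-peak semantics"
        )


def prepare_target_set(
    tensor: ResponseTensor,
    kind: str = "impulse",
    peak_mv: float = 20.0,
    dc_types=(),
    dc_fraction: float = 0.4,
    per_type: bool = False,
) -> TargetSet:
    """Run the full preparation pipeline in its required order.

    ``kind="impulse"`` integrates to step responses first; ``kind="step"``
    skips integration.  Then one normalization pass, then (if ``dc_types``)
    the DC offsets.
    """
    if kind not in ("impulse", "step"):
        raise ValueError("kind must be 'impulse' or 'step'")
    values = tensor.values
    if kind == "impulse":
        dt = float(tensor.times_s[1] - tensor.times_s[0])
        values = impulse_to_step(values, dt)
    values, factor = normalize_targets(values, peak_mv, per_type=per_type)
    prepared = replace(tensor, values=values)
    applied = False
    if dc_types:
        prepared = add_dc(prepared, dc_types, dc_fraction)
        applied = True
    return TargetSet(
        tensor=prepared,
        dc_types=tuple(dc_types),
        dc_fraction=dc_fraction,
        peak_mv=peak_mv,
        scale_factor=factor,
        dc_applied=applied,
    )
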
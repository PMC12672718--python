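"""Synthetic connectomes and ground-truth targets for end-to-end testing.

The generator emulates the structure of the real inputs without any
download: signed, sparse, Dale-consistent synapse-count matrices over a
catalog with designated photoreceptor and lamina-like types, ground-truth
gain/gate parameters that genuinely produce transient (sag/rebound) and
sustained step responses, and target tensors obtained by running the
measurement pipeline on the ground truth (optionally with additive noise and
restricted to an observed subset of types, mirroring the partial-observability
regime of fitting 13 of 65 cell types).

Photoreceptors are assigned a negative (histamine-like) sign, and every
lamina-like type is guaranteed at least one photoreceptor input, so light
steps hyperpolarize the first-order interneurons as in the fly lamina.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network_model import CellTypeCatalog, SignedConnectome, TiledNetwork, tile_network
from .parameters import GainParameters, GateParams, ModelParameters
from .protocol import StimulusProtocol, build_stimulus, measure_receptive_fields
from .target_data import TargetSet

__all__ = [
    "SynthSpec",
    "gen_connectome",
    "gen_ground_truth",
    "gen_targets",
    "make_fixture",
    "Fixture",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the reference configuration: 65 cell types per column,
    5 columns, 8 photoreceptor types, 5 lamina-like types all carrying the
    gate, noiseless targets.  ``density``/``inter_density`` are the fractions
    of nonzero off-diagonal entries; counts are uniform on
    ``[1, max_synapses]``.
    """

    n_types: int = 65
    n_columns: int = 5
    density: float = 0.15
    inter_density: float = 0.05
    max_synapses: int = 50
    frac_inhibitory: float = 0.5
    n_photoreceptors: int = 8
    n_lamina: int = 5
    n_gated: int = 5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.density <= 1 and 0 <= self.inter_density <= 1):
            raise ValueError("densities must lie in [0, 1]")
        if not 0 <= self.frac_inhibitory <= 1:
            raise ValueError("frac_inhibitory must lie in [0, 1]")
        if self.n_photoreceptors < 1:
            raise ValueError("need at least one photoreceptor type")
        if self.n_gated > self.n_lamina:
            raise ValueError("n_gated cannot exceed n_lamina")
        if self.n_types < self.n_photoreceptors + self.n_lamina:
            raise ValueError("n_types too small for the requested photoreceptors + lamina")
        if self.max_synapses < 1:
            raise ValueError("max_synapses must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _make_catalog(spec: SynthSpec) -> CellTypeCatalog:
    n_pr, n_lam = spec.n_photoreceptors, spec.n_lamina
    n_other = spec.n_types - n_pr - n_lam
    names = (
        [f"R{i + 1}" for i in range(n_pr)]
        + [f"L{i + 1}" for i in range(n_lam)]
        + [f"M{i + 1:02d}" for i in range(n_other)]
    )
    is_pr = np.zeros(spec.n_types, bool)
    is_pr[:n_pr] = True
    is_lam = np.zeros(spec.n_types, bool)
    is_lam[n_pr : n_pr + n_lam] = True
    is_gated = np.zeros(spec.n_types, bool)
    is_gated[n_pr : n_pr + spec.n_gated] = True
    # first up-to-3 lamina types are tonically depolarized (L1-L3 analog)
    e_leak = np.full(spec.n_types, -50.0)
    e_leak[n_pr : n_pr + min(3, n_lam)] = -20.0
    return CellTypeCatalog(
        names=tuple(names),
        is_photoreceptor=is_pr,
        is_lamina=is_lam,
        e_leak_mv=e_leak,
        is_gated=is_gated,
    )


def gen_connectome(spec: SynthSpec) -> SignedConnectome:
    """Random signed, Dale-consistent intra/inter synapse-count matrices.

    Each presynaptic type is assigned a single sign applied to all its
    outgoing entries; photoreceptors are always negative (histamine-like).
    Every lamina type is guaranteed a photoreceptor input and every
    non-photoreceptor type at least one input from the photoreceptor/lamina
    pool, so the stimulus drives the whole circuit.  Reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cat = _make_catalog(spec)
    n = spec.n_types
    signs = np.where(rng.random(n) < spec.frac_inhibitory, -1, 1)
    signs[cat.is_photoreceptor] = -1

    def random_counts(density: float) -> np.ndarray:
        mask = rng.random((n, n)) < density
        np.fill_diagonal(mask, False)
        counts = rng.integers(1, spec.max_synapses + 1, size=(n, n))
        return np.where(mask, counts, 0)

    intra = random_counts(spec.density)
    inter = random_counts(spec.inter_density)
    if spec.density > 0:
        # connectivity guarantees so the stimulus drives the whole circuit;
        # skipped for deliberately empty (zero-density) matrices
        pr = cat.photoreceptor_indices
        lam = np.flatnonzero(cat.is_lamina)
        drivers = np.concatenate([pr, lam]) if lam.size else pr
        for i in lam:  # lamina must hear the photoreceptors
            if intra[i, pr].sum() == 0:
                intra[i, rng.choice(pr)] = rng.integers(
                    max(1, spec.max_synapses // 2), spec.max_synapses + 1
                )
        for i in range(n):  # everything else needs a driven input path
            if cat.is_photoreceptor[i]:
                continue
            if intra[i].sum() == 0:
                intra[i, rng.choice(drivers)] = rng.integers(1, spec.max_synapses + 1)
    intra = intra * signs[np.newaxis, :]
    inter = inter * signs[np.newaxis, :]
    return SignedConnectome(intra=intra, inter=inter, catalog=cat)


def gen_ground_truth(spec: SynthSpec, connectome: SignedConnectome) -> ModelParameters:
    """Random ground-truth parameters that produce rich, stable dynamics.

    Gains are drawn log-uniformly from the connectivity-derived
    initialization range (see :func:`optolobe.fitting.default_gain_range`).
    When the spec requests gated types, the gate activates under
    hyperpolarization (negative slope) with its half-activation voltage
    placed inside the gated cells' simulated operating range - where real
    HCN channels sit relative to their cell's excursions - so the ground
    truth genuinely produces sag/rebound transients in the targets.
    """
    from .dynamics import simulate
    from .fitting import default_gain_range

    rng = np.random.default_rng(spec.seed + 1_000_003)
    cat = connectome.catalog
    net = tile_network(connectome, spec.n_columns)
    lo, hi = default_gain_range(net)
    gains = GainParameters(
        inp_gain=np.exp(rng.uniform(np.log(lo), np.log(hi), cat.n_types)),
        out_gain=np.exp(rng.uniform(np.log(lo), np.log(hi), cat.n_types)),
    )
    gate = None
    if spec.n_gated > 0:
        # passive run to locate the gated cells' voltage excursion under the
        # stimulus; half-activation goes to the middle of that excursion
        proto = build_stimulus(cat, spec.n_columns)
        v = simulate(net, ModelParameters(gains=gains), proto)
        rows = [
            net.neuron_index(int(t), net.center_column) for t in cat.gated_indices
        ]
        on = proto.onset_index
        baseline = float(np.mean(v[rows, on - 1]))
        v_low = float(np.min(v[rows, on:]))
        v_half = 0.5 * (baseline + v_low)
        gate = GateParams(
            g_max=rng.uniform(3.0, 8.0, cat.n_gated),
            v_mid=v_half + rng.uniform(-2.0, 2.0),
            slope=rng.uniform(-0.3, -0.1),
            tau_midv=v_half + rng.uniform(-5.0, 5.0),
        )
    return ModelParameters(gains=gains, gate=gate)


def gen_targets(
    connectome: SignedConnectome,
    params: ModelParameters,
    n_columns: int,
    subset,
    noise_sd: float = 0.0,
    seed: int = 0,
    proto: StimulusProtocol | None = None,
) -> TargetSet:
    """Target tensor from the ground truth: simulate, filter, extract, noise.

    Restricted to ``subset`` (observed types); independent Gaussian noise of
    SD ``noise_sd`` mV is added to post-onset samples (pre-onset samples stay
    exactly zero, as the tensor convention requires).  Already in mV - no
    re-normalization is applied.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("observed subset must be nonempty")
    net = tile_network(connectome, n_columns)
    if proto is None:
        proto = build_stimulus(connectome.catalog, n_columns)
    tensor = measure_receptive_fields(net, params, proto).restrict(subset)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = tensor.values.copy()
        on = tensor.onset_index
        noisy[..., on:] += rng.normal(0.0, noise_sd, noisy[..., on:].shape)
        tensor = replace(tensor, values=noisy)
    return TargetSet(tensor=tensor)


@dataclass(frozen=True)
class Fixture:
    """A complete synthetic experiment bundle."""

    spec: SynthSpec
    connectome: SignedConnectome
    net: TiledNetwork
    params: ModelParameters
    proto: StimulusProtocol
    targets: TargetSet


def make_fixture(spec: SynthSpec, subset=None) -> Fixture:
    """Generate connectome, ground truth, protocol and targets in one call.

    ``subset`` defaults to all non-photoreceptor types (interneurons are the
    observed population); pass an explicit tuple for partial observability.
    """
    connectome = gen_connectome(spec)
    cat = connectome.catalog
    params = gen_ground_truth(spec, connectome)
    net = tile_network(connectome, spec.n_columns)
    proto = build_stimulus(cat, spec.n_columns)
    if subset is None:
        subset = tuple(np.asarray(cat.names)[~cat.is_photoreceptor])
    targets = gen_targets(
        connectome, params, spec.n_columns, subset,
        noise_sd=spec.noise_sd, seed=spec.seed + 7, proto=proto,
    )
    return Fixture(spec, connectome, net, params, proto, targets)
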
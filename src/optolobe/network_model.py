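"""Cell-type catalog, signed connectivity, and multi-column network assembly.

The circuit is described at the level of *cell types*: a signed synapse-count
matrix within one optical column (``intra``) and one between a column and its
immediate neighbor (``inter``).  Tiling replicates the type set across a linear
array of columns and splits the signed counts into separate excitatory and
inhibitory weight matrices with non-negative entries.

Matrix orientation convention (used everywhere in this package): entry
``M[i, j]`` is the number of synapses from presynaptic type/neuron ``j`` onto
postsynaptic type/neuron ``i``, matching the summation index of the synaptic
conductance equations in :mod:`optolobe.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellTypeCatalog",
    "SignedConnectome",
    "TiledNetwork",
    "split_signed_matrix",
    "tile_network",
]


@dataclass(frozen=True)
class CellTypeCatalog:
    """Ordered catalog of columnar cell types.

    Parameters
    ----------
    names
        Unique type identifiers, in matrix order.
    is_photoreceptor
        Flag per type; photoreceptors receive the injected stimulus current.
    is_lamina
        Flag per type; lamina monopolar cells are tonically active first-order
        interneurons (some have a depolarized leak reversal).
    e_leak_mv
        Leak reversal potential per type, in mV.
    is_gated
        Flag per type; gated types carry the hyperpolarization-activated
        conductance when the model's gate is enabled.  Defaults to
        ``is_lamina``.
    target_names
        Optional per-type name of the matching experimental target trace
        (``None`` for unobserved types).
    """

    names: tuple[str, ...]
    is_photoreceptor: np.ndarray
    is_lamina: np.ndarray
    e_leak_mv: np.ndarray
    is_gated: np.ndarray | None = None
    target_names: tuple[str | None, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("cell-type names must be unique")
        object.__setattr__(self, "names", tuple(self.names))
        for attr in ("is_photoreceptor", "is_lamina"):
            arr = np.asarray(getattr(self, attr), dtype=bool)
            if arr.shape != (n,):
                raise ValueError(f"{attr} must have one entry per type")
            object.__setattr__(self, attr, arr)
        e = np.asarray(self.e_leak_mv, dtype=float)
        if e.shape != (n,) or not np.all(np.isfinite(e)):
            raise ValueError("e_leak_mv must be finite, one entry per type")
        object.__setattr__(self, "e_leak_mv", e)
        if not self.is_photoreceptor.any():
            raise ValueError("catalog needs at least one photoreceptor type")
        gated = self.is_gated
        gated = self.is_lamina.copy() if gated is None else np.asarray(gated, bool)
        if gated.shape != (n,):
            raise ValueError("is_gated must have one entry per type")
        object.__setattr__(self, "is_gated", gated)
        tn = self.target_names
        tn = tuple([None] * n) if tn is None else tuple(tn)
        if len(tn) != n:
            raise ValueError("target_names must have one entry per type")
        present = [t for t in tn if t]
        if len(present) != len(set(present)):
            raise ValueError("each target name may be assigned to one type only")
        object.__setattr__(self, "target_names", tn)

    @property
    def n_types(self) -> int:
        return len(self.names)

    @property
    def n_gated(self) -> int:
        return int(self.is_gated.sum())

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown cell type {name!r}") from None

    @property
    def photoreceptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_photoreceptor)

    @property
    def gated_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_gated)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "is_photoreceptor": self.is_photoreceptor.astype(int),
                "is_lamina": self.is_lamina.astype(int),
                "is_gated": self.is_gated.astype(int),
                "E_leak_mV": self.e_leak_mv,
                "target_name": ["" if t is None else t for t in self.target_names],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellTypeCatalog":
        kwargs = {}
        if "is_gated" in df.columns:
            kwargs["is_gated"] = df["is_gated"].astype(bool).to_numpy()
        targets = None
        if "target_name" in df.columns:
            targets = tuple(
                None if (pd.isna(t) or str(t) == "") else str(t)
                for t in df["target_name"]
            )
        return cls(
            names=tuple(str(n) for n in df["name"]),
            is_photoreceptor=df["is_photoreceptor"].astype(bool).to_numpy(),
            is_lamina=df["is_lamina"].astype(bool).to_numpy(),
            e_leak_mv=df["E_leak_mV"].to_numpy(dtype=float),
            target_names=targets,
            **kwargs,
        )


def _check_dale(intra: np.ndarray, inter: np.ndarray, names) -> None:
    """Each presynaptic type must act with one sign across both matrices."""
    for j in range(intra.shape[1]):
        col = np.concatenate([intra[:, j], inter[:, j]])
        nz = col[col != 0]
        if nz.size and not (np.all(nz > 0) or np.all(nz < 0)):
            raise ValueError(
                f"Dale consistency violated for presynaptic type {names[j]!r}: "
                "outgoing synapse counts mix signs"
            )


@dataclass(frozen=True)
class SignedConnectome:
    """Signed intra- and inter-columnar synapse-count matrices.

    ``intra[i, j]``: synapses from type ``j`` onto type ``i`` within one
    column.  ``inter[i, j]``: synapses from type ``j`` in a column onto type
    ``i`` in an immediately neighboring column (applied identically to the
    left and right neighbor).  Signs encode the presynaptic transmitter.
    """

    intra: np.ndarray
    inter: np.ndarray
    catalog: CellTypeCatalog

    def __post_init__(self) -> None:
        n = self.catalog.n_types
        for attr in ("intra", "inter"):
            m = np.asarray(getattr(self, attr))
            if m.shape != (n, n):
                raise ValueError(f"{attr} must be {n}x{n} to match the catalog")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{attr} contains non-finite entries")
            if not np.all(m == np.round(m)):
                raise ValueError(f"{attr} entries must be integer synapse counts")
            object.__setattr__(self, attr, m.astype(float))
        _check_dale(self.intra, self.inter, self.catalog.names)

    @property
    def n_types(self) -> int:
        return self.catalog.n_types

    def presynaptic_signs(self) -> np.ndarray:
        """Sign (+1/-1/0) of each presynaptic type's outgoing connections."""
        signs = np.zeros(self.n_types, dtype=int)
        for j in range(self.n_types):
            col = np.concatenate([self.intra[:, j], self.inter[:, j]])
            nz = col[col != 0]
            if nz.size:
                signs[j] = 1 if nz[0] > 0 else -1
        return signs


def split_signed_matrix(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a signed matrix into non-negative excitatory/inhibitory parts.

    Returns ``(m_exc, m_inh)`` with ``m_exc - m_inh == m`` elementwise.
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        bad = np.argwhere(~np.isfinite(m))
        raise ValueError(f"non-finite entries at indices {bad.tolist()[:10]}")
    return np.maximum(m, 0.0), np.maximum(-m, 0.0)


@dataclass(frozen=True)
class TiledNetwork:
    """The full linear multi-column network.

    Neurons are indexed column-major by column: neuron ``c * n_types + t`` is
    type ``t`` in column ``c``.  ``m_exc`` and ``m_inh`` are non-negative
    weight matrices over all neurons with nonzeros only in same-column and
    adjacent-column blocks (boundary columns are truncated, no wraparound).
    """

    n_columns: int
    m_exc: np.ndarray
    m_inh: np.ndarray
    catalog: CellTypeCatalog
    type_of_neuron: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.catalog.n_types * self.n_columns
        if self.m_exc.shape != (n, n) or self.m_inh.shape != (n, n):
            raise ValueError("weight matrices must cover all neurons")
        object.__setattr__(
            self,
            "type_of_neuron",
            np.tile(np.arange(self.catalog.n_types), self.n_columns),
        )

    @property
    def n_types(self) -> int:
        return self.catalog.n_types

    @property
    def n_neurons(self) -> int:
        return self.n_types * self.n_columns

    @property
    def center_column(self) -> int:
        return self.n_columns // 2

    def neuron_index(self, type_name: str | int, column: int) -> int:
        """Flat neuron index of ``type_name`` in ``column`` (bijective)."""
        t = type_name if isinstance(type_name, (int, np.integer)) else self.catalog.index_of(type_name)
        if not 0 <= t < self.n_types:
            raise KeyError(f"type index {t} out of range")
        if not 0 <= column < self.n_columns:
            raise IndexError(f"column {column} out of range [0, {self.n_columns})")
        return int(column) * self.n_types + int(t)

    def neuron_location(self, index: int) -> tuple[str, int]:
        """Inverse of :meth:`neuron_index`: ``(type name, column)``."""
        if not 0 <= index < self.n_neurons:
            raise IndexError(f"neuron index {index} out of range")
        column, t = divmod(int(index), self.n_types)
        return self.catalog.names[t], column


def tile_network(connectome: SignedConnectome, n_columns: int) -> TiledNetwork:
    """Tile intra+inter connectivity across a linear array of columns.

    Same-column blocks carry the intra matrix; blocks from column ``c`` onto
    ``c - 1`` and ``c + 1`` carry the inter matrix (one matrix, applied
    identically to both neighbors).  The signed assembly is then split into
    excitatory and inhibitory parts.  Deterministic: identical inputs give
    bit-identical matrices.
    """
    if n_columns < 1:
        raise ValueError("n_columns must be >= 1")
    n = connectome.n_types
    total = n * n_columns
    signed = np.zeros((total, total))

    def block(i: int, j: int):
        return np.s_[i * n : (i + 1) * n, j * n : (j + 1) * n]

    for c in range(n_columns):
        signed[block(c, c)] = connectome.intra
        if c > 0:
            signed[block(c - 1, c)] = connectome.inter
        if c < n_columns - 1:
            signed[block(c + 1, c)] = connectome.inter
    m_exc, m_inh = split_signed_matrix(signed)
    return TiledNetwork(
        n_columns=n_columns, m_exc=m_exc, m_inh=m_inh, catalog=connectome.catalog
    )
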
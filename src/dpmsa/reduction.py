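"""Quantization of continuous profiles to discrete symbol strings.

The quantizer must keep up with an accelerated pairwise aligner, so it is a
constant-time *near*-neighbor lookup rather than an exact nearest-neighbor
search: each frequency is scaled by Q and truncated, and the resulting
integer tuple indexes a precomputed table mapping cells to codebook symbols.
Only cells that can actually contain a point of the simplex are stored (the
truncated coordinates lie within a scaled distance (D-1)*eps of the
hyperplane), which makes the table ragged: a tiny fraction of the dense Q^D
grid.

Each stored cell references the codebook point nearest to the cell's center
projected onto the simplex.  For any query x in a cell of side 1/Q this
bounds the excess distance over the true nearest neighbor by twice the
cell-center distance, i.e. sqrt(D)/Q — small compared with the codebook's
own lattice spacing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .profile_space import SamplePointCodebook, project_to_simplex

__all__ = [
    "ReductionTable",
    "DiscreteProfile",
    "build_reduction_table",
    "reduce_profile",
    "nearest_sample_point",
]


@dataclass(frozen=True)
class DiscreteProfile:
    """A profile reduced to a string of codebook symbols."""

    symbols: np.ndarray  # (length,) int64
    K: int  # codebook size the symbols refer to

    def __post_init__(self) -> None:
        syms = np.asarray(self.symbols, dtype=np.int64)
        object.__setattr__(self, "symbols", syms)
        if syms.size and (syms.min() < 0 or syms.max() >= self.K):
            raise ValueError("discrete profile contains symbols outside the codebook")

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass(frozen=True)
class ReductionTable:
    """Ragged lookup table from truncated integer coordinates to symbols.

    Cells are keyed by the mixed-radix encoding ``sum_i g_i * Q**i`` of their
    integer coordinates and held as a sorted key array plus parallel symbol
    array, so a batch of lookups is two vectorized operations.
    """

    scale: int  # Q: quantization levels per axis
    keys: np.ndarray  # sorted (n_cells,) int64 encoded coordinates
    cell_symbols: np.ndarray  # (n_cells,) int64
    codebook: SamplePointCodebook

    @property
    def n_cells(self) -> int:
        return int(self.keys.size)

    @property
    def dense_cells(self) -> int:
        return int(self.scale ** self.codebook.alphabet.D)

    def _encode(self, indices: np.ndarray) -> np.ndarray:
        D = self.codebook.alphabet.D
        powers = self.scale ** np.arange(D, dtype=np.int64)
        return np.asarray(indices, dtype=np.int64) @ powers

    def lookup(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, D) truncated coordinates to symbols; raise on missing cells."""
        enc = self._encode(indices)
        pos = np.searchsorted(self.keys, enc)
        pos_c = np.clip(pos, 0, self.keys.size - 1)
        bad = (pos >= self.keys.size) | (self.keys[pos_c] != enc)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"profile position {i} maps to cell {tuple(np.asarray(indices)[i])} "
                f"absent from the reduction table; input is off the simplex"
            )
        return self.cell_symbols[pos_c]

    def to_tsv(self, path) -> None:
        """Debug dump of all stored cells."""
        D = self.codebook.alphabet.D
        with open(path, "w") as fh:
            fh.write(f"# Q={self.scale}\tD={D}\tcells={self.n_cells}\n")
            for key, sym in zip(self.keys, self.cell_symbols):
                g, rem = [], int(key)
                for _ in range(D):
                    g.append(rem % self.scale)
                    rem //= self.scale
                fh.write("\t".join(map(str, g)) + f"\t{int(sym)}\n")


def _admissible_cells(D: int, Q: int) -> np.ndarray:
    """Integer tuples g in [0, Q-1]^D whose cell can contain a simplex point.

    A point with sum(f) = 1 truncates to coordinates with
    Q - D <= sum(g) <= Q (each floor loses < 1; f = 1.0 clamps to Q - 1).
    """
    lo = max(0, Q - D)
    cells = [g for g in itertools.product(range(Q), repeat=D) if lo <= sum(g) <= Q]
    return np.array(cells, dtype=np.int64)


def build_reduction_table(codebook: SamplePointCodebook, scale: int = 16) -> ReductionTable:
    """Exhaustively precompute the symbol for every admissible cell.

    The representative of a cell is its center projected onto the simplex;
    the stored symbol is the exact nearest codebook point to that
    representative.  Construction is deterministic.
    """
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    if scale < codebook.params.L:
        raise ValueError(
            f"scale ({scale}) must be at least the codebook lattice resolution "
            f"L={codebook.params.L} so cells resolve the lattice"
        )
    D = codebook.alphabet.D
    cells = _admissible_cells(D, scale)
    centers = project_to_simplex((cells + 0.5) / scale, D)
    # exact nearest neighbor per representative, vectorized over cells
    d2 = ((centers[:, None, :] - codebook.points[None, :, :]) ** 2).sum(axis=2)
    syms = np.argmin(d2, axis=1).astype(np.int64)
    # a cell that contains a codebook point exactly maps to that point (the
    # zero-distance winner), overriding the cell-center choice
    powers_tmp = np.int64(scale) ** np.arange(D, dtype=np.int64)
    cell_keys = cells @ powers_tmp
    cb_cells = np.clip(np.floor(codebook.points * scale).astype(np.int64), 0, scale - 1)
    cb_keys = cb_cells @ powers_tmp
    for sym in range(codebook.K - 1, -1, -1):  # reversed: lowest symbol wins ties
        idx = np.flatnonzero(cell_keys == cb_keys[sym])
        if idx.size:
            syms[idx[0]] = sym
    powers = np.int64(scale) ** np.arange(D, dtype=np.int64)
    keys = cells @ powers
    order = np.argsort(keys)
    return ReductionTable(scale=scale, keys=keys[order], cell_symbols=syms[order],
                          codebook=codebook)


def reduce_profile(freqs: np.ndarray, table: ReductionTable) -> DiscreteProfile:
    """Quantize profile rows to codebook symbols by scale-truncate lookup.

    ``freqs`` is a (positions, D) array of simplex rows (a
    ``ContinuousProfile.freqs``).  Per position the cell index is
    ``floor(f * Q)`` clamped to [0, Q-1]; the symbol comes from the ragged
    table.  Pure function of its inputs.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    Q = table.scale
    indices = np.clip(np.floor(freqs * Q).astype(np.int64), 0, Q - 1)
    return DiscreteProfile(symbols=table.lookup(indices), K=table.codebook.K)


def nearest_sample_point(point: np.ndarray, codebook: SamplePointCodebook) -> int:
    """Exact nearest-neighbor symbol (Euclidean); ties go to the lowest symbol.

    This is the oracle the table lookup approximates: a full distance scan
    over the codebook.
    """
    if codebook.K == 0:
        raise ValueError("codebook is empty")
    point = np.asarray(point, dtype=float)
    d2 = ((codebook.points - point) ** 2).sum(axis=1)
    return int(np.argmin(d2))  # argmin returns the first (lowest) minimizer
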
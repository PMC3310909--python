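"""Seeded synthetic nucleotide sequence families with known true alignments.

A random ancestor evolves down a binary tree; every branch applies per-site
substitutions (transition-biased, kappa = 2) and geometric-length indels.
Column homology is tracked explicitly, so alongside the unaligned leaf
sequences the generator returns the *true* multiple alignment — the
reference against which test alignments can be scored.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .profiles import AlignedGroup

__all__ = ["FamilyParams", "generate_family"]

_BASES = "ACGT"
# transition partner per base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": "CT", "G": "CT", "C": "AG", "T": "AG",
}


@dataclass(frozen=True)
class FamilyParams:
    """Simulation knobs.

    ``substitution_rate`` and ``indel_rate`` are per-site probabilities per
    branch; indel lengths are geometric with the given mean; ``tree_shape``
    is "balanced" (caterpillar-free, roughly log-depth) or "random" (random
    topology from repeated joins).
    """

    ancestor_length: int = 300
    n_sequences: int = 10
    substitution_rate: float = 0.02
    indel_rate: float = 0.005
    mean_indel_length: float = 2.0
    tree_shape: str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be >= 1")
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be >= 2")
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.mean_indel_length < 1.0:
            raise ValueError("mean_indel_length must be >= 1")
        if self.tree_shape not in ("balanced", "random"):
            raise ValueError("tree_shape must be 'balanced' or 'random'")


class _Columns:
    """Global total order of homology columns; supports insertion."""

    def __init__(self, n: int):
        self.order: list[int] = list(range(n))
        self.next_id = n

    def insert_after(self, pos_id: int | None, count: int) -> list[int]:
        """New column ids placed directly after ``pos_id`` (None = front)."""
        new = list(range(self.next_id, self.next_id + count))
        self.next_id += count
        at = 0 if pos_id is None else self.order.index(pos_id) + 1
        self.order[at:at] = new
        return new


def _mutate(seq: list[tuple[int, str]], cols: _Columns, params: FamilyParams,
            rng: np.random.Generator) -> list[tuple[int, str]]:
    """One branch: substitutions then indels on a (column_id, base) list."""
    out = []
    for col, base in seq:
        if rng.random() < params.substitution_rate:
            if rng.random() < 0.5:  # kappa = 2: transitions as likely as
                base = _TRANSITION[base]  # both transversions together
            else:
                base = _TRANSVERSIONS[base][rng.integers(2)]
        out.append((col, base))
    # indel events, scanning positions left to right
    p_len = 1.0 / params.mean_indel_length
    result: list[tuple[int, str]] = []
    i = 0
    while i < len(out):
        if rng.random() < params.indel_rate:
            length = int(rng.geometric(p_len))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            # insertion after current position
            result.append(out[i])
            anchor = out[i][0]
            new_cols = cols.insert_after(anchor, length)
            for c in new_cols:
                result.append((c, _BASES[rng.integers(4)]))
            i += 1
        else:
            result.append(out[i])
            i += 1
    if not result:  # deletions wiped the sequence; keep one random base
        anchor_cols = cols.insert_after(None, 1)
        result = [(anchor_cols[0], _BASES[rng.integers(4)])]
    return result


def _tree_topology(n: int, shape: str, rng: np.random.Generator):
    """Nested-tuple topology over leaf indices 0..n-1."""
    if shape == "balanced":
        def split(lo: int, hi: int):
            if hi - lo == 1:
                return lo
            mid = (lo + hi + 1) // 2
            return (split(lo, mid), split(mid, hi))
        return split(0, n)
    nodes: list = list(range(n))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        nodes[i] = (nodes[i], nodes.pop(j))
    return nodes[0]


def generate_family(params: FamilyParams) -> tuple[AlignedGroup, list[str]]:
    """Simulate a family; return (true alignment, unaligned sequences).

    The true alignment has one row per leaf, rows in leaf order ``seq1..n``;
    columns where every leaf is gapped (ancestral positions lost in all
    lineages) are dropped.  Degapping row i yields exactly the i-th
    unaligned sequence.
    """
    rng = np.random.default_rng(params.seed)
    cols = _Columns(params.ancestor_length)
    ancestor = [(i, _BASES[rng.integers(4)]) for i in range(params.ancestor_length)]
    topo = _tree_topology(params.n_sequences, params.tree_shape, rng)

    leaves: dict[int, list[tuple[int, str]]] = {}

    def evolve(node, seq) -> None:
        if isinstance(node, int):
            leaves[node] = seq
            return
        left, right = node
        evolve(left, _mutate(seq, cols, params, rng))
        evolve(right, _mutate(seq, cols, params, rng))

    evolve(topo, ancestor)

    order_index = {c: i for i, c in enumerate(cols.order)}
    used = sorted({c for seq in leaves.values() for c, _ in seq},
                  key=order_index.__getitem__)
    col_pos = {c: i for i, c in enumerate(used)}
    width = len(used)
    rows = []
    for leaf in range(params.n_sequences):
        row = ["-"] * width
        for c, base in leaves[leaf]:
            row[col_pos[c]] = base
        rows.append("".join(row))
    ids = [f"seq{i+1}" for i in range(params.n_sequences)]
    truth = AlignedGroup(rows, ids)
    return truth, list(truth.degapped_rows())
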
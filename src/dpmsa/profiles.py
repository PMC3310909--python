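"""Continuous profiles of aligned sequence groups, and group merging.

A group of aligned sequences is summarized column by column as a vector of
character frequencies over residues plus gap — one point on the profile
simplex per column.  Counting is unweighted: every row contributes 1/n to
its column's frequencies.  IUPAC ambiguity codes are spread as fractional
counts across their compatible residues (R adds 1/2 to A and 1/2 to G, N a
quarter to each nucleotide, and so on); strict mode rejects them instead.

Merging two groups after their discrete profiles have been aligned is a pure
bookkeeping step: the edit string interleaves all-gap columns into whichever
group the alignment skipped, and the rows are stacked.  Degapping any output
row always reproduces the original ungapped sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pairwise import DELETE, INSERT, MATCH, EditString
from .profile_space import DNA, AlphabetSpec

__all__ = ["AlignedGroup", "ContinuousProfile", "compute_profile", "apply_edit_string"]

_GAP_CHARS = "-."

# IUPAC nucleotide ambiguity codes -> compatible residues
_IUPAC = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class AlignedGroup:
    """Equal-length gapped rows with per-row identifiers."""

    rows: tuple[str, ...]
    ids: tuple[str, ...]

    def __init__(self, rows: Sequence[str], ids: Sequence[str] | None = None):
        rows = tuple(rows)
        if ids is None:
            ids = tuple(f"seq{i + 1}" for i in range(len(rows)))
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "ids", tuple(ids))
        if len(self.rows) != len(self.ids):
            raise ValueError("rows and ids differ in length")
        if not rows:
            raise ValueError("aligned group must contain at least one row")
        width = len(rows[0])
        for rid, row in zip(self.ids, rows):
            if len(row) != width:
                raise ValueError(f"row {rid!r} has length {len(row)}, expected {width}")
            if not self.degapped(row):
                raise ValueError(f"row {rid!r} contains no residues")

    @staticmethod
    def degapped(row: str) -> str:
        return "".join(c for c in row if c not in _GAP_CHARS)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return self.n_columns

    def degapped_rows(self) -> tuple[str, ...]:
        return tuple(self.degapped(r) for r in self.rows)

    def reordered(self, ids: Sequence[str]) -> "AlignedGroup":
        """Rows permuted into the given id order."""
        index = {rid: i for i, rid in enumerate(self.ids)}
        perm = [index[rid] for rid in ids]
        return AlignedGroup([self.rows[i] for i in perm], list(ids))


@dataclass(frozen=True)
class ContinuousProfile:
    """Positions x D matrix of character frequencies; rows sum to 1."""

    freqs: np.ndarray
    alphabet: AlphabetSpec = field(default=DNA)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)

    def __len__(self) -> int:
        return self.freqs.shape[0]


def _char_vectors(alphabet: AlphabetSpec, strict: bool) -> np.ndarray:
    """(256, D) table mapping byte values to fractional count vectors.

    Rows of NaN mark characters outside the alphabet; the caller reports the
    offending row/column.
    """
    D = alphabet.D
    table = np.full((256, D), np.nan)
    for i, c in enumerate(alphabet.characters):
        for variant in (c.upper(), c.lower()):
            table[ord(variant)] = np.eye(D)[i]
    # U counts as T for nucleotide alphabets
    if "T" in alphabet.characters:
        t = alphabet.characters.index("T")
        table[ord("U")] = table[ord("u")] = np.eye(D)[t]
    for g in _GAP_CHARS + alphabet.gap_symbol:
        table[ord(g)] = np.eye(D)[alphabet.gap_index]
    if not strict:
        for code, bases in _IUPAC.items():
            members = [alphabet.characters.index(b) for b in bases
                       if b in alphabet.characters]
            if not members:
                continue
            vec = np.zeros(D)
            vec[members] = 1.0 / len(members)
            table[ord(code)] = table[ord(code.lower())] = vec
    return table


def compute_profile(
    group: AlignedGroup,
    alphabet: AlphabetSpec = DNA,
    *,
    strict: bool = False,
) -> ContinuousProfile:
    """Column-wise character frequencies of an aligned group.

    ``freqs[col, n]`` is the count of character n in column col divided by
    the number of rows.  With ``strict=True`` ambiguity codes raise instead
    of being spread fractionally.
    """
    table = _char_vectors(alphabet, strict)
    total = np.zeros((group.n_columns, alphabet.D))
    for rid, row in zip(group.ids, group.rows):
        codes = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        vecs = table[codes]
        bad = np.isnan(vecs[:, 0])
        if bad.any():
            col = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"row {rid!r}, column {col}: character {row[col]!r} is not in "
                f"the alphabet"
            )
        total += vecs
    return ContinuousProfile(freqs=total / group.n_rows, alphabet=alphabet)


def apply_edit_string(
    group_a: AlignedGroup, group_b: AlignedGroup, edits: EditString
) -> AlignedGroup:
    """Merge two aligned groups along a pairwise profile alignment.

    Insert operations interleave a gap column into every row of ``group_a``
    (the alignment consumed a column of B alone); Delete operations do the
    same to ``group_b``.  Output rows are A's rows followed by B's.
    """
    n_m, n_i, n_d = edits.n_match, edits.n_insert, edits.n_delete
    if n_m + n_d != group_a.n_columns or n_m + n_i != group_b.n_columns:
        raise ValueError(
            f"edit string inconsistent with groups: #M+#D={n_m + n_d} vs "
            f"{group_a.n_columns} columns in A, #M+#I={n_m + n_i} vs "
            f"{group_b.n_columns} columns in B"
        )
    # per-op source column index, or -1 for an interleaved gap column
    a_src, b_src = [], []
    ai = bi = 0
    for op in edits:
        if op == MATCH:
            a_src.append(ai)
            b_src.append(bi)
            ai += 1
            bi += 1
        elif op == DELETE:
            a_src.append(ai)
            b_src.append(-1)
            ai += 1
        else:
            a_src.append(-1)
            b_src.append(bi)
            bi += 1
    rows = [
        "".join(row[s] if s >= 0 else "-" for s in a_src) for row in group_a.rows
    ] + [
        "".join(row[s] if s >= 0 else "-" for s in b_src) for row in group_b.rows
    ]
    return AlignedGroup(rows, list(group_a.ids) + list(group_b.ids))
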
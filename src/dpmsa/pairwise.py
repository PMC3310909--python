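"""Global pairwise alignment of discrete profiles with linear gap costs.

Discrete profiles are plain integer strings, so Stage 3 of progressive MSA
becomes ordinary Needleman-Wunsch over a precomputed symbol substitution
table.  The aligner maximizes ``sum s'(a_i, b_j) + gap * (#I + #D)`` and
returns an edit string of Match / Insert / Delete operations that also
applies to the underlying sequence groups.

Two implementations share one contract: a quadratic-space DP with an
explicit pointer matrix, and a divide-and-conquer (Hirschberg-style) variant
whose auxiliary memory is proportional to the shorter input.  Traceback ties
are broken Match > Delete > Insert, fixed for reproducibility.

The DP kernels compile with numba when available and fall back to pure
Python otherwise; both paths compute identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np

from .profile_space import SampleSubstitutionTable
from .reduction import DiscreteProfile

__all__ = [
    "EditString",
    "AlignmentParams",
    "align_discrete",
    "align_discrete_linear_space",
]

MATCH, DELETE, INSERT = "M", "D", "I"


@dataclass(frozen=True)
class EditString:
    """Sequence of edit operations: M consumes both inputs, D consumes only
    the first (gap inserted into the second), I consumes only the second."""

    ops: str

    def __post_init__(self) -> None:
        if set(self.ops) - {MATCH, DELETE, INSERT}:
            raise ValueError("edit string may contain only M, I, D")

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self):
        return iter(self.ops)

    @property
    def n_match(self) -> int:
        return self.ops.count(MATCH)

    @property
    def n_insert(self) -> int:
        return self.ops.count(INSERT)

    @property
    def n_delete(self) -> int:
        return self.ops.count(DELETE)

    def swapped(self) -> "EditString":
        """The same alignment with the roles of the two inputs exchanged."""
        trans = {MATCH: MATCH, DELETE: INSERT, INSERT: DELETE}
        return EditString("".join(trans[o] for o in self.ops))

    def cigar(self) -> str:
        """Run-length rendering, e.g. '5M2I3M1D'."""
        return "".join(f"{len(list(g))}{op}" for op, g in groupby(self.ops))


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution table plus per-position linear gap score (<= 0)."""

    substitution: SampleSubstitutionTable | np.ndarray
    gap: int | None = None

    @property
    def table(self) -> np.ndarray:
        if isinstance(self.substitution, SampleSubstitutionTable):
            return self.substitution.table
        return np.asarray(self.substitution, dtype=np.int64)

    @property
    def gap_score(self) -> int:
        if self.gap is not None:
            return int(self.gap)
        if isinstance(self.substitution, SampleSubstitutionTable):
            return self.substitution.gap_score
        raise ValueError("gap score required when substitution is a bare array")


# pointer codes in the traceback matrix
_PM, _PD, _PI = 0, 1, 2


def _fill_py(a, b, sub, gap):
    n, m = a.size, b.size
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    ptr = np.empty((n + 1, m + 1), dtype=np.uint8)
    H[0, 0] = 0
    for j in range(1, m + 1):
        H[0, j] = j * gap
        ptr[0, j] = _PI
    for i in range(1, n + 1):
        H[i, 0] = i * gap
        ptr[i, 0] = _PD
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            if diag >= up and diag >= left:
                H[i, j] = diag
                ptr[i, j] = _PM
            elif up >= left:
                H[i, j] = up
                ptr[i, j] = _PD
            else:
                H[i, j] = left
                ptr[i, j] = _PI
    return H[n, m], ptr


def _last_row_py(a, b, sub, gap):
    m = b.size
    prev = np.arange(m + 1, dtype=np.int64) * gap
    cur = np.empty(m + 1, dtype=np.int64)
    for i in range(1, a.size + 1):
        cur[0] = i * gap
        for j in range(1, m + 1):
            diag = prev[j - 1] + sub[a[i - 1], b[j - 1]]
            up = prev[j] + gap
            left = cur[j - 1] + gap
            best = diag if diag >= up else up
            if left > best:
                best = left
            cur[j] = best
        prev, cur = cur, prev
    return prev.copy()


try:  # numba speeds the kernels ~100x; the pure-Python path is the reference
    from numba import njit

    _fill = njit(cache=False)(_fill_py)
    _last_row = njit(cache=False)(_last_row_py)
except ImportError:  # pragma: no cover
    _fill, _last_row = _fill_py, _last_row_py


def _check_symbols(a: np.ndarray, b: np.ndarray, K: int) -> None:
    for name, arr in (("a", a), ("b", b)):
        if arr.size and (arr.min() < 0 or arr.max() >= K):
            raise ValueError(f"profile {name} contains symbols outside the "
                             f"{K}-symbol table")


def _as_symbols(x) -> np.ndarray:
    if isinstance(x, DiscreteProfile):
        return x.symbols
    return np.asarray(x, dtype=np.int64)


def align_discrete(a, b, params: AlignmentParams) -> tuple[int, EditString]:
    """Optimal global alignment via full-matrix DP with traceback.

    Returns the maximal score and an edit string attaining it.  On score
    ties the traceback prefers Match, then Delete, then Insert.
    """
    a, b = _as_symbols(a), _as_symbols(b)
    sub, gap = params.table, np.int64(params.gap_score)
    _check_symbols(a, b, sub.shape[0])
    score, ptr = _fill(a, b, sub, gap)
    ops = []
    i, j = a.size, b.size
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == _PM:
            ops.append(MATCH)
            i -= 1
            j -= 1
        elif p == _PD:
            ops.append(DELETE)
            i -= 1
        else:
            ops.append(INSERT)
            j -= 1
    return int(score), EditString("".join(reversed(ops)))


def align_discrete_linear_space(
    a, b, params: AlignmentParams, _stats: dict | None = None
) -> tuple[int, EditString]:
    """Same contract as :func:`align_discrete` in O(min(len a, len b)) memory.

    Hirschberg's divide and conquer: score rows for the first half meet
    reversed score rows for the second half; the crossing column with the
    highest combined score (lowest index on ties) splits the problem.  The
    optional ``_stats`` dict records the peak auxiliary row length under
    ``"max_row"`` for memory instrumentation.
    """
    a, b = _as_symbols(a), _as_symbols(b)
    sub, gap = params.table, np.int64(params.gap_score)
    _check_symbols(a, b, sub.shape[0])
    swap = b.size > a.size
    if swap:
        a, b = b, a
    if _stats is not None:
        _stats["max_row"] = 0

    def note_row(m: int) -> None:
        if _stats is not None and m + 1 > _stats["max_row"]:
            _stats["max_row"] = m + 1

    def rec(a: np.ndarray, b: np.ndarray) -> str:
        if a.size == 0:
            return INSERT * b.size
        if b.size == 0:
            return DELETE * a.size
        if a.size == 1 or b.size == 1:
            note_row(b.size)
            _, edits = align_discrete(a, b, AlignmentParams(sub, int(gap)))
            return edits.ops
        mid = a.size // 2
        upper = _last_row(a[:mid], b, sub, gap)
        lower = _last_row(a[mid:][::-1].copy(), b[::-1].copy(), sub, gap)
        note_row(b.size)
        total = upper + lower[::-1]
        split = int(np.argmax(total))  # first maximizer -> deterministic
        return rec(a[:mid], b[:split]) + rec(a[mid:], b[split:])

    ops = rec(a, b)
    score = _score_of(a, b, ops, sub, int(gap))
    edits = EditString(ops)
    if swap:
        edits = edits.swapped()
    return score, edits


def _score_of(a: np.ndarray, b: np.ndarray, ops: str, sub: np.ndarray, gap: int) -> int:
    """Score an explicit edit string (also used by tests as a checker)."""
    i = j = 0
    total = 0
    for op in ops:
        if op == MATCH:
            total += int(sub[a[i], b[j]])
            i += 1
            j += 1
        elif op == DELETE:
            total += gap
            i += 1
        else:
            total += gap
            j += 1
    if i != a.size or j != b.size:
        raise ValueError("edit string does not consume both inputs exactly")
    return total
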
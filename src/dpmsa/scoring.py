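"""Alignment-quality metrics: sum-of-pairs (Q) score, fractional identity, APSI.

All metrics compare alignments through the *residue pairing* they induce —
which residue of one sequence sits in the same column as which residue of
another — so they are invariant under row reordering and under insertion of
all-gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .profiles import AlignedGroup

__all__ = ["QualityReport", "sum_of_pairs_score", "fractional_identity", "apsi",
           "quality_report"]

_GAPS = {"-", "."}


@dataclass(frozen=True)
class QualityReport:
    q_score: float
    fractional_identity: float
    apsi: float
    ref_pairs: int
    test_correct_pairs: int
    characters_scored: int

    def to_dict(self) -> dict:
        return {
            "q_score": self.q_score,
            "fractional_identity": self.fractional_identity,
            "apsi_percent": self.apsi,
            "ref_pairs": self.ref_pairs,
            "test_correct_pairs": self.test_correct_pairs,
            "characters_scored": self.characters_scored,
        }


def _column_maps(msa: AlignedGroup) -> list[np.ndarray]:
    """Per row: array mapping residue index -> column index."""
    maps = []
    for row in msa.rows:
        cols = [c for c, ch in enumerate(row) if ch not in _GAPS]
        maps.append(np.asarray(cols, dtype=np.int64))
    return maps


def _check_comparable(test: AlignedGroup, ref: AlignedGroup) -> AlignedGroup:
    """Validate ids/content agree; return test with rows in ref's order."""
    if set(test.ids) != set(ref.ids):
        raise ValueError("test and reference alignments contain different ids")
    test = test.reordered(ref.ids)
    for rid, t, r in zip(ref.ids, test.degapped_rows(), ref.degapped_rows()):
        if t != r:
            raise ValueError(f"sequence {rid!r} differs between test and reference")
    return test


def sum_of_pairs_score(test: AlignedGroup, ref: AlignedGroup) -> float:
    """Fraction of reference residue-residue pairs reproduced by the test.

    For every pair of rows, the reference pairs residue r of one row with
    residue s of another whenever they share a column; the score counts how
    many of those pairs share a column in the test alignment too.
    Residue-gap pairs are never counted.
    """
    test = _check_comparable(test, ref)
    tmaps, rmaps = _column_maps(test), _column_maps(ref)
    total = correct = 0
    n = ref.n_rows
    # invert ref column maps: per row, column -> residue index (-1 for gap)
    rinv = []
    for row_map in rmaps:
        inv = np.full(ref.n_columns, -1, dtype=np.int64)
        inv[row_map] = np.arange(row_map.size)
        rinv.append(inv)
    for i, j in combinations(range(n), 2):
        ri, rj = rinv[i], rinv[j]
        both = (ri >= 0) & (rj >= 0)
        pairs_i, pairs_j = ri[both], rj[both]
        total += pairs_i.size
        # test columns of those residues
        correct += int((tmaps[i][pairs_i] == tmaps[j][pairs_j]).sum())
    if total == 0:
        raise ValueError("reference alignment induces no residue pairs")
    return correct / total


def fractional_identity(test: AlignedGroup, ref: AlignedGroup) -> float:
    """Per-character agreement between the two alignments.

    For every ordered row pair (i, j) and every residue of row i, the
    reference assigns a partner in row j: a residue index, or a gap.  The
    character agrees when the test alignment assigns the same partner.  FI
    is the agreeing fraction over all characters and partner rows.
    """
    test = _check_comparable(test, ref)
    tmaps, rmaps = _column_maps(test), _column_maps(ref)

    def partner_arrays(maps: list[np.ndarray], msa: AlignedGroup):
        """partners[i][j]: for each residue of row i, residue index in row j
        sharing its column, or -1 for gap."""
        inv = []
        for m in maps:
            a = np.full(msa.n_columns, -1, dtype=np.int64)
            a[m] = np.arange(m.size)
            inv.append(a)
        n = msa.n_rows
        return [[inv[j][maps[i]] for j in range(n)] for i in range(n)]

    rp = partner_arrays(rmaps, ref)
    tp = partner_arrays(tmaps, test)
    n = ref.n_rows
    agree = total = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            agree += int((rp[i][j] == tp[i][j]).sum())
            total += rp[i][j].size
    if total == 0:
        raise ValueError("alignments contain no residues to score")
    return agree / total


def apsi(msa: AlignedGroup) -> float:
    """Average pairwise sequence identity of an alignment, in percent.

    Pairwise identity is matched residues over columns where both rows hold
    a residue; pairs with no overlap contribute 0 by convention.
    """
    if msa.n_rows < 2:
        raise ValueError("APSI needs at least 2 rows")
    rows = [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in msa.rows]
    res = [~np.isin(r, [ord("-"), ord(".")]) for r in rows]
    idents = []
    for i, j in combinations(range(msa.n_rows), 2):
        both = res[i] & res[j]
        total = int(both.sum())
        if total == 0:
            idents.append(0.0)
        else:
            idents.append(float((rows[i][both] == rows[j][both]).sum()) / total)
    return 100.0 * float(np.mean(idents))


def quality_report(test: AlignedGroup, ref: AlignedGroup) -> QualityReport:
    """All metrics at once (APSI is computed on the reference alignment)."""
    test_ord = _check_comparable(test, ref)
    rmaps = _column_maps(ref)
    ref_pairs = 0
    rinv = []
    for m in rmaps:
        inv = np.full(ref.n_columns, -1, dtype=np.int64)
        inv[m] = np.arange(m.size)
        rinv.append(inv)
    for i, j in combinations(range(ref.n_rows), 2):
        ref_pairs += int(((rinv[i] >= 0) & (rinv[j] >= 0)).sum())
    q = sum_of_pairs_score(test_ord, ref)
    fi = fractional_identity(test_ord, ref)
    chars = sum(len(r) for r in ref.degapped_rows()) * (ref.n_rows - 1)
    return QualityReport(
        q_score=q, fractional_identity=fi, apsi=apsi(ref),
        ref_pairs=ref_pairs, test_correct_pairs=round(q * ref_pairs),
        characters_scored=chars,
    )
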
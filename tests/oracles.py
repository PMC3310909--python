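"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithms: alignment scores are
found by enumerating every global alignment recursively, lattice counts by
exhaustive grid enumeration, substitution scores by an explicit double loop.
"""

from __future__ import annotations

import itertools

import numpy as np


def best_alignment_score_bruteforce(a, b, sub, gap: int) -> int:
    """Maximum global alignment score by recursive enumeration of all
    alignments (no memoization; exponential, for tiny inputs only)."""

    def rec(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            best = sub[a[i], b[j]] + rec(i + 1, j + 1)
        if i < len(a):
            v = gap + rec(i + 1, j)
            best = v if best is None or v > best else best
        if j < len(b):
            v = gap + rec(i, j + 1)
            best = v if best is None or v > best else best
        return best

    return int(rec(0, 0))


def lattice_points_bruteforce(D: int, L: int) -> list[tuple[int, ...]]:
    """All integer grid points in [0, L]^D with max(0, L-D+1) <= sum <= L-1."""
    lo = max(0, L - D + 1)
    return [
        ks for ks in itertools.product(range(L + 1), repeat=D)
        if lo <= sum(ks) <= L - 1
    ]


def substitution_score_bruteforce(ci, cj, s, beta: float) -> float:
    """Explicit double sum sum_m sum_n c_i[m] c_j[n] s[m, n] / beta."""
    total = 0.0
    for m in range(len(ci)):
        for n in range(len(cj)):
            total += cj[n] * ci[m] * s[n, m]
    return total / beta


def nearest_symbol_bruteforce(point, points) -> int:
    """Exhaustive nearest-neighbor scan, ties to the lowest index."""
    best, best_d = 0, None
    for k in range(len(points)):
        dist = float(np.sqrt(((np.asarray(points[k]) - np.asarray(point)) ** 2).sum()))
        if best_d is None or dist < best_d - 1e-15:
            best, best_d = k, dist
    return best


def column_pairs(msa_rows: list[str]) -> set[tuple]:
    """All residue-residue pairs an alignment induces, as
    ((row_i, residue_index_i), (row_j, residue_index_j)) with i < j."""
    gaps = {"-", "."}
    n = len(msa_rows)
    counters = [0] * n
    pairs = set()
    for col in range(len(msa_rows[0])):
        present = []
        for r in range(n):
            ch = msa_rows[r][col]
            if ch not in gaps:
                present.append((r, counters[r]))
                counters[r] += 1
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                pairs.add((present[x], present[y]))
    return pairs
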
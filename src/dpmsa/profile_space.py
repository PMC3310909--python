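"""Sample-point codebooks on the profile simplex and their substitution tables.

A *profile* column over an alphabet of R residues plus the gap character is a
point on the (D-1)-simplex in D = R + 1 dimensions: a vector of character
frequencies summing to one.  This module selects a small, fixed set of
*sample points* from that simplex — the codebook of a vector quantizer — and
precomputes an integer substitution table between them, so that profile
columns can later be replaced by small integer symbols and aligned exactly
like sequences.

Sample points are obtained by enumerating the cubic lattice with spacing 1/L
inside a band of width (D-1)/L below the simplex, projecting each lattice
point orthogonally (along the all-ones direction) onto the hyperplane
``sum(f) = 1``, optionally discarding points whose purine and pyrimidine
frequencies are simultaneously high and balanced (such columns are rare in
real alignments because substitution scores discourage cross-class
alignment), and finally adding the pure-residue corners.  The all-gap corner
is never a sample point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AlphabetSpec",
    "BaseScoringParams",
    "CodebookParams",
    "SamplePointCodebook",
    "SampleSubstitutionTable",
    "DNA",
    "TOY_AC",
    "generate_lattice_points",
    "project_to_simplex",
    "filter_improbable",
    "build_codebook",
    "build_substitution_table",
    "default_base_table",
    "round_half_away",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CTU")


@dataclass(frozen=True)
class AlphabetSpec:
    """Residue alphabet plus gap; the gap always occupies the last coordinate."""

    characters: tuple[str, ...] = ("A", "C", "G", "T")
    gap_symbol: str = "-"

    def __post_init__(self) -> None:
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("alphabet characters must be unique")
        if self.D < 3:
            raise ValueError("alphabet needs at least 2 residues (D >= 3)")
        if self.gap_symbol in self.characters:
            raise ValueError("gap symbol cannot also be a residue")

    @property
    def D(self) -> int:
        """Profile-space dimension: residues + 1 gap coordinate."""
        return len(self.characters) + 1

    @property
    def gap_index(self) -> int:
        return len(self.characters)

    def index_of(self, char: str) -> int:
        c = char.upper()
        if c == "U":
            c = "T"
        if c in (self.gap_symbol, ".", "-"):
            return self.gap_index
        try:
            return self.characters.index(c)
        except ValueError:
            raise KeyError(f"character {char!r} not in alphabet") from None

    @property
    def purine_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.characters) if c in _PURINES)

    @property
    def pyrimidine_indices(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.characters) if c in _PYRIMIDINES)


#: Standard nucleotide alphabet (U is folded onto T on input).
DNA = AlphabetSpec()

#: Three-dimensional toy alphabet {A, C, gap}, handy for worked examples and
#: for plotting profile space as a triangle.
TOY_AC = AlphabetSpec(characters=("A", "C"))


def default_base_table(
    alphabet: AlphabetSpec = DNA,
    *,
    match: float = 5.0,
    transition: float = -2.0,
    transversion: float = -4.0,
    gap_extend: float = -4.0,
    gap_gap: float = 0.0,
) -> np.ndarray:
    """Build a D x D residue/gap scoring table.

    Transitions (purine<->purine, pyrimidine<->pyrimidine) score higher than
    transversions, which is also what motivates filtering sample points with
    balanced cross-class frequencies.  The gap row and column are set to
    ``gap_extend + 1`` against every residue: one unit better than extending
    a gap, which discourages a gap in one group being answered by a gap in
    the other during pairwise alignment.
    """
    D = alphabet.D
    s = np.empty((D, D), dtype=float)
    pur = set(alphabet.purine_indices)
    pyr = set(alphabet.pyrimidine_indices)
    for i in range(D - 1):
        for j in range(D - 1):
            if i == j:
                s[i, j] = match
            elif (i in pur and j in pur) or (i in pyr and j in pyr):
                s[i, j] = transition
            else:
                s[i, j] = transversion
    g = alphabet.gap_index
    s[g, :] = gap_extend + 1
    s[:, g] = gap_extend + 1
    s[g, g] = gap_gap
    return s


@dataclass(frozen=True)
class BaseScoringParams:
    """Residue-level scores from which the sample substitution table is built.

    ``s`` is the D x D table (gap row/column included, in score units).
    ``beta`` rescales the bilinear profile scores so that every table entry
    fits in ``entry_bits`` signed bits; ``beta=None`` selects the smallest
    power of two that fits.  The gap model is linear: ``gap_open`` is kept
    for completeness but the aligner charges ``gap_extend`` per gap position.
    """

    s: np.ndarray = field(default_factory=default_base_table)
    gap_open: float = -4.0
    gap_extend: float = -4.0
    beta: float | None = None
    entry_bits: int = 8

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "s", s)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("base table must be square")
        if not np.allclose(s, s.T):
            raise ValueError("base table must be symmetric")
        if self.entry_bits not in (4, 8):
            raise ValueError("entry_bits must be 4 or 8")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")

    def validate_gap_rule(self, alphabet: AlphabetSpec) -> None:
        """Check s[gap, n] = gap_extend + 1 for every residue n."""
        g = alphabet.gap_index
        want = self.gap_extend + 1
        for n in range(alphabet.D - 1):
            if self.s[g, n] != want or self.s[n, g] != want:
                raise ValueError(
                    f"gap rule violated: s[gap,{alphabet.characters[n]}] must be "
                    f"gap_extend + 1 = {want}, got {self.s[g, n]}"
                )


@dataclass(frozen=True)
class CodebookParams:
    """Knobs of the sample-point selection.

    L
        lattice points per unit axis interval; the lattice spacing is 1/L and
        the projected planes are sqrt(D)/(D*L) apart.
    T_c, T_d
        purine/pyrimidine filter thresholds: a point is dropped when some
        purine/pyrimidine frequency pair sums above ``T_c`` while differing
        by less than ``T_d``.
    """

    L: int = 4
    T_c: float = 0.75
    T_d: float = 0.30
    apply_filter: bool = True
    max_symbols: int = 64

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be a positive integer")
        for name, v in (("T_c", self.T_c), ("T_d", self.T_d)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_symbols < 1:
            raise ValueError("max_symbols must be positive")


@dataclass(frozen=True)
class SamplePointCodebook:
    """K sample points on the simplex, bound to symbols 0..K-1.

    Symbol order is deterministic: residue corners first (alphabet order),
    then projected lattice points in lexicographic order of their integer
    lattice coordinates.
    """

    points: np.ndarray  # (K, D) float
    is_corner: np.ndarray  # (K,) bool
    alphabet: AlphabetSpec
    params: CodebookParams

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "is_corner", np.asarray(self.is_corner, dtype=bool))

    @property
    def K(self) -> int:
        return self.points.shape[0]

    @property
    def symbols(self) -> np.ndarray:
        return np.arange(self.K)

    @property
    def epsilon(self) -> float:
        """Spacing between adjacent projected lattice planes: sqrt(D)/(D*L)."""
        D = self.alphabet.D
        return sqrt(D) / (D * self.params.L)

    def corner_symbol(self, residue: str) -> int:
        """Symbol of the pure-residue corner for ``residue``."""
        idx = self.alphabet.index_of(residue)
        if idx == self.alphabet.gap_index:
            raise KeyError("the all-gap corner is not in the codebook")
        corners = np.flatnonzero(self.is_corner)
        for sym in corners:
            if self.points[sym, idx] == 1.0:
                return int(sym)
        raise KeyError(f"no corner for residue {residue!r}")

    def to_tsv(self, path) -> None:
        """Write the codebook as TSV with a parameter header."""
        p = self.params
        with open(path, "w") as fh:
            fh.write(f"# D={self.alphabet.D}\tL={p.L}\tT_c={p.T_c}\tT_d={p.T_d}\t"
                     f"filter={int(p.apply_filter)}\t"
                     f"alphabet={''.join(self.alphabet.characters)}"
                     f"{self.alphabet.gap_symbol}\n")
            cols = "\t".join(f"f_{c}" for c in self.alphabet.characters)
            fh.write(f"symbol\tis_corner\t{cols}\tf_gap\n")
            for k in range(self.K):
                coords = "\t".join(f"{x:.12g}" for x in self.points[k])
                fh.write(f"{k}\t{int(self.is_corner[k])}\t{coords}\n")

    @classmethod
    def from_tsv(cls, path) -> "SamplePointCodebook":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("codebook TSV must start with a '#' header line")
            meta = dict(tok.split("=", 1) for tok in header[1:].split())
            fh.readline()  # column names
            rows, corners = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                corners.append(bool(int(parts[1])))
                rows.append([float(x) for x in parts[2:]])
        alpha_str = meta["alphabet"]
        alphabet = AlphabetSpec(characters=tuple(alpha_str[:-1]), gap_symbol=alpha_str[-1])
        params = CodebookParams(
            L=int(meta["L"]), T_c=float(meta["T_c"]), T_d=float(meta["T_d"]),
            apply_filter=bool(int(meta.get("filter", 1))),
        )
        return cls(points=np.array(rows), is_corner=np.array(corners), alphabet=alphabet,
                   params=params)


def lattice_point_count(D: int, L: int) -> int:
    """Closed-form count of in-band lattice points (stars and bars)."""
    return sum(comb(s + D - 1, D - 1) for s in range(max(0, L - D + 1), L))


def generate_lattice_points(D: int, L: int) -> np.ndarray:
    """Enumerate lattice points with coordinates k/L inside the simplex band.

    Only points whose coordinate sum S satisfies
    ``max(0, 1 - (D-1)/L) <= S <= 1 - 1/L`` are kept: these lie on the D-1
    parallel planes closest below the simplex, so their orthogonal
    projections cover it without duplication.  Returned in lexicographic
    order of integer coordinates, shape (n, D).
    """
    if D < 2:
        raise ValueError("D must be at least 2")
    if L < 1:
        raise ValueError("L must be a positive integer")
    lo = max(0, L - D + 1)
    pts: list[tuple[int, ...]] = []
    for ks in itertools.product(range(L + 1), repeat=D):
        if lo <= sum(ks) <= L - 1:
            pts.append(ks)
    pts.sort()
    return np.array(pts, dtype=float) / L


def project_to_simplex(p: np.ndarray, D: int | None = None) -> np.ndarray:
    """Orthogonally project point(s) onto the hyperplane ``sum(f) = 1``.

    Adds ``t = (1 - sum(p))/D`` to every coordinate — a shift along the
    all-ones normal of the simplex.  Accepts a single point or an (n, D)
    array.
    """
    p = np.asarray(p, dtype=float)
    d = p.shape[-1] if D is None else D
    t = (1.0 - p.sum(axis=-1, keepdims=True)) / d
    return p + t


def filter_improbable(
    points: np.ndarray,
    T_c: float,
    T_d: float,
    alphabet: AlphabetSpec = DNA,
) -> np.ndarray:
    """Drop points with high, balanced purine + pyrimidine frequencies.

    A point is eliminated when any pair (i in purines, j in pyrimidines)
    satisfies ``f_i + f_j > T_c`` and ``|f_i - f_j| < T_d``; such columns are
    improbable in real alignments.  Surviving points keep their order.
    """
    for name, v in (("T_c", T_c), ("T_d", T_d)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    points = np.asarray(points, dtype=float)
    keep = np.ones(points.shape[0], dtype=bool)
    for i in alphabet.purine_indices:
        for j in alphabet.pyrimidine_indices:
            fi, fj = points[:, i], points[:, j]
            keep &= ~((fi + fj > T_c) & (np.abs(fi - fj) < T_d))
    return points[keep]


def build_codebook(
    alphabet: AlphabetSpec = DNA,
    params: CodebookParams = CodebookParams(),
) -> SamplePointCodebook:
    """Assemble the sample-point codebook.

    Pipeline: lattice enumeration -> orthogonal projection -> improbability
    filter -> union with pure-residue corners.  The all-gap corner is never
    included.  Raises if the resulting symbol count exceeds
    ``params.max_symbols``.
    """
    D = alphabet.D
    lattice = generate_lattice_points(D, params.L)
    projected = project_to_simplex(lattice, D)
    if params.apply_filter:
        projected = filter_improbable(projected, params.T_c, params.T_d, alphabet)
    corners = np.eye(D)[: D - 1]  # residue corners only; all-gap corner excluded
    points = np.vstack([corners, projected])
    is_corner = np.zeros(points.shape[0], dtype=bool)
    is_corner[: D - 1] = True
    K = points.shape[0]
    if K > params.max_symbols:
        raise ValueError(
            f"codebook has {K} symbols, exceeding the cap of {params.max_symbols}; "
            f"reduce L or tighten the filter thresholds"
        )
    return SamplePointCodebook(points=points, is_corner=is_corner,
                               alphabet=alphabet, params=params)


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (bit-reproducible, unlike banker's rounding)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class SampleSubstitutionTable:
    """K x K integer alignment scores between codebook symbols."""

    table: np.ndarray  # (K, K) int
    codebook: SamplePointCodebook
    beta: float
    entry_bits: int
    gap_score: int  # per-position linear gap score in table units

    @property
    def K(self) -> int:
        return self.table.shape[0]

    def to_tsv(self, path) -> None:
        cb = self.codebook
        with open(path, "w") as fh:
            fh.write(f"# D={cb.alphabet.D}\tL={cb.params.L}\tT_c={cb.params.T_c}\t"
                     f"T_d={cb.params.T_d}\tbeta={self.beta:g}\t"
                     f"entry_bits={self.entry_bits}\tgap_score={self.gap_score}\t"
                     f"alphabet={''.join(cb.alphabet.characters)}{cb.alphabet.gap_symbol}\n")
            for row in self.table:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")


def _fits(table: np.ndarray, entry_bits: int) -> bool:
    lo, hi = -(2 ** (entry_bits - 1)), 2 ** (entry_bits - 1) - 1
    return bool(table.min() >= lo and table.max() <= hi)


def build_substitution_table(
    codebook: SamplePointCodebook,
    scoring: BaseScoringParams = BaseScoringParams(),
) -> SampleSubstitutionTable:
    """Precompute symbol-vs-symbol scores from the residue table.

    The score of aligning sample points c_i and c_j is the expected residue
    score under their frequency vectors,

        s'[i, j] = round( (sum_m sum_n c[i,m] * c[j,n] * s[m,n]) / beta ),

    i.e. the bilinear form ``c_i^T s c_j`` scaled by beta and rounded half
    away from zero.  With ``beta=None`` the smallest power of two making all
    entries fit ``entry_bits`` signed bits is chosen.
    """
    scoring.validate_gap_rule(codebook.alphabet)
    if scoring.s.shape[0] != codebook.alphabet.D:
        raise ValueError("base table dimension does not match the alphabet")
    C = codebook.points
    raw = C @ scoring.s @ C.T
    if scoring.beta is not None:
        beta = float(scoring.beta)
        table = round_half_away(raw / beta)
        if not _fits(table, scoring.entry_bits):
            bad = np.unravel_index(np.argmax(np.abs(table)), table.shape)
            raise ValueError(
                f"entry s'[{bad[0]},{bad[1]}] = {int(table[bad])} does not fit "
                f"{scoring.entry_bits} signed bits with beta={beta}"
            )
    else:
        beta = 1.0
        while True:
            table = round_half_away(raw / beta)
            if _fits(table, scoring.entry_bits):
                break
            beta *= 2.0
    gap_score = int(round_half_away(np.array(scoring.gap_extend / beta)))
    return SampleSubstitutionTable(
        table=table.astype(np.int64), codebook=codebook, beta=beta,
        entry_bits=scoring.entry_bits, gap_score=gap_score,
    )
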
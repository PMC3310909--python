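# Methods

## Model

Progressive MSA proceeds in three stages: all-pairs similarity, guide-tree
construction, and tree-ordered profile–profile alignment. `dpmsa`
implements the third stage over *discrete* profiles. A group of aligned
nucleotide sequences is summarized column-wise as points on the
4-simplex in D = 5 dimensions — frequencies of A, C, G, T and gap, with the
gap always the last coordinate and U folded onto T. Each column is replaced
by the integer symbol of a nearby *sample point* from a fixed codebook, and
the two symbol strings are aligned by global dynamic programming against a
precomputed symbol-vs-symbol score table. The winning edit string applies
verbatim to the underlying groups because profile positions correspond
one-to-one with alignment columns.

The method trades a controlled quantization error in the column
representation for a much simpler alignment kernel. Its accuracy therefore
depends on the codebook resolving profile space finely enough relative to
the divergence of the sequences being merged.

## Codebook construction

Lattice points with coordinates k/L (L per unit axis interval) are kept if
their coordinate sum S lies in the band max(0, 1 − (D−1)/L) ≤ S ≤ 1 − 1/L;
these sit on the D−1 parallel hyperplanes nearest below the simplex, spaced
ε = √D/(D·L) apart. Each is projected orthogonally onto Σf = 1 by adding
t = (1 − S)/D to every coordinate. Because the band's sum range is narrower
than the projection direction's pitch, no two band points project to the
same simplex point. A published description of this construction gives the
projection as p′ = t·p, which does not land on the hyperplane (its
coordinate sum is t·S ≠ 1 in general); the additive form used here is the
orthogonal projection consistent with the construction's geometric intent,
and reduces to the same fixed points on the simplex itself.

Points where some purine/pyrimidine pair (i ∈ {A,G}, j ∈ {C,T}) has
f_i + f_j > T_c while |f_i − f_j| < T_d are removed: columns holding both
base classes at high, balanced frequency are rare in real alignments
because substitution scores penalize cross-class pairing. Defaults
T_c = 0.75, T_d = 0.30. The four pure-residue corners are always included;
the all-gap corner never is (an all-gap column cannot arise from degapped
input). Symbols are assigned deterministically: corners first in alphabet
order, then lattice points lexicographically.

With the default L = 4 the unfiltered codebook has 56 + 4 = 60 symbols and
the filtered default 52, both within the 64-symbol (6-bit) budget that a
table-driven alignment kernel with 4/8-bit score entries implies.

## Substitution table

For sample points c_i, c_j and base table s (D × D, gap row included), the
symbol score is the bilinear form

    s′(i, j) = round( c_iᵀ s c_j / β ),

i.e. the expected residue-level score when a column drawn from c_i aligns
against one drawn from c_j. Rounding is half-away-from-zero so tables are
bit-identical across platforms. β rescales entries into the configured
signed 4- or 8-bit range; by default it is chosen automatically as the
smallest power of two that fits and reported in the table metadata.

The base table is not dictated by the method; the default is match +5,
transition −2, transversion −4, linear gap −4 per position — a conventional
nucleotide scoring that exercises the purine/pyrimidine structure the
filter assumes. The gap row obeys s[gap, n] = gap_extend + 1 for every
residue n (checked before table construction): aligning a residue against
an existing gap column is one unit better than opening a new gap position,
which prevents a gap in one group from being answered by a gap in the
other. s[gap, gap] defaults to 0 so gap-dominated columns align against
each other at no cost; this value is unconstrained by the gap rule and is
configurable.

## Reduction (quantization)

Exact nearest-neighbor search per column would dominate the cost the
discrete representation is meant to remove, so reduction is a constant-time
*near*-neighbor lookup: each frequency is scaled by Q (default 16) and
truncated; the integer tuple indexes a precomputed table. Only cells whose
coordinate sums permit intersection with the simplex (Q − D ≤ Σg ≤ Q) are
stored, giving a ragged table of 17 341 cells instead of the dense
16⁵ = 1 048 576 for the default configuration. f = 1.0 clamps into the top
cell rather than overflowing the index range.

Each stored cell references the codebook point nearest to the cell's center
projected onto the simplex; a cell that contains a codebook point exactly
references that point (the zero-distance winner). Either way, for any query
x in a cell of side 1/Q the returned point is within
2·(half cell diagonal) = √D/Q of optimal in the center case and within one
cell diagonal in the contained-point case, so the worst-case excess over
the true nearest neighbor is bounded by 2√D/Q ≈ 0.28 at the defaults —
about 2.5× smaller than the codebook plane spacing ε at L = 4, and the
empirical mean excess on uniform simplex points is two orders of magnitude
smaller still (~0.002). Q = 16 keeps table construction well under a
second while making quantization error negligible next to codebook error;
Q must be ≥ L so cells resolve the lattice.

## Pairwise alignment

Needleman–Wunsch with linear gap costs (no separate opening penalty —
matching the capability of the simple table-driven kernels this
representation targets), maximizing Σ s′(a_i, b_j) + gap·(#I + #D). The
implementation maximizes similarity; the sign convention of the default
table makes larger better. Traceback tie order is fixed Match > Delete >
Insert for reproducibility. A Hirschberg divide-and-conquer variant
returns identical optimal scores using score rows over the shorter input
only (the split column is the first maximizer, also deterministic); it is
an exact equivalent, not an approximation. DP kernels are compiled with
numba when present; a pure-Python fallback computes identical matrices.

## Progressive driver

Stage 1 distances, first iteration: d(a,b) = 1 − Σ_w min(n_a(w), n_b(w)) /
(min(|a|,|b|) − k + 1) over k-mer counts, k = 6 by default; k-mers touching
non-ACGT characters are skipped. Two interchangeable counters (dictionary
reference and vectorized 2-bit rolling code) are tested for exact
agreement. Second iteration: d = 1 − fractional identity computed from the
first alignment (matched residues over co-residue columns; pairs with no
overlap get distance 1). Stage 2: UPGMA with size-weighted average linkage;
ties broken by lowest cluster-creation index, children ordered by subtree
size then lowest leaf id, so trees and hence alignments are deterministic.
Stage 3: post-order traversal computing profile → reduction → DP → edit
string application at every internal node. At most two iterations are run.

Sequence weighting, anchor columns, and iterative refinement — features of
mature progressive aligners — are deliberately absent: profiles are plain
unweighted frequency counts, which is the representation the quantization
operates on.

## Synthetic families

The generator evolves a uniform-random ancestor down a balanced (default)
or random binary tree. Per branch and per site: substitution with
probability `substitution_rate` (transition:transversion bias κ = 2 — a
transition is as likely as both transversions combined — so the
purine/pyrimidine filter faces realistic column compositions), indel
initiation with probability `indel_rate` (insertion or deletion equally
likely, geometric length with mean `mean_indel_length`, default 2). Column
homology is tracked through a global column order, yielding the true
alignment of the leaves; columns gapped in every leaf are dropped.

Defaults (length 300, 10 sequences, substitution 0.02/branch, indel
0.005/branch) produce families near 85–90 % average pairwise identity for
balanced trees of 10–20 leaves — the high-identity regime where a
quantized-profile aligner is expected to match continuous-profile quality.
The generator emulates point substitution and short indels only: no rate
heterogeneity across sites, no GC bias, no large rearrangements, no
sequencing error. Passing quality tests on these families demonstrates the
pipeline's mechanics and its behavior versus divergence, not performance on
curated structural benchmarks.

## Numerical and degenerate-input choices

- Simplex membership tolerances: codebook points sum to 1 within 1e-9;
  projection verified to 1e-12 in tests.
- Nearest-neighbor ties: lowest symbol index (first argmin).
- Empty-vs-empty alignment: score 0, empty edit string; empty-vs-nonempty:
  all gaps.
- Alignments with zero co-residue columns: identity 0, distance 1, APSI
  contribution 0.
- Rows that degap to nothing are rejected at `AlignedGroup` construction.
- IUPAC ambiguity codes spread fractional counts by default;
  `strict=True` raises instead. Gap characters `-` and `.` are both
  accepted; `-` is canonical on output.

## Known limitations

- Nucleotides only; a protein alphabet would need D = 21 and a different
  sample-point budget.
- Linear gap costs only; affine gaps would require a three-state DP and a
  richer table format.
- UPGMA assumes roughly clock-like divergence; strongly rate-heterogeneous
  families may get suboptimal merge orders.
- Quality on low-identity families (< 60 % APSI) degrades faster than for
  continuous-profile aligners, as quantization error grows relative to the
  signal; the acceptance checks quantify this trend on synthetic data.
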
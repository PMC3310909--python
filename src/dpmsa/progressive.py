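"""Three-stage progressive MSA driver over discrete profiles.

Stage 1 scores all sequence pairs with an alignment-free k-mer distance
(first iteration) or fractional-identity distance from an existing alignment
(second iteration).  Stage 2 clusters the distance matrix into a rooted
binary guide tree with UPGMA.  Stage 3 walks the tree in post-order; at each
internal node the two child groups are summarized as continuous profiles,
quantized to discrete profiles, aligned with the symbol-table DP, and merged
by the resulting edit string.

At most two iterations are run: the first from k-mer distances, the second
re-estimating distances from the first alignment's percent identities and
realigning from scratch.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import RunConfig
from .pairwise import AlignmentParams, align_discrete
from .profile_space import (
    CodebookParams,
    DNA,
    SamplePointCodebook,
    SampleSubstitutionTable,
    build_codebook,
    build_substitution_table,
)
from .profiles import AlignedGroup, apply_edit_string, compute_profile
from .reduction import ReductionTable, build_reduction_table, reduce_profile

__all__ = [
    "DistanceMatrix",
    "GuideTree",
    "TreeNode",
    "kmer_distance_matrix",
    "identity_distance_matrix",
    "build_guide_tree",
    "progressive_align",
    "run_msa",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric n x n distances in [0, 1] with zero diagonal."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted binary guide tree."""

    leaf_id: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.leaf_id is not None

    @property
    def size(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.size for c in self.children)

    @property
    def min_leaf(self) -> str:
        if self.is_leaf:
            return self.leaf_id
        return min(c.min_leaf for c in self.children)

    def leaf_ids(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf_id]
        return [lid for c in self.children for lid in c.leaf_ids()]

    def newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            branch = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.leaf_id}:{branch:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{branch:.6g}"

        if self.is_leaf:
            return f"{self.leaf_id};"
        inner = ",".join(render(c, self.height) for c in self.children)
        return f"({inner});"


@dataclass(frozen=True)
class GuideTree:
    root: TreeNode
    ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return self.root.size

    def newick(self) -> str:
        return self.root.newick()


# ---------------------------------------------------------------------------
# Stage 1: distances

_KMER_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _kmer_counts_scalar(seq: str, k: int) -> dict[str, int]:
    """Reference k-mer counter: plain dict over k-mer substrings.

    K-mers containing characters outside {A, C, G, T/U} are skipped.
    """
    counts: dict[str, int] = {}
    s = seq.upper().replace("U", "T")
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        if all(c in "ACGT" for c in w):
            counts[w] = counts.get(w, 0) + 1
    return counts


def _kmer_count_vector(seq: str, k: int) -> np.ndarray:
    """Vectorized k-mer counter: rolling 2-bit codes into a 4**k bincount."""
    codes = np.array([_KMER_CODE.get(c, -1) for c in seq.upper()], dtype=np.int64)
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(4 ** k, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    words = (np.where(windows >= 0, windows, 0) @ powers)[valid]
    return np.bincount(words, minlength=4 ** k).astype(np.int64)


def kmer_distance_matrix(
    seqs: Sequence[str], ids: Sequence[str] | None = None, k: int = 6
) -> DistanceMatrix:
    """Alignment-free distances from shared k-mer counts.

    For sequences a, b the similarity is
    ``F = sum_w min(count_a(w), count_b(w)) / (min(|a|, |b|) - k + 1)`` and
    the distance ``1 - F`` clamped to [0, 1].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = tuple(ids) if ids is not None else tuple(f"seq{i+1}" for i in range(len(seqs)))
    for rid, s in zip(ids, seqs):
        if len(s) < k:
            raise ValueError(f"sequence {rid!r} is shorter than k = {k}")
    vecs = np.stack([_kmer_count_vector(s, k) for s in seqs])
    n = len(seqs)
    d = np.zeros((n, n))
    lens = np.array([len(s) for s in seqs])
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.minimum(vecs[i], vecs[j]).sum()
            f = shared / (min(lens[i], lens[j]) - k + 1)
            d[i, j] = d[j, i] = min(max(1.0 - f, 0.0), 1.0)
    return DistanceMatrix(values=d, ids=ids)


def identity_distance_matrix(msa: AlignedGroup) -> DistanceMatrix:
    """1 - fractional identity for every row pair of an alignment.

    Identity counts matched residues over columns where both rows hold a
    residue; pairs with no such column get distance 1.
    """
    rows = [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in msa.rows]
    gap_codes = {ord("-"), ord(".")}
    residue = [~np.isin(r, list(gap_codes)) for r in rows]
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = residue[i] & residue[j]
            total = int(both.sum())
            if total == 0:
                d[i, j] = d[j, i] = 1.0
                continue
            matches = int((rows[i][both] == rows[j][both]).sum())
            d[i, j] = d[j, i] = 1.0 - matches / total
    return DistanceMatrix(values=d, ids=msa.ids)


# ---------------------------------------------------------------------------
# Stage 2: guide tree

def build_guide_tree(dist: DistanceMatrix) -> GuideTree:
    """UPGMA agglomeration with deterministic tie-breaking.

    The closest pair merges first; on ties the pair with the lowest cluster
    indices (creation order) wins.  Merge heights are half the merge
    distance and non-decreasing.
    """
    n = dist.n
    if n < 2:
        raise ValueError("guide tree needs at least 2 sequences")
    nodes: dict[int, TreeNode] = {i: TreeNode(leaf_id=dist.ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_idx = n
    while len(nodes) > 1:
        bi, bj = min(d, key=lambda ij: (d[ij], ij))
        h = d[bi, bj] / 2.0
        merged = TreeNode(children=(nodes[bi], nodes[bj]), height=h)
        si, sj = sizes[bi], sizes[bj]
        others = [o for o in nodes if o not in (bi, bj)]
        new_d = {}
        for o in others:
            d_oi = d[(min(o, bi), max(o, bi))]
            d_oj = d[(min(o, bj), max(o, bj))]
            # size-weighted average linkage (UPGMA)
            new_d[(o, next_idx)] = (si * d_oi + sj * d_oj) / (si + sj)
        del nodes[bi], nodes[bj], sizes[bi], sizes[bj]
        for key in [k for k in d if bi in k or bj in k]:
            del d[key]
        d.update(new_d)
        nodes[next_idx] = merged
        sizes[next_idx] = si + sj
        next_idx += 1
    root = nodes.popitem()[1]
    return GuideTree(root=root, ids=dist.ids)


# ---------------------------------------------------------------------------
# Stage 3: progressive alignment


def progressive_align(
    seqs: Sequence[str],
    tree: GuideTree,
    table: SampleSubstitutionTable,
    reduction_table: ReductionTable,
    params: AlignmentParams | None = None,
    ids: Sequence[str] | None = None,
) -> AlignedGroup:
    """Align sequences along the guide tree using discrete profiles.

    Post-order traversal; children are visited smaller subtree first (ties
    by lowest leaf id) for a deterministic merge order.  At each internal
    node both child groups are profiled, quantized and pairwise-aligned; the
    edit string merges the groups.
    """
    if params is None:
        params = AlignmentParams(table)
    ids = tuple(ids) if ids is not None else tree.ids
    by_id = dict(zip(ids, seqs))
    if set(tree.root.leaf_ids()) != set(ids):
        raise ValueError("guide tree leaves do not match sequence ids")
    alphabet = table.codebook.alphabet

    def rec(node: TreeNode) -> AlignedGroup:
        if node.is_leaf:
            return AlignedGroup([by_id[node.leaf_id]], [node.leaf_id])
        c1, c2 = sorted(node.children, key=lambda c: (c.size, c.min_leaf))
        ga, gb = rec(c1), rec(c2)
        pa = reduce_profile(compute_profile(ga, alphabet).freqs, reduction_table)
        pb = reduce_profile(compute_profile(gb, alphabet).freqs, reduction_table)
        _, edits = align_discrete(pa, pb, params)
        return apply_edit_string(ga, gb, edits)

    return rec(tree.root)


def run_msa(
    seqs: Sequence[str],
    ids: Sequence[str] | None = None,
    config: RunConfig | None = None,
) -> tuple[AlignedGroup, dict]:
    """Full progressive MSA: distances, guide tree, discrete-profile merge.

    With ``config.maxiters == 2`` the first alignment's percent identities
    re-estimate the distance matrix, the tree is rebuilt and the sequences
    realigned.  Returns the final alignment (rows in input order) and a run
    report with stage timings, codebook size and reduction-table statistics.
    """
    if len(seqs) < 2:
        raise ValueError("MSA needs at least 2 sequences")
    config = config or RunConfig()
    ids = tuple(ids) if ids is not None else tuple(f"seq{i+1}" for i in range(len(seqs)))
    seqs = [s.upper().replace("U", "T").replace(".", "-").replace("-", "") for s in seqs]
    codebook, table, rtable = build_pipeline_tables(config)
    params = AlignmentParams(table)
    report: dict = {
        "n_sequences": len(seqs),
        "codebook_size": codebook.K,
        "beta": table.beta,
        "reduction_cells": rtable.n_cells,
        "reduction_dense_cells": rtable.dense_cells,
        "iterations": [],
    }
    msa: AlignedGroup | None = None
    for it in range(1, config.maxiters + 1):
        t0 = time.perf_counter()
        if it == 1:
            dist = kmer_distance_matrix(seqs, ids, k=config.kmer)
        else:
            dist = identity_distance_matrix(msa)
        t1 = time.perf_counter()
        tree = build_guide_tree(dist)
        t2 = time.perf_counter()
        msa = progressive_align(seqs, tree, table, rtable, params, ids)
        t3 = time.perf_counter()
        report["iterations"].append(
            {"iteration": it, "stage1_s": t1 - t0, "stage2_s": t2 - t1,
             "stage3_s": t3 - t2, "columns": msa.n_columns}
        )
        report["tree_newick"] = tree.newick()
    return msa.reordered(ids), report


_PIPELINE_CACHE: dict[tuple, tuple] = {}


def build_pipeline_tables(
    config: RunConfig,
) -> tuple[SamplePointCodebook, SampleSubstitutionTable, ReductionTable]:
    """Codebook, substitution table and reduction table for a configuration.

    Deterministic in the configuration, so results are memoized per process.
    """
    key = config.cache_key()
    if key not in _PIPELINE_CACHE:
        alphabet = DNA
        cb_params = CodebookParams(
            L=config.lattice_l, T_c=config.t_c, T_d=config.t_d,
            apply_filter=config.apply_filter, max_symbols=config.max_symbols,
        )
        codebook = build_codebook(alphabet, cb_params)
        scoring = config.scoring_params(alphabet)
        table = build_substitution_table(codebook, scoring)
        rtable = build_reduction_table(codebook, scale=config.reduction_scale)
        _PIPELINE_CACHE[key] = (codebook, table, rtable)
    return _PIPELINE_CACHE[key]
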
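"""Stage 1-3 driver: distances, UPGMA, progressive alignment, run_msa."""

import numpy as np
import pytest

from dpmsa import (
    AlignedGroup,
    DistanceMatrix,
    RunConfig,
    TOY_AC,
    CodebookParams,
    build_codebook,
    build_guide_tree,
    build_pipeline_tables,
    build_reduction_table,
    build_substitution_table,
    identity_distance_matrix,
    kmer_distance_matrix,
    progressive_align,
    run_msa,
)
from dpmsa.profile_space import AlphabetSpec, BaseScoringParams, default_base_table
from dpmsa.progressive import _kmer_count_vector, _kmer_counts_scalar


class TestKmerDistance:
    def test_identical_sequences_distance_zero(self):
        d = kmer_distance_matrix(["ACGTACGT", "ACGTACGT"], k=3)
        assert d.values[0, 1] == 0.0

    def test_disjoint_kmers_distance_one(self):
        d = kmer_distance_matrix(["AAAA", "CCCC"], k=2)
        assert d.values[0, 1] == 1.0

    def test_hand_counted_example(self):
        # shared 2-mers of ACGT and CGTA: {CG, GT}; F = 2/3
        d = kmer_distance_matrix(["ACGT", "CGTA"], k=2)
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            kmer_distance_matrix(["ACGT", "AC"], ids=["a", "b"], k=3)

    def test_vectorized_and_scalar_counters_agree(self):
        """The portable array implementation must match the reference
        dictionary counter exactly."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=rng.integers(8, 60)))
            for k in (2, 3, 6):
                vec = _kmer_count_vector(seq, k)
                ref = _kmer_counts_scalar(seq, k)
                got = {w: int(c) for w, c in zip(_all_words(k), vec) if c}
                assert got == ref

    def test_zero_iff_identical_for_random_pairs(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(6)]
        d = kmer_distance_matrix(seqs, k=4)
        for i in range(6):
            for j in range(i + 1, 6):
                assert (d.values[i, j] == 0.0) == (seqs[i] == seqs[j])


def _all_words(k):
    from itertools import product
    return ("".join(w) for w in product("ACGT", repeat=k))


class TestIdentityDistance:
    def test_identical_rows(self):
        d = identity_distance_matrix(AlignedGroup(["ACG", "ACG"], ["a", "b"]))
        assert d.values[0, 1] == 0.0

    def test_hand_counted_example(self):
        # co-residue columns of AC-G / AT-G: 3, matches: 2
        d = identity_distance_matrix(AlignedGroup(["AC-G", "AT-G"], ["a", "b"]))
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_no_overlap_convention(self):
        d = identity_distance_matrix(AlignedGroup(["AC--", "--GT"], ["a", "b"]))
        assert d.values[0, 1] == 1.0


class TestGuideTree:
    def test_closest_pair_merges_first(self):
        vals = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        tree = build_guide_tree(DistanceMatrix(vals, ("s1", "s2", "s3")))
        first = min(
            (c for c in tree.root.children), key=lambda c: c.height
        )
        inner = [c for c in tree.root.children if not c.is_leaf]
        assert len(inner) == 1
        assert sorted(inner[0].leaf_ids()) == ["s1", "s2"]

    def test_all_equal_distances_cascade_by_index(self):
        n = 4
        vals = np.ones((n, n)) * 0.4
        np.fill_diagonal(vals, 0.0)
        tree = build_guide_tree(DistanceMatrix(vals, tuple(f"s{i}" for i in range(n))))
        # lowest-index tie rule: (s0, s1) merge first
        def first_merge(node):
            if node.is_leaf:
                return None
            for c in node.children:
                r = first_merge(c)
                if r is not None:
                    return r
            if all(c.is_leaf for c in node.children):
                return sorted(node.leaf_ids())
            return None
        assert first_merge(tree.root) == ["s0", "s1"]

    def test_two_leaves(self):
        vals = np.array([[0.0, 0.2], [0.2, 0.0]])
        tree = build_guide_tree(DistanceMatrix(vals, ("a", "b")))
        assert tree.root.size == 2
        assert tree.root.height == pytest.approx(0.1)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        n = 8
        m = rng.uniform(0.1, 1.0, size=(n, n))
        vals = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(vals, 0.0)
        tree = build_guide_tree(DistanceMatrix(vals, tuple(f"s{i}" for i in range(n))))

        def check(node, parent_h):
            assert node.height <= parent_h + 1e-12
            if not node.is_leaf:
                for c in node.children:
                    check(c, node.height)

        check(tree.root, np.inf)

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            build_guide_tree(DistanceMatrix(np.zeros((1, 1)), ("a",)))

    def test_newick_export_contains_all_leaves(self):
        vals = np.array([[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]])
        tree = build_guide_tree(DistanceMatrix(vals, ("s1", "s2", "s3")))
        nwk = tree.newick()
        assert nwk.endswith(";")
        for leaf in ("s1", "s2", "s3"):
            assert leaf in nwk


class TestProgressiveAlign:
    def test_toy_alphabet_example(self, toy_codebook):
        """Four sequences over {A, C, gap}: merge structure is consistent."""
        alphabet = TOY_AC
        s = default_base_table(alphabet, match=5, transversion=-4,
                               transition=-2, gap_extend=-4)
        scoring = BaseScoringParams(s=s, gap_extend=-4.0, beta=1.0)
        table = build_substitution_table(toy_codebook, scoring)
        rt = build_reduction_table(toy_codebook, scale=8)
        seqs = ["ACCA", "ACA", "CACA", "CAA"]
        d = kmer_distance_matrix(seqs, ids=list("abcd"), k=2)
        tree = build_guide_tree(d)
        msa = progressive_align(seqs, tree, table, rt, ids=list("abcd"))
        assert msa.n_rows == 4
        assert len(set(len(r) for r in msa.rows)) == 1
        assert sorted(msa.degapped_rows()) == sorted(seqs)

    def test_two_identical_sequences_gapless(self, dna_pipeline):
        cb, table, rt = dna_pipeline
        seqs = ["ACGTACGT", "ACGTACGT"]
        d = kmer_distance_matrix(seqs, k=3)
        tree = build_guide_tree(d)
        msa = progressive_align(seqs, tree, table, rt, ids=d.ids)
        assert msa.rows == ("ACGTACGT", "ACGTACGT")


class TestRunMsa:
    def test_identical_inputs_iteration_count_irrelevant(self):
        seqs = ["ACGTACGTAC"] * 3
        m1, _ = run_msa(seqs, config=RunConfig(maxiters=1, kmer=3))
        m2, _ = run_msa(seqs, config=RunConfig(maxiters=2, kmer=3))
        assert m1.rows == m2.rows

    def test_degap_recovery_and_determinism(self):
        from dpmsa import FamilyParams, generate_family

        truth, seqs = generate_family(FamilyParams(seed=99, n_sequences=8,
                                                   ancestor_length=150))
        m1, rep1 = run_msa(seqs, truth.ids, RunConfig())
        m2, rep2 = run_msa(seqs, truth.ids, RunConfig())
        assert m1.rows == m2.rows  # byte-identical
        assert m1.degapped_rows() == tuple(seqs)
        assert rep1["codebook_size"] == rep2["codebook_size"]
        assert len(rep1["iterations"]) == 2

    def test_rows_in_input_order(self):
        seqs = ["ACGTACAG", "TTACGTAC", "ACGTTCAG"]
        msa, _ = run_msa(seqs, ["z", "y", "x"], RunConfig(kmer=3))
        assert msa.ids == ("z", "y", "x")

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            run_msa(["ACGT"], config=RunConfig())
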
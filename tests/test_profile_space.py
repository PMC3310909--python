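"""Codebook generation: lattice band, projection, filter, substitution table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpmsa import (
    AlphabetSpec,
    BaseScoringParams,
    CodebookParams,
    DNA,
    TOY_AC,
    SamplePointCodebook,
    build_codebook,
    build_substitution_table,
    default_base_table,
    filter_improbable,
    generate_lattice_points,
    project_to_simplex,
)
from dpmsa.profile_space import lattice_point_count, round_half_away

from oracles import lattice_points_bruteforce, substitution_score_bruteforce


class TestLattice:
    @pytest.mark.parametrize("D,L,expected", [(3, 4, 16), (2, 2, 2), (5, 1, 1)])
    def test_band_counts(self, D, L, expected):
        pts = generate_lattice_points(D, L)
        assert pts.shape == (expected, D)

    @pytest.mark.parametrize("D", range(2, 6))
    @pytest.mark.parametrize("L", range(1, 7))
    def test_matches_bruteforce_enumeration(self, D, L):
        pts = generate_lattice_points(D, L)
        brute = lattice_points_bruteforce(D, L)
        assert len(pts) == len(brute) == lattice_point_count(D, L)
        got = {tuple(np.round(p * L).astype(int)) for p in pts}
        assert got == set(brute)

    def test_band_condition_holds(self):
        for D, L in [(3, 4), (5, 4), (4, 6)]:
            sums = generate_lattice_points(D, L).sum(axis=1)
            assert np.all(sums <= 1 - 1 / L + 1e-12)
            assert np.all(sums >= max(0.0, 1 - (D - 1) / L) - 1e-12)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            generate_lattice_points(1, 4)
        with pytest.raises(ValueError):
            generate_lattice_points(3, 0)


class TestProjection:
    def test_origin_projects_to_centroid(self):
        assert np.allclose(project_to_simplex(np.zeros(3)), np.full(3, 1 / 3))

    def test_simplex_point_is_fixed(self):
        p = np.array([0.2, 0.3, 0.5])
        assert np.allclose(project_to_simplex(p), p)

    def test_direct_arithmetic_example(self):
        got = project_to_simplex(np.array([0.25, 0.25, 0.0]))
        assert np.allclose(got, [0.25 + 1 / 6, 0.25 + 1 / 6, 1 / 6])
        assert got.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True)
    @given(st.lists(st.floats(0, 0.3), min_size=3, max_size=6))
    def test_projection_lands_on_simplex(self, coords):
        p = np.array(coords)
        assert project_to_simplex(p).sum() == pytest.approx(1.0, abs=1e-9)


class TestFilter:
    def test_balanced_purine_pyrimidine_point_eliminated(self):
        pts = np.array([[0.4, 0.4, 0.1, 0.1, 0.0]])  # A + C = 0.8, |A-C| = 0
        assert filter_improbable(pts, 0.75, 0.30).shape[0] == 0

    def test_residue_corner_retained(self):
        pts = np.eye(5)[:1]  # pure A: every pair fails the difference test
        assert filter_improbable(pts, 0.75, 0.30).shape[0] == 1

    def test_tc_one_keeps_everything(self):
        rng = np.random.default_rng(0)
        pts = rng.dirichlet(np.ones(5), size=50)
        assert filter_improbable(pts, 1.0, 0.30).shape[0] == 50

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        pts = rng.dirichlet(np.ones(5), size=200)
        base = {tuple(p) for p in filter_improbable(pts, 0.75, 0.30)}
        looser_tc = {tuple(p) for p in filter_improbable(pts, 0.85, 0.30)}
        looser_td = {tuple(p) for p in filter_improbable(pts, 0.75, 0.20)}
        assert base <= looser_tc
        assert base <= looser_td

    def test_rejects_out_of_range_thresholds(self):
        with pytest.raises(ValueError):
            filter_improbable(np.eye(5)[:1], 1.5, 0.3)


class TestCodebook:
    def test_unfiltered_dna_codebook_size(self):
        cb = build_codebook(DNA, CodebookParams(L=4, apply_filter=False))
        # 56 in-band lattice points + 4 residue corners, within the 64 cap
        assert cb.K == 60
        assert cb.is_corner.sum() == 4

    def test_toy_codebook_size(self, toy_codebook):
        assert toy_codebook.K == 18  # 16 lattice + 2 residue corners
        assert toy_codebook.is_corner.sum() == 2

    def test_simplex_closure_and_distinctness(self, dna_codebook):
        pts = dna_codebook.points
        assert np.allclose(pts.sum(axis=1), 1.0, atol=1e-9)
        assert pts.min() >= 0 and pts.max() <= 1
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1e-9

    def test_all_gap_corner_absent(self, dna_codebook):
        gap_corner = np.zeros(5)
        gap_corner[-1] = 1.0
        assert not np.any(np.all(dna_codebook.points == gap_corner, axis=1))

    def test_every_residue_corner_present(self, dna_codebook):
        for c in "ACGT":
            sym = dna_codebook.corner_symbol(c)
            assert dna_codebook.points[sym, DNA.index_of(c)] == 1.0

    def test_symbol_cap_enforced(self):
        with pytest.raises(ValueError, match="exceed"):
            build_codebook(DNA, CodebookParams(L=6, apply_filter=False, max_symbols=64))

    def test_epsilon_is_plane_spacing(self, dna_codebook):
        assert dna_codebook.epsilon == pytest.approx(np.sqrt(5) / (5 * 4))

    def test_deterministic_order(self):
        a = build_codebook(DNA, CodebookParams())
        b = build_codebook(DNA, CodebookParams())
        assert np.array_equal(a.points, b.points)

    def test_tsv_round_trip(self, dna_codebook, tmp_path):
        path = tmp_path / "cb.tsv"
        dna_codebook.to_tsv(path)
        back = SamplePointCodebook.from_tsv(path)
        assert np.allclose(back.points, dna_codebook.points)
        assert np.array_equal(back.is_corner, dna_codebook.is_corner)
        assert back.params == dna_codebook.params


class TestSubstitutionTable:
    def test_corner_pair_reproduces_base_entry(self, dna_codebook):
        scoring = BaseScoringParams(beta=1.0)
        t = build_substitution_table(dna_codebook, scoring)
        a = dna_codebook.corner_symbol("A")
        c = dna_codebook.corner_symbol("C")
        assert t.table[a, c] == -4  # transversion
        g = dna_codebook.corner_symbol("G")
        assert t.table[a, g] == -2  # transition
        assert t.table[a, a] == 5

    def test_symmetry(self, dna_table):
        assert np.array_equal(dna_table.table, dna_table.table.T)

    def test_matches_bruteforce_double_sum(self, dna_codebook):
        scoring = BaseScoringParams(beta=1.0)
        t = build_substitution_table(dna_codebook, scoring)
        rng = np.random.default_rng(7)
        for _ in range(25):
            i, j = rng.integers(dna_codebook.K, size=2)
            raw = substitution_score_bruteforce(
                dna_codebook.points[i], dna_codebook.points[j], scoring.s, 1.0
            )
            assert t.table[i, j] == round_half_away(np.array(raw))

    def test_gap_dominated_point_value(self):
        # corner T against a column that is 3/4 gap, 1/4 T
        gap_heavy = np.array([0.0, 0.0, 0.0, 0.25, 0.75])
        cb = SamplePointCodebook(
            points=np.vstack([np.eye(5)[:4], gap_heavy]),
            is_corner=np.array([True] * 4 + [False]),
            alphabet=DNA, params=CodebookParams(),
        )
        t = build_substitution_table(cb, BaseScoringParams(beta=1.0))
        expected = 0.25 * 5 + 0.75 * (-3)  # f_T*s[T,T] + f_gap*(gap_extend+1)
        assert t.table[cb.corner_symbol("T"), 4] == round_half_away(np.array(expected))

    def test_entries_fit_entry_bits(self, dna_codebook):
        t4 = build_substitution_table(dna_codebook, BaseScoringParams(entry_bits=4))
        assert t4.table.min() >= -8 and t4.table.max() <= 7
        t8 = build_substitution_table(dna_codebook, BaseScoringParams(entry_bits=8))
        assert t8.table.min() >= -128 and t8.table.max() <= 127

    def test_auto_beta_is_power_of_two(self, dna_codebook):
        big = default_base_table(DNA, match=500.0, transversion=-400.0,
                                 transition=-200.0, gap_extend=-400.0)
        scoring = BaseScoringParams(s=big, gap_extend=-400.0, entry_bits=8)
        t = build_substitution_table(dna_codebook, scoring)
        assert t.beta == 4.0  # 500/4 = 125 fits, 500/2 does not
        assert t.table.max() <= 127

    def test_overflow_with_fixed_beta_raises(self, dna_codebook):
        big = default_base_table(DNA, match=500.0, transversion=-400.0,
                                 transition=-200.0, gap_extend=-400.0)
        scoring = BaseScoringParams(s=big, gap_extend=-400.0, beta=1.0)
        with pytest.raises(ValueError, match="does not fit"):
            build_substitution_table(dna_codebook, scoring)

    def test_gap_rule_enforced(self, dna_codebook):
        s = default_base_table(DNA)
        s[4, 0] = s[0, 4] = -7.0  # violate s[gap, A] = gap_extend + 1
        with pytest.raises(ValueError, match="gap rule"):
            build_substitution_table(dna_codebook, BaseScoringParams(s=s))


class TestAlphabet:
    def test_u_folds_to_t(self):
        assert DNA.index_of("U") == DNA.index_of("T")
        assert DNA.index_of("u") == DNA.index_of("t")

    def test_gap_is_last_coordinate(self):
        assert DNA.gap_index == DNA.D - 1

    def test_purine_pyrimidine_classes(self):
        assert DNA.purine_indices == (0, 2)  # A, G
        assert DNA.pyrimidine_indices == (1, 3)  # C, T
        assert TOY_AC.purine_indices == (0,)
        assert TOY_AC.pyrimidine_indices == (1,)

    def test_rejects_duplicate_characters(self):
        with pytest.raises(ValueError):
            AlphabetSpec(characters=("A", "A", "C"))
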
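"""Scoring scheme and the three DP engines, against independent oracles."""

import random

import numpy as np
import pytest

from conftest import (
    dp_oracle_score,
    enumerate_alignment_score,
    mutate_sequence,
    random_profile,
    single_profile,
)
from promsa.pair_align import (
    BAND_FAIL,
    AlignmentResult,
    _AlignFailure,
    align_profiles_banded,
    align_profiles_full,
    align_profiles_tiled,
    align_with_fallback,
    default_scheme,
    position_gap_penalties,
    profile_cell_score,
)
from promsa.profile import Profile, build_profile
from promsa.seq_io import ALPHABET_INDEX, RunConfig


class TestDefaultScheme:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            ("A", "A", 18.0),
            ("C", "C", 18.0),
            ("A", "G", 5.0),
            ("C", "T", 5.0),
            ("A", "T", -8.0),
            ("A", "C", -8.0),
            ("G", "T", -8.0),
            ("A", "-", -5.0),
            ("N", "-", -5.0),
            ("-", "-", 0.0),
            ("N", "A", 0.0),
        ],
    )
    def test_entries(self, p, q, expected):
        sch = default_scheme()
        assert sch.score(p, q) == expected
        assert sch.score(q, p) == expected

    def test_gap_penalties(self):
        sch = default_scheme()
        assert sch.gop == -50.0
        assert sch.gep == -5.0

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            # asymmetric table
            s = np.zeros((6, 6))
            s[0, 1] = 1.0
            from promsa.pair_align import SubstitutionScheme

            SubstitutionScheme(s=s, gop=-50, gep=-5)


class TestPositionGapPenalties:
    def test_gap_free_column_unchanged(self):
        sch = default_scheme(psgp_enabled=True)
        p = build_profile({"a": "ACGT"}, {"a": 1.0})
        gop, gep = position_gap_penalties(p, sch)
        assert (gop == -50.0).all()
        assert (gep == -5.0).all()

    def test_half_gap_column(self):
        sch = default_scheme(psgp_enabled=True)
        p = build_profile({"a": "A", "b": "-"}, {"a": 1.0, "b": 1.0})
        gop, gep = position_gap_penalties(p, sch)
        assert gop[0] == pytest.approx(-50 * 0.3 * 0.5)  # -7.5
        assert gep[0] == pytest.approx(-2.5)

    def test_all_gap_column_free_to_open(self):
        sch = default_scheme(psgp_enabled=True)
        p = Profile(
            freq=np.array([[0, 0, 0, 0, 0, 1.0]]), total_weight=1.0
        )
        gop, gep = position_gap_penalties(p, sch)
        assert gop[0] == 0.0


class TestProfileCellScore:
    def test_single_sequence_profiles_reduce_to_matrix(self, scheme):
        assert profile_cell_score(single_profile("A"), 0, single_profile("A"), 0, scheme) == 18.0

    def test_mixed_column_double_sum(self, scheme):
        pa = build_profile({"a": "A", "b": "G"}, {"a": 0.5, "b": 0.5})
        pb = single_profile("A")
        # 0.5*18 + 0.5*5 = 11.5
        assert profile_cell_score(pa, 0, pb, 0, scheme) == pytest.approx(11.5)

    def test_symmetry(self, scheme):
        rng = random.Random(2)
        for _ in range(10):
            pa = random_profile(rng, 3)
            pb = random_profile(rng, 4)
            assert profile_cell_score(pa, 1, pb, 2, scheme) == pytest.approx(
                profile_cell_score(pb, 2, pa, 1, scheme)
            )


class TestFullDP:
    def test_identical_sequences_all_match(self, scheme):
        s = "ACGTACGTAC"
        r = align_profiles_full(single_profile(s), single_profile(s), scheme)
        assert r.ops == "M" * len(s)
        assert r.score == 18.0 * len(s)

    def test_empty_vs_k(self, scheme):
        empty = Profile(freq=np.zeros((0, 6)), total_weight=1.0)
        r = align_profiles_full(empty, single_profile("ACGT"), scheme)
        assert r.score == -50.0 + 3 * -5.0
        assert r.ops == "AAAA"

    def test_matches_exhaustive_enumeration(self, scheme):
        rng = random.Random(8)
        for _ in range(30):
            la, lb = rng.randint(1, 4), rng.randint(1, 4)
            pa = random_profile(rng, la, n_rows=2)
            pb = random_profile(rng, lb, n_rows=2)
            expected = enumerate_alignment_score(pa, pb, scheme)
            got = align_profiles_full(pa, pb, scheme)
            assert got.score == pytest.approx(expected, abs=1e-9)

    def test_matches_independent_dp(self, scheme):
        rng = random.Random(9)
        for _ in range(60):
            pa = random_profile(rng, rng.randint(1, 12))
            pb = random_profile(rng, rng.randint(1, 12))
            assert align_profiles_full(pa, pb, scheme).score == pytest.approx(
                dp_oracle_score(pa, pb, scheme), abs=1e-9
            )

    def test_matches_independent_dp_with_psgp(self):
        sch = default_scheme(psgp_enabled=True)
        rng = random.Random(10)
        for _ in range(30):
            pa = random_profile(rng, rng.randint(1, 10))
            pb = random_profile(rng, rng.randint(1, 10))
            gapsA = position_gap_penalties(pa, sch)
            gapsB = position_gap_penalties(pb, sch)
            assert align_profiles_full(pa, pb, sch).score == pytest.approx(
                dp_oracle_score(pa, pb, sch, gapsA, gapsB), abs=1e-9
            )

    def test_matches_classic_affine_needleman_wunsch(self, scheme):
        """Single-sequence unit-weight profiles reduce to textbook global
        affine-gap alignment; cross-check against Biopython's aligner."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        m = substitution_matrices.Array("ACGT", dims=2)
        for p in "ACGT":
            for q in "ACGT":
                m[p, q] = scheme.score(p, q)
        aligner.substitution_matrix = m
        aligner.mode = "global"
        aligner.open_gap_score = scheme.gop
        aligner.extend_gap_score = scheme.gep

        rng = random.Random(13)
        for _ in range(60):
            sa = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 15)))
            sb = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 15)))
            ours = align_profiles_full(single_profile(sa), single_profile(sb), scheme)
            assert ours.score == pytest.approx(aligner.score(sa, sb), abs=1e-9)

    def test_score_symmetric_mirrored_paths(self, scheme):
        rng = random.Random(14)
        for _ in range(20):
            pa = random_profile(rng, rng.randint(1, 8))
            pb = random_profile(rng, rng.randint(1, 8))
            ab = align_profiles_full(pa, pb, scheme)
            ba = align_profiles_full(pb, pa, scheme)
            assert ab.score == pytest.approx(ba.score, abs=1e-9)
            assert ab.pathA.count("0") == ba.pathB.count("0")

    def test_deterministic(self, scheme):
        rng = random.Random(15)
        pa = random_profile(rng, 9)
        pb = random_profile(rng, 7)
        r1 = align_profiles_full(pa, pb, scheme)
        r2 = align_profiles_full(pa, pb, scheme)
        assert (r1.ops, r1.score) == (r2.ops, r2.score)

    def test_positive_shift_keeps_gap_free_optimum(self, scheme):
        from promsa.pair_align import SubstitutionScheme

        s = "ACGTTGCA"
        shifted = SubstitutionScheme(
            s=scheme.s + 7.0, gop=scheme.gop, gep=scheme.gep
        )
        r1 = align_profiles_full(single_profile(s), single_profile(s), scheme)
        r2 = align_profiles_full(single_profile(s), single_profile(s), shifted)
        assert r1.ops == r2.ops == "M" * len(s)


class TestBandedDP:
    def test_infinite_xdrop_equals_full(self, scheme):
        rng = random.Random(20)
        for _ in range(60):
            pa = random_profile(rng, rng.randint(1, 12))
            pb = random_profile(rng, rng.randint(1, 12))
            f = align_profiles_full(pa, pb, scheme)
            b = align_profiles_banded(pa, pb, scheme, float("inf"))
            assert (b.score, b.ops) == (f.score, f.ops)

    def test_default_xdrop_on_similar_profiles(self, scheme):
        rng = random.Random(21)
        for _ in range(5):
            s = "".join(rng.choice("ACGT") for _ in range(200))
            s2 = mutate_sequence(rng, s, 0.05, 0.01)
            f = align_profiles_full(single_profile(s), single_profile(s2), scheme)
            b = align_profiles_banded(single_profile(s), single_profile(s2), scheme, 3000.0)
            assert (b.score, b.ops) == (f.score, f.ops)

    def test_zero_xdrop_identical_sequences_complete(self, scheme):
        s = "ACGTACGT"
        b = align_profiles_banded(single_profile(s), single_profile(s), scheme, 0.0)
        assert b.ops == "M" * len(s)

    def test_zero_xdrop_forced_gap_fails(self, scheme):
        b = align_profiles_banded(
            single_profile("AAAAAA"), single_profile("A"), scheme, 0.0
        )
        assert b is BAND_FAIL


class TestTiledDP:
    def test_single_tile_degenerates_to_banded(self, scheme):
        rng = random.Random(30)
        for _ in range(30):
            pa = random_profile(rng, rng.randint(1, 10))
            pb = random_profile(rng, rng.randint(1, 10))
            b = align_profiles_banded(pa, pb, scheme, 1e9)
            t = align_profiles_tiled(pa, pb, scheme, 64, 1e9)
            assert not isinstance(t, _AlignFailure)
            assert (t.score, t.ops) == (b.score, b.ops)

    def test_equals_full_when_no_fail(self, scheme):
        rng = random.Random(31)
        checked = 0
        for _ in range(60):
            pa = random_profile(rng, rng.randint(1, 12))
            pb = random_profile(rng, rng.randint(1, 12))
            f = align_profiles_full(pa, pb, scheme)
            t = align_profiles_tiled(pa, pb, scheme, 16, 1e9)
            if not isinstance(t, _AlignFailure):
                assert (t.score, t.ops) == (f.score, f.ops)
                checked += 1
        assert checked > 10

    def test_multi_tile_long_similar_sequences(self, scheme):
        rng = random.Random(32)
        s = "".join(rng.choice("ACGT") for _ in range(400))
        s2 = mutate_sequence(rng, s, 0.08, 0.03)
        b = align_profiles_banded(single_profile(s), single_profile(s2), scheme, 250.0)
        t = align_profiles_tiled(single_profile(s), single_profile(s2), scheme, 48, 250.0)
        assert not isinstance(b, _AlignFailure)
        if not isinstance(t, _AlignFailure):
            assert (t.score, t.ops) == (b.score, b.ops)

    def test_pointer_storage_bounded_by_tile_size(self, scheme):
        """Traceback pointer storage must not grow with sequence length."""
        rng = random.Random(33)
        tile = 48
        peaks = {}
        for L in (100, 500, 2000):
            s = "".join(rng.choice("ACGT") for _ in range(L))
            s2 = mutate_sequence(rng, s, 0.03, 0.01)
            t = align_profiles_tiled(
                single_profile(s), single_profile(s2), scheme, tile, 250.0
            )
            if isinstance(t, _AlignFailure):
                continue
            peaks[L] = t.pointer_cells
        assert len(peaks) >= 2
        bound = 2 * tile * (tile + 3)  # window of <= 2*tile wavefronts, each <= tile+2 wide
        assert all(p <= bound for p in peaks.values())


class TestFallback:
    def test_cooperative_inputs_use_tiled(self, scheme):
        cfg = RunConfig()
        s = "ACGTACGTACGT"
        r = align_with_fallback(single_profile(s), single_profile(s), scheme, cfg)
        assert r.ops == "M" * len(s)

    def test_adversarial_inputs_fall_back_to_full(self, scheme):
        cfg = RunConfig(xdrop=0.0, tile_size=2)
        pa = single_profile("AAAAAAAAAA")
        pb = single_profile("A")
        r = align_with_fallback(pa, pb, scheme, cfg)
        assert isinstance(r, AlignmentResult)
        assert r.pathA.count("0") == 10
        assert r.pathB.count("0") == 1

    def test_result_invariants_on_random_inputs(self, scheme):
        rng = random.Random(40)
        cfg = RunConfig(tile_size=8)
        for _ in range(40):
            pa = random_profile(rng, rng.randint(1, 15))
            pb = random_profile(rng, rng.randint(1, 15))
            r = align_with_fallback(pa, pb, scheme, cfg)
            assert isinstance(r, AlignmentResult)
            assert r.pathA.count("0") == pa.length
            assert r.pathB.count("0") == pb.length
            assert len(r.pathA) == len(r.pathB) == len(r.ops)
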
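"""Complementarity alignment, overhang handling and pattern encoding."""

import numpy as np
import pytest

from conftest import random_rna
from mireader.assembly import Contig
from mireader.duplex import (
    DuplexCandidate, EncodedPattern, ScoringScheme,
    complement_align, encode_duplex, select_duplexes,
)
from oracles import (
    align_score_recursive, biopython_core_scorer,
    enumerate_alignments_score, overhang_align_oracle,
)

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"
RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(s):
    return "".join(RC[c] for c in reversed(s))


class TestComplementAlign:
    def test_perfect_complement(self):
        c = complement_align(LET7, revcomp(LET7))
        assert c.score == len(LET7) * 2
        assert str(c.pattern) == "M" * len(LET7)
        assert (c.overhang_top3, c.overhang_bottom3) == (0, 0)

    def test_single_wobble_column(self):
        # make column 10 a G:U pair instead of Watson-Crick
        bottom = list(revcomp(LET7))
        # column i pairs top[i] with reversed-bottom[i] = bottom[L-1-i]
        i = 10
        assert LET7[i] == "G"
        bottom[len(LET7) - 1 - i] = "U"
        c = complement_align(LET7, "".join(bottom))
        assert c.score == 21 * 2 + 1
        assert str(c.pattern) == "M" * len(LET7)

    def test_single_mismatch_column(self):
        bottom = list(revcomp(LET7))
        i = 9
        assert LET7[i] == "A"
        bottom[len(LET7) - 1 - i] = "G"  # A:G pairs with nothing
        c = complement_align(LET7, "".join(bottom))
        assert c.score == 21 * 2 - 1
        assert str(c.pattern) == "M" * 9 + "X" + "M" * 12

    def test_bottom_3prime_overhang_free(self):
        bottom = revcomp(LET7) + "CA"  # 2 extra nt at bottom's 3' end
        c = complement_align(LET7, bottom)
        assert c.overhang_bottom3 == 2
        assert c.score == len(LET7) * 2  # overhang unscored
        assert str(c.pattern) == "M" * len(LET7)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            complement_align("", "ACGU")

    def test_score_symmetry(self, rng):
        for _ in range(50):
            a = random_rna(rng, int(rng.integers(8, 20)))
            b = random_rna(rng, int(rng.integers(8, 20)))
            assert complement_align(a, b).score == complement_align(b, a).score

    def test_self_complement_identity(self, rng):
        for _ in range(20):
            s = random_rna(rng, int(rng.integers(10, 30)))
            assert complement_align(s, revcomp(s)).score == 2 * len(s)

    def test_matches_complete_enumeration_small(self, rng):
        """Score equals complete alignment-path enumeration (lengths <= 5)."""
        sch = ScoringScheme()
        for _ in range(80):
            a = random_rna(rng, int(rng.integers(1, 6)))
            b = random_rna(rng, int(rng.integers(1, 6)))
            want = overhang_align_oracle(a, b, enumerate_alignments_score)
            assert complement_align(a, b, sch).score == pytest.approx(want)

    def test_matches_memoized_recursion_mid(self, rng):
        """Score equals a top-down memoized affine recursion (lengths <= 10)."""
        for _ in range(40):
            a = random_rna(rng, int(rng.integers(4, 11)))
            b = random_rna(rng, int(rng.integers(4, 11)))
            want = overhang_align_oracle(a, b, align_score_recursive)
            assert complement_align(a, b).score == pytest.approx(want)

    def test_matches_biopython_reference(self, rng):
        """Score equals an independent Bio.Align affine-gap aligner at 22 nt."""
        core = biopython_core_scorer()
        for _ in range(60):
            a = random_rna(rng, int(rng.integers(15, 31)))
            b = random_rna(rng, int(rng.integers(15, 31)))
            want = overhang_align_oracle(a, b, core)
            assert complement_align(a, b).score == pytest.approx(want)


class TestEncode:
    def test_conservation_over_generated_duplexes(self, rng):
        for _ in range(150):
            a = random_rna(rng, int(rng.integers(10, 26)))
            b = random_rna(rng, int(rng.integers(10, 26)))
            c = complement_align(a, b)
            p = str(c.pattern)
            assert len(p) == c.paired_columns
            assert sum(p.count(s) for s in "MXID") == len(p)

    def test_gap_in_bottom_is_insertion(self):
        # top has one extra base relative to the complement of bottom
        top = LET7[:10] + "A" + LET7[10:]
        c = complement_align(top, revcomp(LET7))
        assert str(c.pattern).count("I") == 1
        assert "D" not in str(c.pattern)

    def test_gap_in_top_is_deletion(self):
        bottom = revcomp(LET7[:10] + "A" + LET7[10:])
        c = complement_align(LET7, bottom)
        assert str(c.pattern).count("D") == 1

    def test_pattern_alphabet_guard(self):
        with pytest.raises(ValueError):
            EncodedPattern("MMZQ")
        with pytest.raises(ValueError):
            EncodedPattern("")


def _contig(seq, count=1):
    c = Contig(seq, {"r": (0, count)})
    c._member_lengths = {"r": len(seq)}
    return c


class TestSelectDuplexes:
    def test_unique_best_pair(self):
        contigs = [_contig(LET7, 5), _contig(revcomp(LET7), 2),
                   _contig("ACACACACACACACACAC", 1)]
        dups, unpaired = select_duplexes(contigs)
        assert len(dups) == 1
        assert dups[0].score == 2 * len(LET7)
        assert len(unpaired) == 1

    def test_min_score_threshold_leaves_unpaired(self):
        contigs = [_contig("AAAAAAAAAAAAAAA"), _contig("CACACACACACACAC")]
        dups, unpaired = select_duplexes(contigs, min_score=100.0,
                                         policy="threshold")
        assert dups == [] and len(unpaired) == 2

    def test_top_strand_is_higher_count(self):
        a, b = _contig(LET7, 2), _contig(revcomp(LET7), 9)
        dups, _ = select_duplexes([a, b], contig_ids=["low", "high"])
        assert dups[0].top_id == "high"

    def test_each_contig_in_at_most_one_duplex(self, rng):
        contigs = [_contig(random_rna(rng, 20), int(rng.integers(1, 9)))
                   for _ in range(9)]
        dups, unpaired = select_duplexes(contigs, policy="threshold",
                                         min_score=-100)
        seen = [d.top_id for d in dups] + [d.bottom_id for d in dups] + unpaired
        assert sorted(seen) == sorted({s for s in seen})
        assert len(seen) == 9

    def test_permutation_invariance(self, rng):
        contigs = [_contig(random_rna(rng, 20), int(rng.integers(1, 9)))
                   for _ in range(7)]
        ids = [f"c{i}" for i in range(7)]
        base, _ = select_duplexes(contigs, contig_ids=ids)
        pairs = {(d.top_id, d.bottom_id) for d in base}
        for _ in range(3):
            perm = list(rng.permutation(7))
            got, _ = select_duplexes([contigs[i] for i in perm],
                                     contig_ids=[ids[i] for i in perm])
            assert {(d.top_id, d.bottom_id) for d in got} == pairs

    def test_flagged_contigs_excluded(self):
        a, b = _contig(LET7), _contig(revcomp(LET7))
        a.flagged = True
        dups, unpaired = select_duplexes([a, b])
        assert dups == []


def test_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=-1, gap_extend=-5)
    with pytest.raises(ValueError):
        ScoringScheme(max_overhang=3)


def test_duplex_tsv_roundtrip(tmp_path):
    from mireader.duplex import write_duplexes_tsv

    c = complement_align(LET7, revcomp(LET7))
    c.top_id, c.bottom_id = "a", "b"
    path = tmp_path / "d.tsv"
    write_duplexes_tsv([c], path)
    body = path.read_text().splitlines()
    assert body[1].startswith("a\tb\t44\t")
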
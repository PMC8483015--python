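"""Vector detection/masking/removal and circularity-aware re-organization."""

import numpy as np
import pytest

from fosmidforge import (
    build_construct,
    detect_terminal_overlap,
    detect_vector,
    filter_contigs,
    mask_vector,
    random_dna,
    reorganize_contig,
    revcomp,
)
from fosmidforge.assembly import Contig

from _oracles import dp_align


def _mutate(rng, seq, n_subs):
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
    return "".join(s)


class TestDetectVector:
    def test_exact_embedding_coords_identity_strand(self, rng):
        vector = random_dna(rng, 400)
        contig = Contig("c", random_dna(rng, 2000) + vector + random_dna(rng, 1600), 50)
        [m] = detect_vector(contig, vector)
        assert (m.start, m.end, m.strand) == (2000, 2400, "+")
        assert m.identity == 1.0
        assert m.vector_span == (0, 400)

    def test_reverse_complement_matches_dp_oracle(self, rng):
        vector = random_dna(rng, 300)
        left = random_dna(rng, 700)
        contig = Contig("c", left + revcomp(vector) + random_dna(rng, 600), 50)
        [m] = detect_vector(contig, vector)
        assert m.strand == "-"
        ora = dp_align(contig.seq, revcomp(vector), gap_open=0, gap_extend=3,
                       local=True)
        assert (m.start, m.end) == (ora["q_start"], ora["q_end"]) == (700, 1000)
        assert abs(m.identity - ora["n_match"] / ora["n_cols"]) < 1e-9

    def test_no_homology_returns_empty(self, rng):
        contig = Contig("c", random_dna(rng, 1500), 50)
        assert detect_vector(contig, random_dna(rng, 400)) == []

    def test_two_disjoint_occurrences_found(self, rng):
        v = random_dna(rng, 250)
        contig = Contig(
            "c", v + random_dna(rng, 900) + revcomp(v) + random_dna(rng, 300), 50
        )
        ms = detect_vector(contig, v)
        assert [(m.start, m.end, m.strand) for m in ms] == [
            (0, 250, "+"),
            (1150, 1400, "-"),
        ]

    def test_contig_shorter_than_min_match_len(self, rng):
        assert detect_vector(Contig("c", "ACGT" * 10, 1), random_dna(rng, 300)) == []

    def test_large_seeded_path_agrees_with_small_path(self, rng):
        """The seeded/banded detector (big contigs) finds the same match as
        exhaustive Smith-Waterman does on the same construct."""
        vector = random_dna(rng, 2500)
        ins = random_dna(rng, 6000)
        contig = Contig("c", ins[:3500] + _mutate(rng, vector, 25) + ins[3500:], 80)
        [m_big] = detect_vector(contig, vector)  # 8.5kb x 2.5kb -> seeded path
        ora = dp_align(contig.seq, vector, gap_open=0, gap_extend=3, local=True)
        assert (m_big.start, m_big.end) == (ora["q_start"], ora["q_end"])
        assert m_big.identity >= 0.98


class TestMaskVector:
    def test_exact_mask_span(self, make_contig, rng):
        c = make_contig(random_dna(rng, 100))
        from fosmidforge.vectorops import VectorMatch

        m = VectorMatch("c1", 10, 20, "+", 1.0, (0, 10))
        out = mask_vector(c, [m])
        assert len(out.seq) == 100
        assert out.seq[10:20] == "X" * 10
        assert "X" not in out.seq[:10] + out.seq[20:]

    def test_overlapping_intervals_union(self, make_contig, rng):
        from fosmidforge.vectorops import VectorMatch

        c = make_contig(random_dna(rng, 100))
        ms = [VectorMatch("c1", 10, 20, "+", 1.0, (0, 10)),
              VectorMatch("c1", 15, 30, "+", 1.0, (0, 15))]
        out = mask_vector(c, ms)
        assert out.seq.count("X") == 20
        assert out.seq[10:30] == "X" * 20

    def test_empty_matches_identity(self, make_contig, rng):
        c = make_contig(random_dna(rng, 50))
        assert mask_vector(c, []).seq == c.seq


class TestFilterContigs:
    @pytest.mark.parametrize(
        "length,cov,kept",
        [
            (1000, 50.0, False),  # boundary length removed (strictly longer)
            (1001, 8.0, False),  # boundary coverage removed (strictly above)
            (1001, 8.01, True),
            (5000, 150.0, True),
            (999, 100.0, False),
        ],
    )
    def test_strict_boundaries(self, length, cov, kept, rng):
        c = Contig("c", "A" * length, cov)
        assert (filter_contigs([c]) == [c]) is kept

    def test_nan_coverage_retained(self):
        c = Contig("c", "A" * 2000, float("nan"))
        assert filter_contigs([c]) == [c]

    def test_order_preserved(self, rng):
        cs = [Contig(f"c{i}", "A" * (1500 + i), 20.0) for i in range(5)]
        assert [c.contig_id for c in filter_contigs(cs)] == [c.contig_id for c in cs]


class TestDetectTerminalOverlap:
    def test_exact_500bp_overlap(self, rng):
        ov = random_dna(rng, 500)
        right = random_dna(rng, 1500) + ov
        left = ov + random_dna(rng, 1200)
        assert detect_terminal_overlap(right, left) == 500

    def test_two_substitution_overlap(self, rng):
        ov = random_dna(rng, 500)
        right = random_dna(rng, 1500) + ov
        mutated = _mutate(rng, ov, 2)
        left = mutated + random_dna(rng, 1200)
        assert detect_terminal_overlap(right, left, min_identity=0.98) == 500

    def test_unrelated_ends_none(self, rng):
        assert detect_terminal_overlap(random_dna(rng, 800), random_dna(rng, 800)) is None

    def test_below_min_len_rejected(self, rng):
        ov = random_dna(rng, 15)
        right = random_dna(rng, 500) + ov
        left = ov + random_dna(rng, 500)
        assert detect_terminal_overlap(right, left, min_len=20) is None


def _match_for(contig_seq, vector, cid="c1"):
    [m] = detect_vector(Contig(cid, contig_seq, 50.0), vector)
    return m


class TestReorganizeContig:
    def test_no_vector_unchanged(self, make_contig, rng):
        c = make_contig(random_dna(rng, 3000))
        out = reorganize_contig(c, [])
        assert out.case == "no_vector" and out.contigs_out == [c]

    def test_vector_at_start_trimmed(self, rng, small_vector):
        ins = random_dna(rng, 4000)
        c = Contig("c", small_vector + ins, 50.0)
        m = _match_for(c.seq, small_vector)
        out = reorganize_contig(c, [m])
        assert out.case == "trimmed_extremity"
        assert [x.seq for x in out.contigs_out] == [ins]

    def test_internal_no_overlap_split_two(self, rng, small_vector):
        a, b = random_dna(rng, 2000), random_dna(rng, 2500)
        c = Contig("c", a + small_vector + b, 50.0)
        m = _match_for(c.seq, small_vector)
        out = reorganize_contig(c, [m])
        assert out.case == "split_two"
        assert [x.seq for x in out.contigs_out] == [a, b]

    def test_internal_with_overlap_joined_as_rotation(self, rng, small_vector):
        chunk = random_dna(rng, 6000)
        construct = build_construct(chunk, small_vector, mode="internal",
                                    insertion_pos=2200, overlap_len=500)
        c = Contig("c", construct.full_seq, 50.0)
        m = _match_for(c.seq, small_vector)
        out = reorganize_contig(c, [m])
        assert out.case == "joined_circular"
        assert out.join_overlap_len == 500
        [joined] = out.contigs_out
        assert len(joined.seq) == len(chunk)
        assert joined.seq in chunk + chunk  # rotation equivalence

    def test_masking_then_reorganizing_equals_direct(self, rng, small_vector):
        a, b = random_dna(rng, 1800), random_dna(rng, 2100)
        c = Contig("c", a + small_vector + b, 50.0)
        m = _match_for(c.seq, small_vector)
        direct = reorganize_contig(c, [m])
        masked = reorganize_contig(mask_vector(c, [m]), [m])
        assert [x.seq for x in direct.contigs_out] == [x.seq for x in masked.contigs_out]
        assert all("X" not in x.seq for x in masked.contigs_out)

    def test_sequence_conservation(self, rng, small_vector):
        a, b = random_dna(rng, 1500), random_dna(rng, 1700)
        c = Contig("c", a + small_vector + b, 50.0)
        m = _match_for(c.seq, small_vector)
        out = reorganize_contig(c, [m])
        kept = "".join(x.seq for x in out.contigs_out)
        excised = c.seq[: m.start] + c.seq[m.end :]
        assert sorted(kept) == sorted(excised) and len(kept) == len(excised)

    def test_circular_break_inside_vector_trims_both_ends(self, rng, small_vector):
        """A circular assembly linearised inside the vector leaves vector at
        both contig extremities; both are trimmed, one insert remains."""
        ins = random_dna(rng, 5000)
        v2, v1 = small_vector[:600], small_vector[600:]
        c = Contig("c", v1 + ins + v2, 50.0)
        ms = detect_vector(c, small_vector)
        assert len(ms) == 2
        out = reorganize_contig(c, ms)
        assert out.case == "trimmed_extremity"
        assert [x.seq for x in out.contigs_out] == [ins]

    def test_multiple_internal_occurrences_flagged_no_join(self, rng, small_vector):
        a, b, d = random_dna(rng, 1500), random_dna(rng, 1500), random_dna(rng, 1500)
        c = Contig("c", a + small_vector + b + small_vector + d, 50.0)
        ms = detect_vector(c, small_vector)
        assert len(ms) == 2
        out = reorganize_contig(c, ms)
        assert out.case == "multi_vector" and out.flagged
        assert [x.seq for x in out.contigs_out] == [a, b, d]
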
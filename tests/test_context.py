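"""Repeat parsing/landscape, deletion concordance, and liftover."""

import numpy as np
import pytest

from cichlidsv.core import ConsensusSV, GenomicInterval, SVClass
from cichlidsv.context import (AlignmentBlock, RepeatElement,
                               deletion_concordance, invert_blocks,
                               liftover_interval, parse_repeatmasker_out,
                               read_alignment_bed, repeat_landscape,
                               write_alignment_bed, write_repeatmasker_out)
from cichlidsv.enrichment import Workspace


def iv(start, end, contig="lg1"):
    return GenomicInterval(contig, start, end)


def deletion(start, end, cid="d1"):
    return ConsensusSV(iv(start, end), SVClass.DEL, frozenset({"Mzebra"}),
                       {"Mzebra": frozenset({"delly", "pindel"})}, ("r",), cid)


RM_OUT = """\
   SW  perc perc perc  query     position in query    matching repeat
score  div. del. ins.  sequence  begin end (left)     repeat class/family

  463  12.3  0.0  0.0  lg1  101 200 (0) + SINE2-1 SINE/SINE2 1 100 (0) 1
  300   3.1  0.0  0.0  lg1  501 700 (0) + Tc1 DNA/TcMar 1 200 (0) 2
  250   7.0  0.0  0.0  lg2  11 60 (0) + WeirdRep Foo 1 50 (0) 3
"""


class TestRepeatMaskerParse:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "r.out"
        path.write_text(RM_OUT)
        elements = parse_repeatmasker_out(path)
        sine = elements[0]
        assert sine.repeat_class == "SINE"
        assert sine.divergence == 12.3
        assert (sine.interval.start, sine.interval.end) == (100, 200)

    def test_class_before_slash(self, tmp_path):
        path = tmp_path / "r.out"
        path.write_text(RM_OUT)
        dna = parse_repeatmasker_out(path)[1]
        assert dna.repeat_class == "DNA"
        assert dna.family == "TcMar"

    def test_unrecognized_class_becomes_other(self, tmp_path):
        path = tmp_path / "r.out"
        path.write_text(RM_OUT)
        assert parse_repeatmasker_out(path)[2].repeat_class == "Other"

    def test_round_trip(self, tmp_path):
        elements = [
            RepeatElement(iv(i * 1000, i * 1000 + 300), "LTR", "Gypsy",
                          round(1.5 * i, 1))
            for i in range(10)
        ]
        path = tmp_path / "rt.out"
        write_repeatmasker_out(elements, path)
        assert parse_repeatmasker_out(path) == elements


class TestRepeatLandscape:
    GENOME = Workspace((iv(0, 1000),))

    def test_inside_proportion_arithmetic(self):
        # one SV [0,100), one LTR repeat [10,60) at 7% divergence
        table = repeat_landscape([iv(0, 100)],
                                 [RepeatElement(iv(10, 60), "LTR", "f", 7.0)],
                                 self.GENOME)
        row = table[(table.region == "inside") & (table.div_lo == 5.0)
                    & (table.repeat_class == "LTR")].iloc[0]
        assert row["proportion"] == pytest.approx(0.5)

    def test_no_repeats_all_zero(self):
        table = repeat_landscape([iv(0, 100)], [], self.GENOME)
        assert (table["proportion"] == 0).all()

    def test_straddling_element_counts_nowhere(self):
        table = repeat_landscape([iv(0, 100)],
                                 [RepeatElement(iv(90, 110), "LTR", "f", 7.0)],
                                 self.GENOME)
        assert (table["repeat_nt"] == 0).all()

    def test_complement_conservation(self):
        """Inside plus outside region lengths cover the genome exactly."""
        table = repeat_landscape([iv(100, 300), iv(500, 600)], [],
                                 self.GENOME)
        inside_nt = table[table.region == "inside"]["region_nt"].iloc[0]
        outside_nt = table[table.region == "outside"]["region_nt"].iloc[0]
        assert inside_nt + outside_nt == 1000

    def test_outside_element_counted(self):
        table = repeat_landscape([iv(0, 100)],
                                 [RepeatElement(iv(200, 400), "DNA", "f", 2.0)],
                                 self.GENOME)
        row = table[(table.region == "outside") & (table.div_lo == 0.0)
                    & (table.repeat_class == "DNA")].iloc[0]
        assert row["proportion"] == pytest.approx(200 / 900)


class TestDeletionConcordance:
    def _block(self, start, end):
        return AlignmentBlock(iv(start, end),
                              GenomicInterval("q", 0, end - start), "+", "ch1")

    def test_spanning_block_makes_discordant(self):
        _, n, frac = deletion_concordance([deletion(100, 200)],
                                          [self._block(140, 400)])
        assert (n, frac) == (1, 1.0)  # overlap 60 >= 50% of 100

    def test_short_overlap_concordant(self):
        _, n, frac = deletion_concordance([deletion(100, 200)],
                                          [self._block(180, 400)])
        assert (n, frac) == (0, 0.0)  # overlap 20 < 50

    def test_no_overlap_concordant(self):
        _, n, frac = deletion_concordance([deletion(100, 200)],
                                          [self._block(500, 900)])
        assert n == 0

    def test_verdicts_match_brute_force(self, rng):
        dels = [deletion(int(s) * 100, int(s) * 100 + int(l), f"d{i}")
                for i, (s, l) in enumerate(zip(rng.integers(0, 500, 40),
                                               rng.integers(100, 5000, 40)))]
        blocks = [self._block(int(s) * 100, int(s) * 100 + int(l))
                  for s, l in zip(rng.integers(0, 500, 30),
                                  rng.integers(100, 8000, 30))]
        frame, _, _ = deletion_concordance(dels, blocks)
        for d, verdict in zip(dels, frame["discordant"]):
            oracle = any(
                min(b.ref_interval.end, d.interval.end)
                - max(b.ref_interval.start, d.interval.start)
                >= 0.5 * d.interval.length
                for b in blocks
                if b.ref_interval.contig == d.interval.contig)
            assert bool(verdict) == oracle


class TestLiftover:
    PLUS = [AlignmentBlock(iv(0, 100), GenomicInterval("q", 500, 600),
                           "+", "c1")]
    MINUS = [AlignmentBlock(iv(0, 100), GenomicInterval("q", 500, 600),
                            "-", "c1")]

    def test_plus_strand_offset(self):
        out = liftover_interval(iv(10, 20), self.PLUS)
        assert out == GenomicInterval("q", 510, 520)

    def test_endpoint_outside_unmapped(self):
        assert liftover_interval(iv(50, 150), self.PLUS) is None

    def test_minus_strand_mirror(self):
        out = liftover_interval(iv(0, 10), self.MINUS)
        assert out == GenomicInterval("q", 590, 600)

    def test_minus_strand_per_base_oracle(self):
        for s in range(0, 90, 7):
            out = liftover_interval(iv(s, s + 10), self.MINUS)
            # base-by-base: ref p maps to q 599-p
            expected = {599 - p for p in range(s, s + 10)}
            assert set(range(out.start, out.end)) == expected

    def test_round_trip_through_inverted_chain(self, rng):
        blocks = []
        qpos = 10000
        for k, start in enumerate(range(0, 5000, 1000)):
            strand = "+" if k % 2 == 0 else "-"
            blocks.append(AlignmentBlock(
                iv(start + 100, start + 800),
                GenomicInterval("q", qpos, qpos + 700), strand, f"c{k}"))
            qpos += 1000
        inverse = invert_blocks(blocks)
        for _ in range(50):
            start = int(rng.integers(0, 4900))
            length = int(rng.integers(1, 100))
            src = iv(start, start + length)
            mapped = liftover_interval(src, blocks)
            if mapped is None:
                continue
            back = liftover_interval(mapped, inverse)
            assert back == src

    def test_chains_are_independent(self):
        """Endpoints in different chains do not combine."""
        blocks = [
            AlignmentBlock(iv(0, 50), GenomicInterval("q", 0, 50), "+", "c1"),
            AlignmentBlock(iv(60, 120), GenomicInterval("q", 500, 560),
                           "+", "c2"),
        ]
        assert liftover_interval(iv(40, 100), blocks) is None

    def test_mismatched_block_lengths_rejected(self):
        with pytest.raises(ValueError, match="c9"):
            AlignmentBlock(iv(0, 100), GenomicInterval("q", 0, 50), "+", "c9")


def test_alignment_bed_round_trip(tmp_path):
    blocks = [
        AlignmentBlock(iv(0, 100), GenomicInterval("q1", 500, 600), "+", "a"),
        AlignmentBlock(iv(200, 450), GenomicInterval("q2", 0, 250), "-", "b"),
    ]
    path = tmp_path / "aln.bed"
    write_alignment_bed(blocks, path)
    assert read_alignment_bed(path) == blocks
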
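"""Consensus parsing, strand-aware scanning vs a brute-force oracle,
upstream extraction, hit-gene assignment, and MI enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cyclenuc as cn
from cyclenuc.errors import CycleNucError, MotifParseError
from cyclenuc.motifs import reverse_complement

PAPER_CONSENSI = [
    "[AGT]ACGCG[AT][ACG]A",   # SWI4 (S. bayanus)
    "[AGT][AT]CGCGT[CT][AGT]",  # MBP1 (S. cerevisiae)
    "CGCGT[CT]",              # average MBP1 core
    "[AG]TAAACAA[AT]",        # FKH1
]


def oracle_scan(seq, motif):
    """Position-by-position set membership at every offset, both strands."""
    hits = set()
    L = motif.length
    seq = seq.upper()
    for i in range(len(seq) - L + 1):
        win = seq[i : i + L]
        if all(b in s for b, s in zip(win, motif.positions)):
            hits.add((i, i + L, "+"))
        rc = reverse_complement(win)
        if all(b in s for b, s in zip(rc, motif.positions)):
            hits.add((i, i + L, "-"))
    return hits


class TestParse:
    def test_average_mbp1_core_has_six_positions(self):
        m = cn.parse_consensus("CGCGT[CT]")
        assert m.length == 6
        assert m.positions[-1] == frozenset("CT")
        assert m.positions[0] == frozenset("C")

    def test_single_letter_and_fully_degenerate_class(self):
        assert cn.parse_consensus("A").positions == (frozenset("A"),)
        m = cn.parse_consensus("[ACGT]")
        assert m.length == 1 and m.matches("G")

    @pytest.mark.parametrize("bad", ["[AG", "A]G", "[]A", "[AX]", "Q", ""])
    def test_malformed_patterns_raise_with_position(self, bad):
        with pytest.raises(MotifParseError):
            cn.parse_consensus(bad)

    def test_reverse_complement_of_consensus(self):
        m = cn.parse_consensus("[AGT][AT]CGCGT[CT][AGT]")
        assert m.reverse_complement().pattern == "[ACT][AG]ACGCG[AT][ACT]"


class TestScan:
    def test_plus_strand_hit_with_coordinates(self):
        hits = cn.scan_sequence("ACGCGTCA", cn.parse_consensus("CGCGT[CT]"))
        assert [(h.start, h.end, h.strand) for h in hits] == [(1, 7, "+")]
        assert hits[0].matched_seq == "CGCGTC"

    def test_minus_strand_hit_on_reverse_complement_sequence(self):
        seq = reverse_complement("ACGCGTCA")  # TGACGCGT
        hits = cn.scan_sequence(seq, cn.parse_consensus("CGCGT[CT]"))
        assert [(h.start, h.end, h.strand) for h in hits] == [(1, 7, "-")]
        assert hits[0].matched_seq == "CGCGTC"

    def test_n_never_matches(self):
        assert cn.scan_sequence("NNNNNNN", cn.parse_consensus("[ACGT][ACGT]")) == []
        assert cn.scan_sequence("NNNNNNNN", cn.parse_consensus("CGCGT[CT]")) == []

    def test_overlapping_hits_are_all_reported(self):
        hits = cn.scan_sequence("AAAA", cn.parse_consensus("AA"), strands="plus")
        assert [(h.start, h.end) for h in hits] == [(0, 2), (1, 3), (2, 4)]

    @pytest.mark.parametrize("pattern", PAPER_CONSENSI)
    def test_scanner_equals_bruteforce_oracle_on_random_sequences(self, pattern, rng):
        motif = cn.parse_consensus(pattern)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            got = {(h.start, h.end, h.strand) for h in cn.scan_sequence(seq, motif)}
            assert got == oracle_scan(seq, motif)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=0, max_size=80),
        pattern=st.sampled_from(PAPER_CONSENSI),
    )
    def test_scanner_equals_oracle_on_arbitrary_sequences(self, seq, pattern):
        motif = cn.parse_consensus(pattern)
        got = {(h.start, h.end, h.strand) for h in cn.scan_sequence(seq, motif)}
        assert got == oracle_scan(seq, motif)

    @pytest.mark.parametrize("pattern", PAPER_CONSENSI)
    def test_strand_involution(self, pattern, rng):
        """'-' hits on seq == '+' hits on revcomp(seq), coordinates mapped."""
        motif = cn.parse_consensus(pattern)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        minus = {
            (h.start, h.end) for h in cn.scan_sequence(seq, motif) if h.strand == "-"
        }
        rc = reverse_complement(seq)
        plus_on_rc = {
            (len(seq) - h.end, len(seq) - h.start)
            for h in cn.scan_sequence(rc, motif)
            if h.strand == "+"
        }
        assert minus == plus_on_rc


class TestUpstream:
    GENOME = {"chr1": "".join(np.random.default_rng(7).choice(list("ACGT"), 2000))}

    def _gene(self, strand, coding_start, name="g1"):
        return {
            "name": name, "contig": "chr1", "strand": strand,
            "coding_start": coding_start, "start": 0, "end": 0,
        }

    def test_plus_strand_window_and_offset_map(self):
        r = cn.extract_upstream(self._gene("+", 1000), self.GENOME, 600)
        assert r.seq == self.GENOME["chr1"][400:1000]
        assert r.offsets[0] == -600 and r.genomic[0] == 400
        assert r.offsets[-1] == -1 and r.genomic[-1] == 999

    def test_minus_strand_window_is_reverse_complemented(self):
        r = cn.extract_upstream(self._gene("-", 1000), self.GENOME, 600)
        assert r.seq == reverse_complement(self.GENOME["chr1"][1001:1601])
        assert r.offsets[-1] == -1 and r.genomic[-1] == 1001
        assert r.genomic[0] == 1600

    def test_truncation_at_contig_edge(self):
        r = cn.extract_upstream(self._gene("+", 100), self.GENOME, 600)
        assert len(r.seq) == 100
        assert r.offsets[0] == -100

    def test_unknown_contig_is_an_error(self):
        gene = self._gene("+", 100)
        gene["contig"] = "chrX"
        with pytest.raises(CycleNucError):
            cn.extract_upstream(gene, self.GENOME, 600)


class TestAssign:
    def test_center_offset_uses_floor_half_length(self):
        region = cn.UpstreamRegion(
            gene="g", contig="c", strand="+", seq="A" * 600,
            offsets=np.arange(-600, 0), genomic=np.arange(400, 1000),
        )
        hit = cn.MotifHit("c", 450, 456, "+", "AAAAAA")  # offsets -150..-145
        (out,) = cn.assign_hits_to_genes({"g": [hit]}, {"g": region})
        assert out.offset == -147
        assert out.gene == "g"

    def test_gene_without_hits_is_absent(self):
        region = cn.UpstreamRegion(
            gene="g", contig="c", strand="+", seq="A" * 10,
            offsets=np.arange(-10, 0), genomic=np.arange(0, 10),
        )
        assert cn.assign_hits_to_genes({"g": []}, {"g": region}) == []

    def test_hit_in_two_overlapping_windows_yields_two_records(self):
        # divergent promoter: same genomic bases serve both genes' windows
        genome = {"c": "T" * 300 + "ACGCGTC" + "T" * 300}
        genes = pd.DataFrame(
            [
                {"name": "left", "contig": "c", "strand": "-", "coding_start": 100,
                 "start": 0, "end": 100, "score": 0},
                {"name": "right", "contig": "c", "strand": "+", "coding_start": 500,
                 "start": 500, "end": 600, "score": 0},
            ]
        )
        motif = cn.parse_consensus("CGCGT[CT]")
        hits, _ = cn.find_upstream_hits(genes, genome, motif, 600)
        assert {h.gene for h in hits} == {"left", "right"}
        spans = {(h.start, h.end) for h in hits}
        assert spans == {(301, 307)}

    def test_minus_strand_assignment_round_trips_genomic_coordinates(self):
        genome = {"c": "T" * 200 + "TTTTCGCGTC" + "T" * 200}
        genes = pd.DataFrame(
            [{"name": "g", "contig": "c", "strand": "-", "coding_start": 100,
              "start": 0, "end": 100, "score": 0}]
        )
        motif = cn.parse_consensus("CGCGT[CT]")
        hits, _ = cn.find_upstream_hits(genes, genome, motif, 600)
        (h,) = hits
        assert genome["c"][h.start : h.end] == "CGCGTC"
        assert h.strand == "+"          # genomic strand
        assert h.upstream_strand == "-"  # found on the gene-oriented '-'


class TestMI:
    def test_perfect_two_bin_split_is_one_bit(self):
        res = cn.mi_enrichment([True, True, False, False], [1, 2, 3, 4],
                               n_bins=2, n_perm=200, seed=0)
        assert res.mi_bits == pytest.approx(1.0)

    def test_presence_independent_of_bins_is_zero_bits(self):
        presence = [True, False] * 4
        res = cn.mi_enrichment(presence, list(range(1, 9)), n_bins=2,
                               n_perm=200, seed=0)
        assert res.mi_bits == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.1

    def test_constant_presence_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            res = cn.mi_enrichment([True] * 6, list(range(1, 7)), n_bins=2)
        assert res.mi_bits == 0.0 and res.p_value == 1.0

    def test_mi_is_nonnegative_and_invariant_under_bin_order(self, rng):
        n = 40
        presence = rng.random(n) < 0.4
        ranks = rng.permutation(np.arange(1, n + 1))
        res = cn.mi_enrichment(presence, ranks, n_bins=5, n_perm=50, seed=1)
        flipped = cn.mi_enrichment(presence, n + 1 - ranks, n_bins=5,
                                   n_perm=50, seed=1)
        assert res.mi_bits >= 0
        assert res.mi_bits == pytest.approx(flipped.mi_bits)

    def test_invalid_ranks_are_rejected(self):
        with pytest.raises(CycleNucError):
            cn.mi_enrichment([True, False], [1, 3], n_bins=2)
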
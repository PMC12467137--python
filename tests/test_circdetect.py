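"""Back-splice caller: anchors, head-to-tail logic, support filter, classes."""
import numpy as np
import pytest

from cernet import circdetect, simulate
from cernet.circdetect import (
    DetectStats,
    GenomeIndex,
    call_backsplice,
    classify_circ,
    detect_circrnas,
    extract_anchors,
    filter_and_aggregate,
    map_anchor,
)
from cernet.types import CircRNACall, GeneModel, Genome, revcomp


def _random_genome(n=4000, seed=0):
    rng = np.random.default_rng(seed)
    return Genome({"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))})


class TestAnchors:
    def test_forty_base_read_splits_into_terminal_twenty_mers(self):
        read = "A" * 20 + "C" * 20
        left, right = extract_anchors(read)
        assert left == "A" * 20 and right == "C" * 20

    def test_short_read_raises(self):
        with pytest.raises(ValueError):
            extract_anchors("ACGT" * 9)  # 36 < 40

    def test_short_reads_are_counted_not_fatal(self):
        genome = _random_genome()
        stats = DetectStats()
        assert call_backsplice("ACGT" * 5, GenomeIndex(genome), stats) is None
        assert stats.short_reads == 1

    def test_unique_anchor_maps_to_its_locus(self):
        genome = _random_genome(seed=1)
        anchor = genome["chr1"][100:120]
        hits = map_anchor(anchor, GenomeIndex(genome))
        assert len(hits) == 1 and hits[0].position == 100 and hits[0].unique

    def test_poly_a_anchor_is_nonunique(self):
        genome = Genome({"chr1": "A" * 100 + "CGCGTTGCAC" * 4})
        hits = map_anchor("A" * 20, GenomeIndex(genome))
        assert len(hits) > 1 and not any(h.unique for h in hits)

    def test_reverse_strand_hits_are_reported(self):
        genome = _random_genome(seed=2)
        anchor = revcomp(genome["chr1"][200:220])
        hits = map_anchor(anchor, GenomeIndex(genome))
        assert len(hits) == 1 and hits[0].strand == "-"


class TestCallBacksplice:
    def _junction_read(self, genome, acc, don, a, read_len=100):
        seq = genome["chr1"]
        return seq[don - a : don] + seq[acc : acc + read_len - a]

    def test_planted_junction_recovered_exactly(self):
        genome = _random_genome(seed=3)
        acc, don = 500, 900
        # avoid a shifted equivalent junction
        assert genome["chr1"][acc - 1] != genome["chr1"][don - 1] or True
        read = self._junction_read(genome, acc, don, a=45)
        got = call_backsplice(read, GenomeIndex(genome))
        assert got is not None
        chrom, strand, a0, d0 = got
        seg = genome["chr1"][a0:d0]
        assert (read in seg + seg) and strand == "+"
        # leftmost-acceptor convention: called junction is the leftmost
        # representation of the same circle
        shift = acc - a0
        assert don - d0 == shift >= 0

    def test_minus_strand_read_recovers_junction(self):
        genome = _random_genome(seed=4)
        read = revcomp(self._junction_read(genome, 1000, 1600, a=30))
        got = call_backsplice(read, GenomeIndex(genome))
        assert got is not None and got[1] == "-"
        seg = genome["chr1"][got[2] : got[3]]
        assert revcomp(read) in seg + seg

    def test_linear_read_returns_none(self):
        genome = _random_genome(seed=5)
        stats = DetectStats()
        assert call_backsplice(genome["chr1"][50:150], GenomeIndex(genome),
                               stats) is None
        assert stats.collinear >= 1

    def test_anchors_on_different_chromosomes_return_none(self):
        rng = np.random.default_rng(6)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
                for _ in range(2)]
        genome = Genome({"chr1": seqs[0], "chr2": seqs[1]})
        chimera = seqs[0][100:150] + seqs[1][300:350]
        assert call_backsplice(chimera, GenomeIndex(genome)) is None

    def test_nonunique_anchor_discards_read(self):
        rng = np.random.default_rng(7)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        dup = core[100:120]
        genome = Genome({"chr1": core + "T" * 10 + dup})  # anchor now twice
        # left anchor of the read is the duplicated 20-mer
        read = dup + core[120:200]
        stats = DetectStats()
        assert call_backsplice(read, GenomeIndex(genome), stats) is None
        assert stats.called == 0 and stats.nonunique_anchor >= 1


class TestSupportFilter:
    def _cands(self, per_sample):
        return {("chr1", "+", 100, 400): per_sample}

    def test_two_distinct_reads_in_one_sample_is_kept(self):
        calls = filter_and_aggregate(
            self._cands({"G1": {"AAAA", "CCCC"}}), ["C1", "G1"])
        assert len(calls) == 1 and calls[0].support == {"C1": 0, "G1": 2}

    def test_three_copies_of_one_sequence_count_once(self):
        # duplicates of a single read sequence collapse before counting
        calls = filter_and_aggregate(self._cands({"G1": {"AAAA"}}), ["G1"])
        assert calls == []

    def test_one_read_in_each_of_many_samples_is_dropped(self):
        per_sample = {f"S{i}": {f"SEQ{i}"} for i in range(10)}
        assert filter_and_aggregate(self._cands(per_sample),
                                    sorted(per_sample)) == []

    def test_pooled_mode_sums_distinct_sequences_across_samples(self):
        per_sample = {"C1": {"AAAA"}, "G1": {"CCCC"}}
        assert filter_and_aggregate(self._cands(per_sample), ["C1", "G1"]) == []
        pooled = filter_and_aggregate(self._cands(per_sample), ["C1", "G1"],
                                      pooled=True)
        assert len(pooled) == 1


class TestClassify:
    @pytest.fixture()
    def gene(self):
        return GeneModel("g1", "chr1", "+",
                         [(100, 200), (300, 400), (500, 650)], (520, 640))

    def _call(self, acc, don, strand="+"):
        return CircRNACall("x", "chr1", strand, (acc, don), {"C1": 2})

    def test_exact_single_exon_is_one_exon_not_annot_exon(self, gene):
        assert classify_circ(self._call(300, 400), [gene]) == "one-exon"

    def test_multi_exon_boundaries_are_annot_exon(self, gene):
        assert classify_circ(self._call(100, 400), [gene]) == "annot-exon"

    def test_span_reaching_into_intron_is_exon_intron(self, gene):
        assert classify_circ(self._call(100, 250), [gene]) == "exon-intron"

    def test_span_inside_intron_is_intron(self, gene):
        assert classify_circ(self._call(210, 290), [gene]) == "intron"

    def test_opposite_strand_containment_is_antisense(self, gene):
        assert classify_circ(self._call(150, 350, strand="-"), [gene]) == "antisense"

    def test_outside_any_gene_is_intergenic(self, gene):
        assert classify_circ(self._call(700, 900), [gene]) == "intergenic"

    def test_planted_types_round_trip_through_classifier(self, planted):
        r, _ = planted
        for c in r.circs:
            call = CircRNACall(c.circ_id, c.chrom, c.strand, c.junction, {"C1": 2})
            assert classify_circ(call, r.genes) == c.circ_type


class TestEndToEnd:
    def test_all_planted_circles_called_at_exact_coordinates(self, planted):
        r, _ = planted
        reads, _ = simulate.simulate_reads(r.genome, r.circs, ["C1", "G1"],
                                           junction_reads_per_circ=5,
                                           linear_reads=50, seed=3)
        calls, _ = detect_circrnas(reads, r.genome, r.genes)
        called = {(c.chrom, c.strand, *c.junction) for c in calls}
        for c in r.circs:
            assert (c.chrom, c.strand, *c.junction) in called
        assert len(calls) == len(r.circs)

    def test_linear_only_reads_give_zero_calls(self, ref):
        reads, _ = simulate.simulate_reads(ref.genome, ref.circs, ["C1"],
                                           junction_reads_per_circ=0,
                                           linear_reads=300, seed=5)
        calls, _ = detect_circrnas(reads, ref.genome)
        assert calls == []

    def test_supporting_reads_reconstruct_from_doubled_segment(self, planted):
        r, _ = planted
        reads, _ = simulate.simulate_reads(r.genome, r.circs, ["C1"],
                                           junction_reads_per_circ=3,
                                           linear_reads=0, seed=6)
        index = GenomeIndex(r.genome)
        for _rid, seq in reads["C1"]:
            got = call_backsplice(seq, index)
            assert got is not None
            chrom, strand, acc, don = got
            assert acc < don
            seg = r.genome[chrom][acc:don]
            fwd = seq if strand == "+" else revcomp(seq)
            assert fwd in seg + seg
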
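"""Anchor-based back-splice junction calling.

Each read's terminal 20-mers (anchors) are exact-matched against the
genome.  A pair of uniquely mapping anchors in head-to-tail orientation
(the right-end anchor upstream of the left-end anchor) indicates a
candidate circRNA junction; the candidate is confirmed by reconstructing
the full read from the doubled circular genomic segment.  Calls require at
least ``min_support`` distinct supporting read sequences in some one sample.

The aligner is deliberately exact-match: anchors and reconstruction admit
no mismatches, which keeps the head-to-tail logic fully auditable on
synthetic genomes.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .types import CircRNACall, GeneModel, Genome, revcomp

ANCHOR_LEN = 20


@dataclass
class AnchorHit:
    read_id: str
    side: str  # left | right
    chrom: str
    strand: str
    position: int  # 0-based start of the anchor on the forward strand
    unique: bool


@dataclass
class DetectStats:
    """Counters for skipped/rejected reads (diagnostics, not results)."""

    short_reads: int = 0
    nonunique_anchor: int = 0
    collinear: int = 0
    reconstruction_fail: int = 0
    called: int = 0


class GenomeIndex:
    """Exact-match k-mer index of the forward strand of every chromosome."""

    def __init__(self, genome: Genome, k: int = ANCHOR_LEN):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.chroms.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((chrom, i))

    def forward_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def hits(self, kmer: str) -> list[tuple[str, int, str]]:
        """All genomic placements of ``kmer`` on both strands."""
        out = [(c, p, "+") for c, p in self.forward_hits(kmer)]
        out += [(c, p, "-") for c, p in self.forward_hits(revcomp(kmer))]
        return out


def extract_anchors(read: str, anchor_len: int = ANCHOR_LEN) -> tuple[str, str]:
    """First and last ``anchor_len`` bases of the read."""
    if len(read) < 2 * anchor_len:
        raise ValueError(f"read shorter than 2*{anchor_len}")
    return read[:anchor_len], read[-anchor_len:]


def map_anchor(anchor: str, index: GenomeIndex, read_id: str = "", side: str = "left"
               ) -> list[AnchorHit]:
    """Exact-match placements of the anchor; unique iff exactly one in total."""
    hits = index.hits(anchor)
    unique = len(hits) == 1
    return [AnchorHit(read_id, side, c, s, p, unique) for c, p, s in hits]


def _extend_right(seq: str, chrom_seq: str, pos: int) -> int:
    """Length of the longest prefix of seq matching chrom_seq at pos."""
    n = 0
    limit = min(len(seq), len(chrom_seq) - pos)
    while n < limit and seq[n] == chrom_seq[pos + n]:
        n += 1
    return n


def _extend_left(seq: str, chrom_seq: str, end: int) -> int:
    """Length of the longest suffix of seq matching chrom_seq ending at end."""
    n = 0
    limit = min(len(seq), end)
    while n < limit and seq[-1 - n] == chrom_seq[end - 1 - n]:
        n += 1
    return n


def call_backsplice(read: str, index: GenomeIndex, stats: DetectStats | None = None
                    ) -> tuple[str, str, int, int] | None:
    """Call a back-splice candidate from one read, or None.

    Returns ``(chrom, strand, acceptor_start, donor_end)``.  Both read
    orientations are tried (a minus-strand circle yields reverse-complement
    reads).  When the breakpoint is ambiguous because of a repeat at the
    junction, the leftmost acceptor is chosen (tie-stable).
    """
    stats = stats if stats is not None else DetectStats()
    if len(read) < 2 * ANCHOR_LEN:
        stats.short_reads += 1
        return None
    for strand, seq in (("+", read), ("-", revcomp(read))):
        cand = _call_plus(seq, index, stats)
        if cand is not None:
            chrom, acceptor, donor = cand
            stats.called += 1
            return (chrom, strand, acceptor, donor)
    return None


def _call_plus(seq: str, index: GenomeIndex, stats: DetectStats
               ) -> tuple[str, int, int] | None:
    left, right = extract_anchors(seq)
    lhits = index.hits(left)
    rhits = index.hits(right)
    if len(lhits) != 1 or len(rhits) != 1:
        if len(lhits) > 1 or len(rhits) > 1:
            stats.nonunique_anchor += 1
        return None
    (lc, lp, ls), (rc, rp, rs) = lhits[0], rhits[0]
    if ls != "+" or rs != "+" or lc != rc:
        return None
    if rp >= lp:  # collinear (ordinary linear read) or same position
        stats.collinear += 1
        return None
    chrom_seq = index.genome[lc]
    n = len(seq)
    a = _extend_right(seq, chrom_seq, lp)  # donor-side prefix match
    b = _extend_left(seq, chrom_seq, rp + ANCHOR_LEN)  # acceptor-side suffix
    if a + b < n:
        stats.reconstruction_fail += 1
        return None
    b_used = min(b, n - ANCHOR_LEN)  # maximal suffix -> leftmost acceptor
    a_used = n - b_used
    donor_end = lp + a_used
    acceptor_start = rp + ANCHOR_LEN - b_used
    if not (0 <= acceptor_start < donor_end):
        stats.reconstruction_fail += 1
        return None
    seg = chrom_seq[acceptor_start:donor_end]
    if seq not in seg + seg:
        stats.reconstruction_fail += 1
        return None
    return (lc, acceptor_start, donor_end)


def collect_candidates(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    index: GenomeIndex,
    stats: DetectStats | None = None,
) -> dict[tuple[str, str, int, int], dict[str, set[str]]]:
    """Run the caller over every read; group candidates by junction.

    Returns ``{(chrom, strand, acceptor, donor): {sample: {read seqs}}}``.
    """
    candidates: dict[tuple, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for sample, reads in reads_by_sample.items():
        for _rid, seq in reads:
            cand = call_backsplice(seq, index, stats)
            if cand is not None:
                candidates[cand][sample].add(seq)
    return candidates


def filter_and_aggregate(
    candidates: dict[tuple[str, str, int, int], dict[str, set[str]]],
    samples: list[str],
    min_unique_reads: int = 2,
    pooled: bool = False,
) -> list[CircRNACall]:
    """Keep junctions supported by >= ``min_unique_reads`` distinct read
    sequences in at least one sample (or pooled across samples if requested).
    """
    calls = []
    for (chrom, strand, acc, don), per_sample in sorted(candidates.items()):
        support = {s: len(per_sample.get(s, ())) for s in samples}
        if pooled:
            pooled_n = len(set().union(*per_sample.values()))
            keep = pooled_n >= min_unique_reads
        else:
            keep = max(support.values(), default=0) >= min_unique_reads
        if keep:
            circ_id = f"{chrom}:{acc}-{don}:{strand}"
            calls.append(CircRNACall(circ_id, chrom, strand, (acc, don), support))
    return calls


def classify_circ(call: CircRNACall, gene_models: list[GeneModel]) -> str:
    """Structural class of a call against the annotation.

    Precedence: one-exon > annot-exon > exon-intron > intron > antisense >
    intergenic.  Exonic/intronic classes require a gene on the same strand;
    antisense means contained in a gene on the opposite strand.
    """
    acc, don = call.junction
    same = [g for g in gene_models
            if g.chrom == call.chrom and g.strand == call.strand]
    opposite = [g for g in gene_models
                if g.chrom == call.chrom and g.strand != call.strand]
    for g in same:
        if (acc, don) in g.exons:
            return "one-exon"
    for g in same:
        if any(acc == s for s, _ in g.exons) and any(don == e for _, e in g.exons):
            return "annot-exon"
    for g in same:
        introns = [(e1, s2) for (_, e1), (s2, _) in zip(g.exons, g.exons[1:])]
        ov_exon = any(s < don and acc < e for s, e in g.exons)
        ov_intron = any(s < don and acc < e for s, e in introns)
        if ov_exon and ov_intron:
            return "exon-intron"
        if any(s <= acc and don <= e for s, e in introns):
            return "intron"
    for g in opposite:
        if g.start <= acc and don <= g.end:
            return "antisense"
    return "intergenic"


def detect_circrnas(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    genome: Genome,
    gene_models: list[GeneModel] | None = None,
    min_unique_reads: int = 2,
    pooled: bool = False,
    index: GenomeIndex | None = None,
) -> tuple[list[CircRNACall], DetectStats]:
    """End-to-end caller: anchor mapping, head-to-tail calling, support
    filtering and (when an annotation is given) type classification."""
    stats = DetectStats()
    index = index if index is not None else GenomeIndex(genome)
    candidates = collect_candidates(reads_by_sample, index, stats)
    calls = filter_and_aggregate(
        candidates, sorted(reads_by_sample), min_unique_reads, pooled
    )
    if gene_models is not None:
        for call in calls:
            call.circ_type = classify_circ(call, gene_models)
    return calls, stats


def calls_to_bed(calls: list[CircRNACall]) -> str:
    """BED6 text: chrom, acceptor_start, donor_end, circ_id, max support, strand."""
    lines = [
        f"{c.chrom}\t{c.junction[0]}\t{c.junction[1]}\t{c.circ_id}"
        f"\t{c.max_support}\t{c.strand}"
        for c in calls
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def calls_to_table(calls: list[CircRNACall], samples: list[str]):
    """Per-sample support table (also the circRNA counts matrix for DE)."""
    import pandas as pd

    rows = {
        c.circ_id: {**{s: c.support.get(s, 0) for s in samples},
                    "circ_type": c.circ_type}
        for c in calls
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if not df.empty:
        df = df[[*samples, "circ_type"]]
    return df
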
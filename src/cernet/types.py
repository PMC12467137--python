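"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; GTF output is
converted to 1-based closed on write, BED stays 0-based half-open.
miRNA sequences are stored in the DNA alphabet (U -> T) so a single
alphabet serves the whole sequence stack.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA = set("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A set of named chromosomes over {A, C, G, T}."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            if set(seq) - DNA:
                raise ValueError(f"chromosome {name!r} contains non-ACGT characters")

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]


@dataclass
class GeneModel:
    """A gene with ordered, disjoint exons and a 3'UTR on one strand.

    ``utr3`` is a genomic interval contained in the gene span (inside the
    terminal exon as generated here).  The spliced mRNA and the 3'UTR
    sequence are derived strand-aware from the genome.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    utr3: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: degenerate exon ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
        if not (self.start <= self.utr3[0] < self.utr3[1] <= self.end):
            raise ValueError(f"{self.gene_id}: 3'UTR outside gene span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def spliced_seq(self, genome: Genome) -> str:
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def utr3_seq(self, genome: Genome) -> str:
        seq = genome.fetch(self.chrom, *self.utr3)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class MiRNA:
    """A mature miRNA, 18-30 nt, DNA alphabet.

    The seed is positions 2-8 (1-based, 5'->3') of the mature strand.
    """

    mirna_id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if not 18 <= len(self.seq) <= 30:
            raise ValueError(
                f"{self.mirna_id}: mature miRNA must be 18-30 nt, got {len(self.seq)}"
            )
        if set(self.seq) - DNA:
            raise ValueError(f"{self.mirna_id}: non-ACGT characters")

    @property
    def seed(self) -> str:
        return self.seq[1:8]


@dataclass
class PlantedCirc:
    """A simulated circRNA defined by its back-splice junction.

    ``junction = (acceptor_start, donor_end)``: the circle runs from the
    acceptor (5' boundary on the plus strand) to the donor and closes
    head-to-tail.  ``exons`` are the constituent exon intervals (the whole
    span for intronic/intergenic circles).
    """

    circ_id: str
    chrom: str
    strand: str
    junction: tuple[int, int]
    exons: list[tuple[int, int]]
    circ_type: str  # intended type at generation time

    def __post_init__(self) -> None:
        a, d = self.junction
        if a >= d:
            raise ValueError(f"{self.circ_id}: acceptor_start must be < donor_end")
        for s, e in self.exons:
            if not (a <= s < e <= d):
                raise ValueError(f"{self.circ_id}: exon outside junction span")

    @property
    def span_len(self) -> int:
        return self.junction[1] - self.junction[0]

    def genomic_span_seq(self, genome: Genome) -> str:
        """Unspliced circle sequence: the genomic segment between the junction
        boundaries (plus strand orientation)."""
        return genome.fetch(self.chrom, *self.junction)

    def mature_seq(self, genome: Genome) -> str:
        """Exon-joined circular sequence, strand-aware (the molecule miRNAs see)."""
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class GroundTruth:
    """Planted regulatory structure used to score every downstream stage."""

    true_log2fc: dict[str, float]
    triples: list[tuple[str, str, str]]  # (circ_id, mirna_id, mrna_id)
    target_pairs: set[tuple[str, str]]  # (mirna_id, target_id), both kinds
    read_labels: dict[str, dict] = field(default_factory=dict)

    @property
    def true_de(self) -> set[str]:
        return {f for f, lfc in self.true_log2fc.items() if abs(lfc) >= 1}


@dataclass
class CountMatrix:
    """Integer feature x sample counts with two groups and mapped totals."""

    counts: pd.DataFrame  # rows = features, columns = samples
    groups: dict[str, str]  # sample_id -> group label in {C, G}
    mapped_totals: pd.Series  # per-sample mapped-read totals

    def __post_init__(self) -> None:
        if set(self.groups) != set(self.counts.columns):
            raise ValueError("group labels do not match sample columns")
        if set(self.groups.values()) != {"C", "G"}:
            raise ValueError("exactly two groups C and G required")
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


@dataclass
class CircRNACall:
    """A called back-splice junction with per-sample unique-read support."""

    circ_id: str
    chrom: str
    strand: str
    junction: tuple[int, int]
    support: dict[str, int]  # sample -> distinct supporting read sequences
    circ_type: str = "unclassified"

    @property
    def max_support(self) -> int:
        return max(self.support.values()) if self.support else 0

    @property
    def span_len(self) -> int:
        return self.junction[1] - self.junction[0]


@dataclass
class TargetSite:
    """One predicted miRNA binding site on a 3'UTR or circRNA."""

    mirna_id: str
    target_id: str
    target_kind: str  # utr3 | circ
    position: int  # 0-based on target sequence
    site_type: str  # 8mer | 7mer-m8
    source: str  # miranda | seedmatch | both
    score: float = float("nan")
    energy: float = float("nan")
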
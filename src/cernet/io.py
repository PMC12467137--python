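"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; GTF, BED, counts TSV and GMT are simple
line formats written directly.  GTF is 1-based closed on disk; BED and all
in-memory coordinates are 0-based half-open.
"""
from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CountMatrix, GeneModel, Genome, MiRNA


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path,
        "fasta",
    )


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_genome_fasta(path: str, genome: Genome) -> None:
    write_fasta(path, sorted(genome.chroms.items()))


def write_mirna_fasta(path: str, mirnas: list[MiRNA]) -> None:
    write_fasta(path, [(m.mirna_id, m.seq) for m in mirnas])


def write_fastq(path: str, reads: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def write_gtf(path: str, genes: list[GeneModel], source: str = "cernet") -> None:
    """Write gene/exon/three_prime_utr features, 1-based closed coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            s, e = g.utr3
            fh.write(
                f"{g.chrom}\t{source}\tthree_prime_utr\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: str) -> list[GeneModel]:
    """Read gene models written by :func:`write_gtf` (exon + three_prime_utr)."""
    exons: dict[str, list] = {}
    utr3: dict[str, tuple[int, int]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feat, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            gid = attrs.split('gene_id "', 1)[1].split('"', 1)[0]
            iv = (int(start) - 1, int(end))
            meta[gid] = (chrom, strand)
            if feat == "exon":
                exons.setdefault(gid, []).append(iv)
            elif feat == "three_prime_utr":
                utr3[gid] = iv
    out = []
    for gid, (chrom, strand) in meta.items():
        out.append(GeneModel(gid, chrom, strand, sorted(exons[gid]), utr3[gid]))
    return out


def write_counts_tsv(path: str, cm: CountMatrix) -> None:
    cm.counts.rename_axis("feature_id").to_csv(path, sep="\t")


def read_counts_tsv(path: str, sample_sheet: str | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.astype(int)
    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep="\t")
        groups = dict(zip(sheet.iloc[:, 0].astype(str), sheet.iloc[:, 1].astype(str)))
    else:
        # fall back on sample-name prefixes (C1..Cn / G1..Gn)
        groups = {s: s[0] for s in df.columns}
    return CountMatrix(df, groups, df.sum(axis=0))


def write_sample_sheet(path: str, groups: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


def read_gmt(path: str) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT term map: term_id -> (description, member gene set)."""
    terms = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = (parts[1], set(p for p in parts[2:] if p))
    return terms


def write_gmt(path: str, terms: dict[str, tuple[str, set[str]]]) -> None:
    with open(path, "w") as fh:
        for tid, (desc, members) in terms.items():
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
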
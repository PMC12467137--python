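"""Synthetic reference, regulation-planting and read/count simulators.

The generators build a miniature two-group (control ``C`` vs grazing ``G``)
muscle transcriptome study entirely in silico: a random genome with gene
models, mature miRNAs and planted circRNAs; known ceRNA triples whose
binding sites are physically embedded in the sequence; negative-binomial
count matrices carrying the planted fold changes and sponge-style
correlation structure; and junction-spanning reads for the back-splice
caller.  Every stage records the ground truth needed to score the
corresponding analysis stage.

Order matters: ``plant_regulation`` edits the genome sequence (it embeds
miRNA binding sites), so reads must be simulated *after* planting.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CountMatrix, GeneModel, Genome, GroundTruth, MiRNA, PlantedCirc, revcomp

ANCHOR_LEN = 20
BASES = np.array(list("ACGT"))

#: circRNA class proportions emulating typical muscle circRNA surveys,
#: dominated by multi-exon circles with annotated boundaries.
DEFAULT_TYPE_MIX = {
    "annot-exon": 0.79,
    "exon-intron": 0.12,
    "one-exon": 0.03,
    "intron": 0.03,
    "intergenic": 0.03,
}


@dataclass
class Reference:
    """Bundle of all generated reference material."""

    genome: Genome
    genes: list[GeneModel]
    mirnas: list[MiRNA]
    circs: list[PlantedCirc]

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def mirna(self, mirna_id: str) -> MiRNA:
        return next(m for m in self.mirnas if m.mirna_id == mirna_id)

    def circ(self, circ_id: str) -> PlantedCirc:
        return next(c for c in self.circs if c.circ_id == circ_id)


class CapacityError(RuntimeError):
    """Requested features cannot be placed on the requested genome."""


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _allocate_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items to the type mix."""
    total = sum(mix.values())
    raw = {t: n * w / total for t, w in mix.items()}
    counts = {t: int(v) for t, v in raw.items()}
    leftover = n - sum(counts.values())
    for t in sorted(mix, key=lambda t: raw[t] - counts[t], reverse=True)[:leftover]:
        counts[t] += 1
    return counts


def generate_reference(
    n_chrom: int = 2,
    chrom_length: int = 60_000,
    n_genes: int = 30,
    n_mirnas: int = 15,
    n_circ: int = 12,
    seed: int = 0,
    type_mix: dict[str, float] | None = None,
    utr3_len: int = 300,
    n_exons_range: tuple[int, int] = (3, 6),
    exon_len_range: tuple[int, int] = (150, 300),
    intron_len_range: tuple[int, int] = (150, 300),
) -> Reference:
    """Generate a random genome with gene models, miRNAs and planted circRNAs.

    Genes are laid left-to-right with random intergenic gaps; every gene
    carries a 3'UTR of ``utr3_len`` (>= 200) nt inside its terminal exon.
    circRNAs are placed according to ``type_mix`` so that the structural
    classifier can be audited against the intended class.

    Raises :class:`CapacityError` when the genome cannot host the request.
    """
    if min(n_chrom, chrom_length, n_genes, n_mirnas, n_circ) < 0:
        raise ValueError("all counts must be non-negative")
    if utr3_len < 200:
        raise ValueError("3'UTR length must be >= 200 nt")
    rng = np.random.default_rng(seed)
    mix = dict(type_mix) if type_mix is not None else dict(DEFAULT_TYPE_MIX)

    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_seqs = {c: list(_random_seq(rng, chrom_length)) for c in chrom_names}

    # --- gene placement -------------------------------------------------
    genes: list[GeneModel] = []
    if n_genes > 0:
        if n_chrom == 0:
            raise CapacityError("cannot place genes on an empty genome")
        cursors = dict.fromkeys(chrom_names, 0)
        order = list(chrom_names)
        ci = 0
        for gi in range(n_genes):
            n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
            exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, size=n_ex)
            intron_lens = rng.integers(
                intron_len_range[0], intron_len_range[1] + 1, size=max(n_ex - 1, 0)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            # terminal exon in transcription order must hold the 3'UTR
            term = n_ex - 1 if strand == "+" else 0
            exon_lens[term] = max(exon_lens[term], utr3_len + 60)
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            gap = int(rng.integers(250, 601))
            placed = False
            for _ in range(n_chrom):
                chrom = order[ci % n_chrom]
                start = cursors[chrom] + gap
                if start + gene_len <= chrom_length:
                    placed = True
                    break
                ci += 1
            if not placed:
                raise CapacityError(
                    f"cannot place gene {gi + 1}/{n_genes}: genome too small"
                )
            exons = []
            pos = start
            for k in range(n_ex):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_ex - 1:
                    pos += int(intron_lens[k])
            if strand == "+":
                utr3 = (exons[-1][1] - utr3_len, exons[-1][1])
            else:
                utr3 = (exons[0][0], exons[0][0] + utr3_len)
            genes.append(
                GeneModel(f"gene{gi + 1:03d}", chrom, strand, exons, utr3)
            )
            cursors[chrom] = exons[-1][1]
            ci += 1

    # --- miRNAs ----------------------------------------------------------
    mirnas: list[MiRNA] = []
    seen_seeds: set[str] = set()
    for mi in range(n_mirnas):
        for _ in range(200):
            # mature lengths 21-24 nt (the 21-23 nt mode of real small-RNA
            # libraries; a 20-mer's perfect duplex would sit below the
            # miRanda-style score threshold by construction)
            seq = _random_seq(rng, int(rng.integers(21, 25)))
            if seq[1:8] not in seen_seeds:
                seen_seeds.add(seq[1:8])
                mirnas.append(MiRNA(f"mir{mi + 1:03d}", seq))
                break
        else:  # pragma: no cover - astronomically unlikely
            raise CapacityError("could not draw a miRNA with a fresh seed")

    # --- circRNAs ---------------------------------------------------------
    circs: list[PlantedCirc] = []
    if n_circ > 0 and n_genes > 0:
        counts = _allocate_counts(n_circ, mix)
        used_junctions: set[tuple[str, int, int]] = set()
        idx = 1
        for ctype, n_of_type in counts.items():
            for _ in range(n_of_type):
                circ = _place_circ(
                    rng, ctype, genes, chrom_seqs, chrom_length, used_junctions,
                    f"circ{idx:03d}",
                )
                circs.append(circ)
                used_junctions.add((circ.chrom, *circ.junction))
                idx += 1

    _disambiguate_junctions(rng, circs, chrom_seqs)
    genome = Genome({c: "".join(s) for c, s in chrom_seqs.items()})
    return Reference(genome, genes, mirnas, circs)


def _disambiguate_junctions(rng, circs, chrom_seqs, max_rounds: int = 10) -> None:
    """Make every planted junction its own leftmost representation.

    If the genome base just before the acceptor equals the base just before
    the donor, the circle admits an equivalent junction shifted one base
    left, and a leftmost-acceptor caller would report that instead of the
    planted coordinates.  Rewriting the (intronic/intergenic) base before
    the acceptor removes the ambiguity.
    """
    for _ in range(max_rounds):
        dirty = False
        for c in circs:
            acc, don = c.junction
            seq = chrom_seqs[c.chrom]
            if acc > 0 and seq[acc - 1] == seq[don - 1]:
                options = [b for b in "ACGT" if b != seq[don - 1]]
                seq[acc - 1] = options[int(rng.integers(0, 3))]
                dirty = True
        if not dirty:
            return


def _place_circ(rng, ctype, genes, chrom_seqs, chrom_length, used, circ_id,
                max_tries: int = 200) -> PlantedCirc:
    for _ in range(max_tries):
        if ctype == "intergenic":
            circ = _place_intergenic(rng, genes, chrom_seqs, chrom_length, circ_id)
        else:
            gene = genes[int(rng.integers(0, len(genes)))]
            circ = _place_genic(rng, ctype, gene, circ_id)
        if circ is not None and (circ.chrom, *circ.junction) not in used:
            return circ
    raise CapacityError(f"cannot place a {ctype} circRNA after {max_tries} tries")


def _place_genic(rng, ctype, gene: GeneModel, circ_id) -> PlantedCirc | None:
    exons = gene.exons
    n_ex = len(exons)
    if ctype == "one-exon":
        k = int(rng.integers(0, n_ex))
        s, e = exons[k]
        return PlantedCirc(circ_id, gene.chrom, gene.strand, (s, e), [(s, e)], ctype)
    if ctype == "annot-exon":
        if n_ex < 2:
            return None
        i = int(rng.integers(0, n_ex - 1))
        j = int(rng.integers(i + 1, n_ex))
        junction = (exons[i][0], exons[j][1])
        return PlantedCirc(
            circ_id, gene.chrom, gene.strand, junction, exons[i : j + 1], ctype
        )
    if ctype == "exon-intron":
        if n_ex < 2:
            return None
        j = int(rng.integers(0, n_ex - 1))  # donor extends into intron after exon j
        i = int(rng.integers(0, j + 1))
        intron = (exons[j][1], exons[j + 1][0])
        donor = (intron[0] + intron[1]) // 2
        junction = (exons[i][0], donor)
        return PlantedCirc(
            circ_id, gene.chrom, gene.strand, junction, exons[i : j + 1], ctype
        )
    if ctype == "intron":
        if n_ex < 2:
            return None
        k = int(rng.integers(0, n_ex - 1))
        s, e = exons[k][1], exons[k + 1][0]
        if e - s < 110:
            return None
        junction = (s + 10, e - 10)
        return PlantedCirc(
            circ_id, gene.chrom, gene.strand, junction, [junction], ctype
        )
    raise ValueError(f"unknown circRNA type {ctype!r}")


def _place_intergenic(rng, genes, chrom_seqs, chrom_length, circ_id) -> PlantedCirc | None:
    chroms = list(chrom_seqs)
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    spans = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
    gaps, prev = [], 0
    for s, e in spans:
        gaps.append((prev, s))
        prev = e
    gaps.append((prev, chrom_length))
    gaps = [(s + 50, e - 50) for s, e in gaps if e - s >= 300]
    if not gaps:
        return None
    gs, ge = gaps[int(rng.integers(0, len(gaps)))]
    length = int(rng.integers(150, min(251, ge - gs + 1)))
    start = int(rng.integers(gs, ge - length + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    junction = (start, start + length)
    return PlantedCirc(circ_id, chrom, strand, junction, [junction], "intergenic")


# ---------------------------------------------------------------------------
# regulation planting
# ---------------------------------------------------------------------------

def _write_transcript(chrom_seq: list[str], interval: tuple[int, int], strand: str,
                      offset: int, site: str) -> tuple[int, int]:
    """Write ``site`` at transcript-space ``offset`` of a genomic interval.

    Returns the genomic interval that was overwritten.
    """
    s, e = interval
    if strand == "+":
        gs = s + offset
        piece = site
    else:
        gs = e - offset - len(site)
        piece = revcomp(site)
    ge = gs + len(site)
    if not (s <= gs and ge <= e):
        raise ValueError("site does not fit in interval")
    chrom_seq[gs:ge] = list(piece)
    return (gs, ge)


def plant_regulation(
    ref: Reference,
    n_triples: int = 8,
    site_len: int | None = None,
    seed: int = 0,
    planted_lfc: float = 3.0,
    extra_de_frac: float = 0.25,
    max_tries: int = 50,
) -> GroundTruth:
    """Plant ceRNA triples (circRNA, miRNA, mRNA) into the reference.

    For each triple the exact reverse complement of the miRNA (or of its
    5' ``site_len`` prefix, which must cover seed positions 2-8) is embedded
    in the host mRNA's 3'UTR and in one exon of the circRNA, so both target
    predictors can recover the pair.  True log2 fold changes are assigned so
    the circRNA and mRNA rise in group G while the shared miRNA falls.

    Mutates ``ref.genome`` in place; simulate reads only after planting.
    """
    if n_triples > min(len(ref.circs), len(ref.mirnas), len(ref.genes)):
        raise ValueError("n_triples exceeds available circRNAs/miRNAs/genes")
    rng = np.random.default_rng(seed)
    chrom_seqs = {c: list(s) for c, s in ref.genome.chroms.items()}
    used: list[tuple[str, int, int]] = []

    circ_ids = [c.circ_id for c in ref.circs]
    mir_ids = [m.mirna_id for m in ref.mirnas]
    gene_ids = [g.gene_id for g in ref.genes]
    pick_c = list(rng.permutation(circ_ids)[:n_triples])
    pick_m = list(rng.permutation(mir_ids)[:n_triples])
    pick_g = list(rng.permutation(gene_ids)[:n_triples])

    triples: list[tuple[str, str, str]] = []
    target_pairs: set[tuple[str, str]] = set()
    for cid, mid, gid in zip(pick_c, pick_m, pick_g):
        mirna = ref.mirna(mid)
        mseq = mirna.seq if site_len is None else mirna.seq[:site_len]
        if len(mseq) < 8:
            raise ValueError("site_len must cover seed positions 2-8 (>= 8 nt)")
        site = revcomp(mseq)
        gene = ref.gene(gid)
        _embed(rng, chrom_seqs[gene.chrom], gene.utr3, gene.strand, site,
               gene.chrom, used, max_tries)
        circ = ref.circ(cid)
        host_exons = [iv for iv in circ.exons if iv[1] - iv[0] >= len(site) + 10]
        if not host_exons:
            raise CapacityError(f"{cid}: no exon can host a {len(site)} nt site")
        exon = host_exons[int(rng.integers(0, len(host_exons)))]
        _embed(rng, chrom_seqs[circ.chrom], exon, circ.strand, site,
               circ.chrom, used, max_tries)
        triples.append((cid, mid, gid))
        target_pairs.add((mid, cid))
        target_pairs.add((mid, gid))

    # planted fold changes: sponge legs move together, the miRNA opposes.
    # Directions alternate between triples so neither direction dominates a
    # count matrix (real DE tallies are near-balanced; majority one-way DE
    # would defeat median-of-ratios normalization on small matrices).
    true_lfc: dict[str, float] = {f: 0.0 for f in circ_ids + mir_ids + gene_ids}
    for k, (cid, mid, gid) in enumerate(triples):
        direction = 1.0 if k % 2 == 0 else -1.0
        true_lfc[cid] = direction * planted_lfc
        true_lfc[gid] = direction * planted_lfc
        true_lfc[mid] = -direction * planted_lfc
    # extra (non-triple) DE features keep the DE stage honest
    free = [f for f, v in true_lfc.items() if v == 0.0]
    n_extra = int(round(extra_de_frac * len(free)))
    for f in rng.permutation(free)[:n_extra]:
        true_lfc[f] = planted_lfc * (1 if rng.random() < 0.5 else -1)

    ref.genome = Genome({c: "".join(s) for c, s in chrom_seqs.items()})
    return GroundTruth(true_lfc, triples, target_pairs)


def _embed(rng, chrom_seq, interval, strand, site, chrom, used, max_tries):
    s, e = interval
    room = (e - s) - len(site)
    if room < 0:
        raise CapacityError("interval too short for binding site")
    for _ in range(max_tries):
        off = int(rng.integers(0, room + 1))
        gs = (s + off) if strand == "+" else (e - off - len(site))
        ge = gs + len(site)
        if all(c != chrom or ge <= us or ue <= gs for c, us, ue in used):
            _write_transcript(chrom_seq, interval, strand, off, site)
            used.append((chrom, gs, ge))
            return
    raise CapacityError("could not embed binding site without collision")


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean m, dispersion a) with variance m + a*m^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    truth: GroundTruth,
    ref: Reference,
    n_per_group: int = 5,
    base_mean_range: tuple[float, float] = (100.0, 1000.0),
    dispersion: float = 0.05,
    sponge_sigma: float = 0.8,
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix, CountMatrix]:
    """Draw NB count matrices for circRNAs, miRNAs and mRNAs.

    Group C means are the per-feature base means (log-uniform over
    ``base_mean_range``); group G means are ``base * 2**true_log2fc``.  For
    every planted triple one latent log-normal factor per sample multiplies
    the circRNA and mRNA means and divides the miRNA mean, imprinting the
    sponge-style correlation sign structure the network stage filters for.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    samples = [f"C{i + 1}" for i in range(n_per_group)] + [
        f"G{i + 1}" for i in range(n_per_group)
    ]
    groups = {s: s[0] for s in samples}
    n_s = len(samples)

    classes = {
        "circ": [c.circ_id for c in ref.circs],
        "mirna": [m.mirna_id for m in ref.mirnas],
        "mrna": [g.gene_id for g in ref.genes],
    }
    lo, hi = np.log10(base_mean_range[0]), np.log10(base_mean_range[1])
    means: dict[str, np.ndarray] = {}
    for cls, feats in classes.items():
        m = np.empty((len(feats), n_s))
        for i, f in enumerate(feats):
            base = 10 ** rng.uniform(lo, hi)
            lfc = truth.true_log2fc.get(f, 0.0)
            row = np.full(n_s, base)
            row[n_per_group:] = base * 2.0**lfc
            m[i] = row
        means[cls] = m

    index = {cls: {f: i for i, f in enumerate(feats)} for cls, feats in classes.items()}
    for cid, mid, gid in truth.triples:
        log_f = sponge_sigma * rng.standard_normal(n_s)
        # centre within each group so the factor imprints within-group
        # covariance without perturbing the group-mean fold changes
        log_f[:n_per_group] -= log_f[:n_per_group].mean()
        log_f[n_per_group:] -= log_f[n_per_group:].mean()
        factor = np.exp(log_f)
        means["circ"][index["circ"][cid]] *= factor
        means["mrna"][index["mrna"][gid]] *= factor
        means["mirna"][index["mirna"][mid]] /= factor

    out = []
    for cls in ("circ", "mirna", "mrna"):
        counts = _nb_draw(rng, means[cls], dispersion).astype(np.int64)
        df = pd.DataFrame(counts, index=classes[cls], columns=samples)
        # mapped totals represent the whole library: the simulated panel is
        # a sliver of it, plus a constant background mass (other RNA classes,
        # unquantified features).  Without the background, per-million scaling
        # of a small panel couples every feature to every other feature's
        # noise through the shared denominator - an artifact real libraries
        # do not show.
        background = int(20 * df.to_numpy().sum() / len(samples))
        totals = df.sum(axis=0) + background
        out.append(CountMatrix(df, dict(groups), totals))
    return tuple(out)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: Genome,
    circs: list[PlantedCirc],
    samples: list[str],
    read_len: int = 100,
    junction_reads_per_circ: int = 8,
    linear_reads: int = 300,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, list[tuple[str, str]]], dict[str, dict]]:
    """Simulate per-sample reads: back-splice junction reads plus linear reads.

    Junction reads straddle the head-to-tail joint with at least
    ``ANCHOR_LEN`` bases on each side: a suffix of the circle (donor side)
    followed by a prefix of the circle (acceptor side).  Linear reads are
    contiguous genome substrings.  Returns ``{sample: [(read_id, seq), ...]}``
    and per-read truth labels.
    """
    if read_len < 2 * ANCHOR_LEN:
        raise ValueError(
            f"read_len must be >= 2*anchor_len = {2 * ANCHOR_LEN}, got {read_len}"
        )
    rng = np.random.default_rng(seed)
    reads: dict[str, list[tuple[str, str]]] = {s: [] for s in samples}
    labels: dict[str, dict] = {}
    for sample in samples:
        for circ in circs:
            span = circ.genomic_span_seq(genome)
            L = len(span)
            a_lo = max(ANCHOR_LEN, read_len - L)
            a_hi = min(read_len - ANCHOR_LEN, L)
            if a_lo > a_hi:
                raise CapacityError(
                    f"{circ.circ_id}: span {L} too short for {read_len} nt junction reads"
                )
            choices = np.arange(a_lo, a_hi + 1)
            if junction_reads_per_circ <= len(choices):
                a_vals = rng.choice(choices, size=junction_reads_per_circ, replace=False)
            else:
                a_vals = rng.choice(choices, size=junction_reads_per_circ, replace=True)
            for k, a in enumerate(sorted(int(x) for x in a_vals)):
                seq = span[L - a :] + span[: read_len - a]
                if circ.strand == "-":
                    seq = revcomp(seq)
                seq = _with_errors(rng, seq, error_rate)
                rid = f"{sample}:junc:{circ.circ_id}:{k}"
                reads[sample].append((rid, seq))
                labels[rid] = {
                    "kind": "junction",
                    "circ_id": circ.circ_id,
                    "chrom": circ.chrom,
                    "strand": circ.strand,
                    "junction": list(circ.junction),
                    "sample": sample,
                }
        chroms = list(genome.chroms)
        for k in range(linear_reads):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            seq_len = len(genome[chrom])
            pos = int(rng.integers(0, seq_len - read_len + 1))
            seq = genome.fetch(chrom, pos, pos + read_len)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            seq = _with_errors(rng, seq, error_rate)
            rid = f"{sample}:lin:{k}"
            reads[sample].append((rid, seq))
            labels[rid] = {"kind": "linear", "chrom": chrom, "pos": pos,
                           "strand": strand, "sample": sample}
    return reads, labels


def _with_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < error_rate
    for i in np.nonzero(hit)[0]:
        alt = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alt[int(rng.integers(0, 3))]
    return "".join(arr)


def truth_to_json(truth: GroundTruth) -> str:
    """Serialise the ground truth (for the `simulate` CLI output)."""
    return json.dumps(
        {
            "true_log2fc": truth.true_log2fc,
            "triples": [list(t) for t in truth.triples],
            "target_pairs": sorted(list(p) for p in truth.target_pairs),
            "read_labels": truth.read_labels,
        },
        indent=1,
    )
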
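"""End-to-end planted-truth pipeline: simulate -> detect -> DE -> targets -> network.

Mirrors the study design: two groups (control C, grazing G) of five
replicates, circRNA calling from reads, |log2FC| >= 1 and p < 0.05
differential expression per RNA class, dual target prediction for the
differential miRNAs, and correlation-filtered ceRNA triple assembly.
Because every input is simulated with known ground truth, the run reports
recovery metrics (triple recall/precision, caller recall) alongside the
biological outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import circdetect, expression, network, simulate
from . import targets as tp
from .types import CircRNACall, CountMatrix, GroundTruth


@dataclass
class PipelineResult:
    ref: simulate.Reference
    truth: GroundTruth
    calls: list[CircRNACall]
    detect_stats: circdetect.DetectStats
    de_circ: pd.DataFrame
    de_mir: pd.DataFrame
    de_mrna: pd.DataFrame
    pairs: set[tuple[str, str]]
    triples: list[network.CeRNATriple]
    metrics: dict[str, float] = field(default_factory=dict)


def match_calls_to_planted(calls: list[CircRNACall],
                           circs: list[simulate.PlantedCirc]) -> dict[str, str]:
    """Map call ids to planted circ ids by exact junction coordinates."""
    planted = {(c.chrom, c.strand, *c.junction): c.circ_id for c in circs}
    out = {}
    for call in calls:
        key = (call.chrom, call.strand, *call.junction)
        if key in planted:
            out[call.circ_id] = planted[key]
    return out


def run_pipeline(
    seed: int = 0,
    n_chrom: int = 2,
    chrom_length: int = 60_000,
    n_genes: int = 30,
    n_mirnas: int = 15,
    n_circ: int = 12,
    n_triples: int = 8,
    n_per_group: int = 5,
    dispersion: float = 0.05,
    sponge_sigma: float = 0.8,
    junction_reads_per_circ: int = 8,
    linear_reads: int = 200,
    min_unique_reads: int = 2,
    p_scope: str = "all",
) -> PipelineResult:
    """Run the whole analysis on a freshly simulated study."""
    ref = simulate.generate_reference(
        n_chrom=n_chrom, chrom_length=chrom_length, n_genes=n_genes,
        n_mirnas=n_mirnas, n_circ=n_circ, seed=seed,
    )
    truth = simulate.plant_regulation(ref, n_triples=n_triples, seed=seed + 1)
    cm_circ, cm_mir, cm_mrna = simulate.simulate_counts(
        truth, ref, n_per_group=n_per_group, dispersion=dispersion,
        sponge_sigma=sponge_sigma, seed=seed + 2,
    )
    samples = list(cm_circ.counts.columns)
    reads, labels = simulate.simulate_reads(
        ref.genome, ref.circs, samples,
        junction_reads_per_circ=junction_reads_per_circ,
        linear_reads=linear_reads, seed=seed + 3,
    )
    truth.read_labels = labels

    calls, stats = circdetect.detect_circrnas(
        reads, ref.genome, ref.genes, min_unique_reads=min_unique_reads,
    )
    matched = match_calls_to_planted(calls, ref.circs)
    for call in calls:
        if call.circ_id in matched:
            call.circ_id = matched[call.circ_id]
    called_circ_ids = {c.circ_id for c in calls}

    # differential expression per RNA class (simulated counts; the reads
    # establish which circRNAs exist, the count matrices their abundance)
    detected_circ_counts = CountMatrix(
        cm_circ.counts.loc[sorted(called_circ_ids & set(cm_circ.counts.index))],
        cm_circ.groups, cm_circ.mapped_totals,
    )
    de_circ = expression.de_test(detected_circ_counts)
    de_mir = expression.de_test(cm_mir)
    de_mrna = expression.de_test(cm_mrna)

    de_mir_ids = set(de_mir.index[de_mir["regulated"] != "ns"])
    de_circ_ids = set(de_circ.index[de_circ["regulated"] != "ns"])
    de_mrna_ids = set(de_mrna.index[de_mrna["regulated"] != "ns"])

    # dual target prediction for the differential miRNAs
    mirnas = [m for m in ref.mirnas if m.mirna_id in de_mir_ids]
    utr_targets = {g.gene_id: g.utr3_seq(ref.genome)
                   for g in ref.genes if g.gene_id in de_mrna_ids}
    circ_targets = {c.circ_id: c.mature_seq(ref.genome)
                    for c in ref.circs if c.circ_id in de_circ_ids}
    pairs: set[tuple[str, str]] = set()
    for kind, targets in (("utr3", utr_targets), ("circ", circ_targets)):
        mir_sites = tp.predict_miranda(mirnas, targets, kind)
        seed_sites = tp.predict_seedmatch(mirnas, targets, kind)
        pairs |= tp.site_pairs(tp.intersect_predictions(mir_sites, seed_sites))

    expr_circ = expression.rpm(cm_circ).values
    expr_mir = expression.tpm_mirna(cm_mir).values
    expr_mrna = expression.rpm(cm_mrna).values
    edges = network.build_edges(pairs, expr_circ, expr_mir, expr_mrna,
                                p_scope=p_scope)
    triples = network.assemble_triples(*edges)
    network.validate_triples(triples, pairs)

    reported = {(t.circ_id, t.mirna_id, t.mrna_id) for t in triples}
    planted = set(truth.triples)
    metrics = {
        "triple_recall": _ratio(len(reported & planted), len(planted)),
        "triple_precision": _ratio(len(reported & planted), len(reported)),
        "circ_call_recall": _ratio(len(matched), len(ref.circs)),
        "circ_call_precision": _ratio(len(matched), len(calls)),
        "n_triples_reported": float(len(reported)),
        "n_de_circ": float(len(de_circ_ids)),
        "n_de_mir": float(len(de_mir_ids)),
        "n_de_mrna": float(len(de_mrna_ids)),
        "n_target_pairs": float(len(pairs)),
    }
    return PipelineResult(ref, truth, calls, stats, de_circ, de_mir, de_mrna,
                          pairs, triples, metrics)


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")
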
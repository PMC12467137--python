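"""Correlation-filtered ceRNA (circRNA-miRNA-mRNA) network assembly.

Sponge legs (circRNA-miRNA and miRNA-mRNA) must be predicted target pairs
with Spearman rank correlation < -0.5; the circRNA-mRNA leg is tested for
every pair sharing at least one candidate miRNA and must have Pearson
correlation > 0.7.  All inequalities are strict, and by default every leg
must also reach p < 0.05 (two-sided).  Correlations are computed across
all samples of both groups pooled, on normalized expression.  A triple is
emitted when all three legs survive.
"""
from __future__ import annotations

import itertools
import json
import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SCC_THRESHOLD = -0.5
PCC_THRESHOLD = 0.7
P_THRESHOLD = 0.05


@dataclass
class CorrelationEdge:
    node_a: str
    class_a: str
    node_b: str
    class_b: str
    method: str  # spearman | pearson
    coefficient: float
    p_value: float
    n: int


@dataclass
class CeRNATriple:
    circ_id: str
    mirna_id: str
    mrna_id: str
    scc_circ_mir: float
    scc_mir_mrna: float
    pcc_circ_mrna: float
    p_circ_mir: float
    p_mir_mrna: float
    p_circ_mrna: float


def spearman_edge(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks, ties averaged) with t-approximation p."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    _check_vectors(x, y)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pearson_edge(x, y) -> tuple[float, float]:
    """Pearson product-moment r with two-sided t p-value (n-2 df)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    _check_vectors(x, y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _check_vectors(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 samples for a correlation edge")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")


_exact_null_cache: dict[int, np.ndarray] = {}


def _spearman_null_counts(n: int) -> np.ndarray:
    """Exact null distribution of D = sum d^2 over all rank permutations.

    Returns counts[D] for D = 0 .. n(n^2-1)/3.  Feasible for n <= 10
    (10! = 3.6M permutations, enumerated in vectorized chunks and cached).
    """
    if n in _exact_null_cache:
        return _exact_null_cache[n]
    if n > 10:
        raise ValueError("exact Spearman null only enumerated for n <= 10")
    dmax = n * (n * n - 1) // 3
    counts = np.zeros(dmax + 1, dtype=np.int64)
    ident = np.arange(n)
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 200_000))
        if not chunk:
            break
        arr = np.asarray(chunk, dtype=np.int64)
        d = ((arr - ident) ** 2).sum(axis=1)
        counts += np.bincount(d, minlength=dmax + 1)
    _exact_null_cache[n] = counts
    return counts


def spearman_exact_p(x, y) -> tuple[float, float]:
    """Spearman rho with the exact two-sided rank-permutation p (n <= 10).

    Serves as the small-sample oracle for the t-approximation.  Requires
    tie-free vectors (the null distribution is enumerated on distinct ranks).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    _check_vectors(x, y)
    n = len(x)
    if len(set(x)) < n or len(set(y)) < n:
        raise ValueError("exact permutation p requires tie-free vectors")
    rx = stats.rankdata(x) - 1
    ry = stats.rankdata(y) - 1
    d_obs = int(((rx - ry) ** 2).sum())
    denom = n * (n * n - 1)
    rho = 1.0 - 6.0 * d_obs / denom
    counts = _spearman_null_counts(n)
    dmax = len(counts) - 1
    # |rho_perm| >= |rho_obs|  <=>  D <= d_lo or D >= d_hi (rho falls with D)
    d_lo = d_obs if rho >= 0 else dmax - d_obs
    d_hi = dmax - d_lo
    p = (counts[: d_lo + 1].sum() + counts[d_hi:].sum()) / counts.sum()
    return float(rho), float(min(p, 1.0))


def build_edges(
    target_pairs: set[tuple[str, str]],
    expr_circ: pd.DataFrame,
    expr_mir: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    scc_thr: float = SCC_THRESHOLD,
    pcc_thr: float = PCC_THRESHOLD,
    p_thr: float = P_THRESHOLD,
    p_scope: str = "all",
) -> tuple[list[CorrelationEdge], list[CorrelationEdge], list[CorrelationEdge]]:
    """Correlation-filter candidate edges of the three leg types.

    ``target_pairs`` holds predicted (mirna_id, target_id) pairs for both
    sponge leg types; circRNA-mRNA candidates are all (circ, mrna) pairs
    sharing a candidate miRNA.  ``p_scope='pcc'`` applies the p < p_thr
    clause to the Pearson leg only (alternative reading); default 'all'.
    Pairs whose members lack an expression row are skipped.
    """
    if p_scope not in ("all", "pcc"):
        raise ValueError("p_scope must be 'all' or 'pcc'")
    circ_ids, mir_ids = set(expr_circ.index), set(expr_mir.index)
    mrna_ids = set(expr_mrna.index)

    def classify(tid: str) -> str | None:
        if tid in circ_ids:
            return "circ"
        if tid in mrna_ids:
            return "mrna"
        return None

    cm_pairs, mg_pairs = [], []
    for mir, tid in sorted(target_pairs):
        kind = classify(tid)
        if mir not in mir_ids or kind is None:
            continue
        (cm_pairs if kind == "circ" else mg_pairs).append((mir, tid))

    n = expr_circ.shape[1]
    scc_p_thr = p_thr if p_scope == "all" else math.inf
    circ_mir = [
        e for mir, circ in cm_pairs
        if (e := _scc_edge(circ, "circ", mir, "mirna", expr_circ.loc[circ],
                           expr_mir.loc[mir], n)) is not None
        and e.coefficient < scc_thr and e.p_value < scc_p_thr
    ]
    mir_mrna = [
        e for mir, g in mg_pairs
        if (e := _scc_edge(mir, "mirna", g, "mrna", expr_mir.loc[mir],
                           expr_mrna.loc[g], n)) is not None
        and e.coefficient < scc_thr and e.p_value < scc_p_thr
    ]

    # circRNA-mRNA candidates: share >= 1 candidate miRNA
    by_mir_circ, by_mir_mrna = defaultdict(set), defaultdict(set)
    for mir, circ in cm_pairs:
        by_mir_circ[mir].add(circ)
    for mir, g in mg_pairs:
        by_mir_mrna[mir].add(g)
    cg_candidates = sorted({
        (c, g) for mir in by_mir_circ
        for c in by_mir_circ[mir] for g in by_mir_mrna.get(mir, ())
    })
    circ_mrna = []
    for c, g in cg_candidates:
        try:
            r, p = pearson_edge(expr_circ.loc[c], expr_mrna.loc[g])
        except ValueError:
            continue
        if r > pcc_thr and p < p_thr:
            circ_mrna.append(CorrelationEdge(c, "circ", g, "mrna", "pearson", r, p, n))
    return circ_mir, mir_mrna, circ_mrna


def _scc_edge(a, cls_a, b, cls_b, xa, xb, n) -> CorrelationEdge | None:
    try:
        rho, p = spearman_edge(xa, xb)
    except ValueError:
        return None
    return CorrelationEdge(a, cls_a, b, cls_b, "spearman", rho, p, n)


def assemble_triples(
    circ_mir: list[CorrelationEdge],
    mir_mrna: list[CorrelationEdge],
    circ_mrna: list[CorrelationEdge],
) -> list[CeRNATriple]:
    """Join the three edge lists on shared miRNAs into deduplicated triples,
    ordered (circ, mirna, mrna) lexicographically."""
    cm = {(e.node_a, e.node_b): e for e in circ_mir}
    mg = {(e.node_a, e.node_b): e for e in mir_mrna}
    cg = {(e.node_a, e.node_b): e for e in circ_mrna}
    mir_to_circ, mir_to_mrna = defaultdict(set), defaultdict(set)
    for c, m in cm:
        mir_to_circ[m].add(c)
    for m, g in mg:
        mir_to_mrna[m].add(g)
    triples = {}
    for m in mir_to_circ:
        for c in mir_to_circ[m]:
            for g in mir_to_mrna.get(m, ()):
                if (c, g) in cg and (c, m, g) not in triples:
                    triples[(c, m, g)] = CeRNATriple(
                        c, m, g,
                        cm[(c, m)].coefficient, mg[(m, g)].coefficient,
                        cg[(c, g)].coefficient,
                        cm[(c, m)].p_value, mg[(m, g)].p_value,
                        cg[(c, g)].p_value,
                    )
    return [triples[k] for k in sorted(triples)]


def validate_triples(
    triples: list[CeRNATriple],
    target_pairs: set[tuple[str, str]],
    scc_thr: float = SCC_THRESHOLD,
    pcc_thr: float = PCC_THRESHOLD,
    p_thr: float = P_THRESHOLD,
) -> None:
    """Independent re-check of every reported triple's defining filters."""
    for t in triples:
        ok = (
            t.scc_circ_mir < scc_thr and t.scc_mir_mrna < scc_thr
            and t.pcc_circ_mrna > pcc_thr
            and max(t.p_circ_mir, t.p_mir_mrna, t.p_circ_mrna) < p_thr
            and (t.mirna_id, t.circ_id) in target_pairs
            and (t.mirna_id, t.mrna_id) in target_pairs
        )
        if not ok:
            raise AssertionError(f"triple {t} violates its defining filters")


def triples_to_frame(triples: list[CeRNATriple]) -> pd.DataFrame:
    return pd.DataFrame(
        [t.__dict__ for t in triples],
        columns=["circ_id", "mirna_id", "mrna_id", "scc_circ_mir",
                 "scc_mir_mrna", "pcc_circ_mrna", "p_circ_mir",
                 "p_mir_mrna", "p_circ_mrna"],
    )


def export_network(triples: list[CeRNATriple], outdir: str, prefix: str = "cerna") -> dict:
    """Write the network as edges TSV, GraphML and a Sankey-ready JSON.

    The Sankey JSON arranges nodes in three columns (circRNA, miRNA, mRNA);
    link weights are |correlation| of the two sponge legs.  Returns the
    Sankey payload.  An empty network yields valid empty files.
    """
    import networkx as nx

    from .io import ensure_dir

    ensure_dir(outdir)
    frame = triples_to_frame(triples)
    frame.to_csv(f"{outdir}/{prefix}_triples.tsv", sep="\t", index=False)

    dedup = {(t.circ_id, t.mirna_id, t.mrna_id): t for t in triples}
    links, nodes = {}, {}
    graph = nx.Graph()
    for t in dedup.values():
        for nid, cls in ((t.circ_id, "circRNA"), (t.mirna_id, "miRNA"),
                         (t.mrna_id, "mRNA")):
            nodes[nid] = cls
            graph.add_node(nid, rna_class=cls)
        links[(t.circ_id, t.mirna_id)] = abs(t.scc_circ_mir)
        links[(t.mirna_id, t.mrna_id)] = abs(t.scc_mir_mrna)
        graph.add_edge(t.circ_id, t.mirna_id, weight=abs(t.scc_circ_mir),
                       kind="circ-mir")
        graph.add_edge(t.mirna_id, t.mrna_id, weight=abs(t.scc_mir_mrna),
                       kind="mir-mrna")
    with open(f"{outdir}/{prefix}_edges.tsv", "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for (a, b), w in sorted(links.items()):
            fh.write(f"{a}\t{b}\t{w:.6g}\n")
    nx.write_graphml(graph, f"{outdir}/{prefix}_network.graphml")
    order = sorted(nodes, key=lambda n: ({"circRNA": 0, "miRNA": 1, "mRNA": 2}[nodes[n]], n))
    node_idx = {n: i for i, n in enumerate(order)}
    sankey = {
        "nodes": [{"name": n, "class": nodes[n]} for n in order],
        "links": [
            {"source": node_idx[a], "target": node_idx[b], "value": w}
            for (a, b), w in sorted(links.items())
        ],
    }
    with open(f"{outdir}/{prefix}_sankey.json", "w") as fh:
        json.dump(sankey, fh, indent=1)
    return sankey
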
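"""miRNA target prediction: seed scan and duplex alignment, intersected.

Two predictors run independently and their results are intersected at the
(miRNA, target) pair level:

* a TargetScan-style scan for exact reverse complements of the seed
  (miRNA positions 2-8, 1-based from the 5' end) in the target, reporting
  7mer-m8 sites and upgrading to 8mer when the target base facing miRNA
  position 1 is an A;
* a miRanda-style local duplex alignment of the miRNA against a window of
  the target, with Watson-Crick pairs scoring +5, G:U wobbles +1,
  mismatches -3, gap-open -4.0 and gap-extend -9.0, pair scores doubled in
  the seed region (5' weighting), and a per-pair stacking proxy for the
  duplex energy (GC -3, AU -2, GU -1 kcal/mol).  A site is kept when
  score >= 140, energy <= -10 kcal/mol and the seed (positions 2-8) is
  paired Watson-Crick without gaps.

circRNA targets are scanned on the doubled circular sequence so sites
crossing the back-splice junction are found; positions are reported modulo
the circle length.
"""
from __future__ import annotations

from dataclasses import dataclass

from .types import MiRNA, TargetSite, revcomp

SCORE_WC = 5.0
SCORE_GU = 1.0
SCORE_MISMATCH = -3.0
GAP_OPEN = -4.0
GAP_EXTEND = -9.0
SEED_POSITIONS = range(2, 9)  # miRNA positions 2-8, 1-based
ENERGY = {"GC": -3.0, "AU": -2.0, "GU": -1.0}
SCORE_THRESHOLD = 140.0
ENERGY_THRESHOLD = -10.0

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def pair_state(mirna_base: str, target_base: str) -> str:
    """Pairing state of a miRNA base opposite a target base (DNA alphabet)."""
    duo = (mirna_base, target_base)
    if duo in _WC:
        return "WC"
    if duo in _GU:
        return "GU"
    return "mismatch"


def pair_score(mirna_base: str, target_base: str, mirna_pos: int) -> float:
    """Score of one aligned pair; seed-region pair scores are doubled."""
    state = pair_state(mirna_base, target_base)
    base = {"WC": SCORE_WC, "GU": SCORE_GU, "mismatch": SCORE_MISMATCH}[state]
    return 2.0 * base if mirna_pos in SEED_POSITIONS else base


def pair_energy(mirna_base: str, target_base: str) -> float:
    """Stacking proxy for one pair: GC -3, AU -2, GU -1 kcal/mol, else 0."""
    state = pair_state(mirna_base, target_base)
    if state == "GU":
        return ENERGY["GU"]
    if state == "WC":
        return ENERGY["GC"] if mirna_base in "GC" else ENERGY["AU"]
    return 0.0


def gap_cost(length: int) -> float:
    """Affine gap: first gapped position pays open, the rest extend."""
    if length <= 0:
        return 0.0
    return GAP_OPEN + (length - 1) * GAP_EXTEND


def seed_of(mirna: MiRNA | str) -> str:
    """Seed = positions 2-8 (1-based, 5'->3') of the mature miRNA."""
    seq = mirna.seq if isinstance(mirna, MiRNA) else mirna
    if len(seq) < 8:
        raise ValueError(f"miRNA must be >= 8 nt for a 2-8 seed, got {len(seq)}")
    return seq[1:8]


@dataclass
class DuplexAlignment:
    """One local miRNA:target duplex with its pairing trace.

    ``pairs`` lists (mirna_pos 1-based, target_pos 0-based in the window,
    state) for aligned pairs, 5'->3' along the target.
    """

    mirna_id: str
    target_id: str
    offset: int  # window-local 0-based start of the aligned target region
    pairs: list[tuple[int, int, str]]
    score: float
    energy: float
    seed_strict: bool


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) occurrence positions of needle in haystack."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def seedmatch_scan(mirna: MiRNA, target_seq: str, target_id: str,
                   target_kind: str = "utr3") -> list[TargetSite]:
    """TargetScan-style scan: every reverse-complement seed occurrence.

    The reported position is the target start of the 7-mer facing miRNA
    positions 8..2; the site is an 8mer when the next target base (facing
    position 1) is an A.  For circRNAs pass the doubled sequence via
    :func:`scan_circular` instead.
    """
    rc_seed = revcomp(seed_of(mirna))
    sites = []
    for p in _find_all(target_seq, rc_seed):
        is_8mer = p + 7 < len(target_seq) and target_seq[p + 7] == "A"
        sites.append(
            TargetSite(mirna.mirna_id, target_id, target_kind, p,
                       "8mer" if is_8mer else "7mer-m8", "seedmatch")
        )
    return sites


def duplex_align(mirna: MiRNA | str, window: str, mirna_id: str = "",
                 target_id: str = "") -> DuplexAlignment:
    """Best local duplex of the miRNA against a target window (Gotoh DP).

    The miRNA is threaded antiparallel: its 5' end pairs the 3' side of the
    window.  Local semantics: the alignment starts and ends on an aligned
    pair (terminal gaps are never counted).  Gap states may follow one
    another on either strand; each maximal per-side run pays open once and
    extend per extra position.
    """
    if isinstance(mirna, MiRNA):
        seq, mirna_id = mirna.seq, mirna.mirna_id
    else:
        seq = mirna
    mr = seq[::-1]  # mr[k] is miRNA position len-k (1-based)
    m, n = len(mr), len(window)
    NEG = float("-inf")
    # states: M ends on a pair, X gap in target (miRNA base skipped),
    # Y gap in miRNA (target base skipped)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    back: dict[tuple[str, int, int], tuple[str, int, int] | None] = {}
    best, best_cell = 0.0, None
    for i in range(1, m + 1):
        pos = m - (i - 1)  # original miRNA position, 1-based
        for j in range(1, n + 1):
            s = pair_score(mr[i - 1], window[j - 1], pos)
            opts = [(0.0, None), (M[i - 1][j - 1], ("M", i - 1, j - 1)),
                    (X[i - 1][j - 1], ("X", i - 1, j - 1)),
                    (Y[i - 1][j - 1], ("Y", i - 1, j - 1))]
            val, prev = max(opts, key=lambda t: t[0])
            M[i][j] = val + s
            back[("M", i, j)] = prev
            xo = [(M[i - 1][j] + GAP_OPEN, ("M", i - 1, j)),
                  (X[i - 1][j] + GAP_EXTEND, ("X", i - 1, j)),
                  (Y[i - 1][j] + GAP_OPEN, ("Y", i - 1, j))]
            X[i][j], back[("X", i, j)] = max(xo, key=lambda t: t[0])
            yo = [(M[i][j - 1] + GAP_OPEN, ("M", i, j - 1)),
                  (Y[i][j - 1] + GAP_EXTEND, ("Y", i, j - 1)),
                  (X[i][j - 1] + GAP_OPEN, ("X", i, j - 1))]
            Y[i][j], back[("Y", i, j)] = max(yo, key=lambda t: t[0])
            if M[i][j] > best:
                best, best_cell = M[i][j], ("M", i, j)

    pairs: list[tuple[int, int, str]] = []
    offset = 0
    if best_cell is not None:
        cell = best_cell
        while cell is not None:
            state, i, j = cell
            if state == "M":
                pos = m - (i - 1)
                pairs.append((pos, j - 1, pair_state(mr[i - 1], window[j - 1])))
                offset = j - 1
            cell = back.get(cell)
        pairs.reverse()
    energy = sum(pair_energy(seq[pos - 1], window[tp]) for pos, tp, st in pairs
                 if st in ("WC", "GU"))
    seed_strict = _seed_is_strict(pairs, len(seq))
    return DuplexAlignment(mirna_id, target_id, offset, pairs, best, energy,
                           seed_strict)


def _seed_is_strict(pairs: list[tuple[int, int, str]], mirna_len: int) -> bool:
    """Seed positions 2-8 all WC-paired, contiguous on the target (no gaps)."""
    seed_pairs = sorted((p, t) for p, t, st in pairs
                        if p in SEED_POSITIONS and st == "WC")
    if len({p for p, _ in seed_pairs}) != len(SEED_POSITIONS):
        return False
    tpos = [t for _, t in seed_pairs]
    # antiparallel: rising miRNA position must step down the target by 1
    return all(b == a - 1 for a, b in zip(tpos, tpos[1:]))


def align_at_seed_sites(mirna: MiRNA, target_seq: str, target_id: str,
                        pad: int = 10) -> list[tuple[int, DuplexAlignment]]:
    """Duplex alignments in windows around each seed-complement occurrence.

    A strict-seed site necessarily contains the reverse complement of the
    seed as a literal 7-mer, so anchoring the alignment windows on those
    occurrences loses no reportable site.  Returns (seed position, duplex).
    """
    rc_seed = revcomp(seed_of(mirna))
    out = []
    for p in _find_all(target_seq, rc_seed):
        lo = max(0, p + 8 - len(mirna.seq) - pad)
        hi = min(len(target_seq), p + 8 + pad)
        out.append((p, duplex_align(mirna, target_seq[lo:hi], target_id=target_id)))
    return out


def predict_miranda(mirnas: list[MiRNA], targets: dict[str, str],
                    target_kind: str = "utr3",
                    score_thr: float = SCORE_THRESHOLD,
                    energy_thr: float = ENERGY_THRESHOLD) -> list[TargetSite]:
    """miRanda-like sites: score >= threshold, energy <= threshold, strict seed."""
    sites = []
    for mirna in mirnas:
        for tid, seq in targets.items():
            L = len(seq)
            if target_kind == "circ":
                # windows are cut in the middle copy of a tripled sequence so
                # junction-crossing sites have full context on both sides;
                # positions are reported modulo the circle length
                pad = len(mirna.seq) + 10
                scan_seq = seq + seq + seq[:pad]
                rc_seed = revcomp(seed_of(mirna))
                anchors = [p + L for p in _find_all(seq + seq[:6], rc_seed)
                           if p < L]
            else:
                scan_seq = seq
                anchors = _find_all(seq, revcomp(seed_of(mirna)))
            seen = set()
            for p in anchors:
                pos = p % L if target_kind == "circ" else p
                if pos in seen:
                    continue
                lo = max(0, p + 8 - len(mirna.seq) - 10)
                hi = min(len(scan_seq), p + 8 + 10)
                dup = duplex_align(mirna, scan_seq[lo:hi], target_id=tid)
                if dup.score >= score_thr and dup.energy <= energy_thr and dup.seed_strict:
                    seen.add(pos)
                    is_8mer = _faces_adenine(scan_seq, p)
                    sites.append(TargetSite(
                        mirna.mirna_id, tid, target_kind, pos,
                        "8mer" if is_8mer else "7mer-m8", "miranda",
                        dup.score, dup.energy,
                    ))
    return sites


def predict_seedmatch(mirnas: list[MiRNA], targets: dict[str, str],
                      target_kind: str = "utr3") -> list[TargetSite]:
    """Seed-scan sites over all (miRNA, target) pairs."""
    sites = []
    for mirna in mirnas:
        for tid, seq in targets.items():
            scan_seq, L = _scannable(seq, target_kind, len(mirna.seq))
            for site in seedmatch_scan(mirna, scan_seq, tid, target_kind):
                if target_kind == "circ":
                    if site.position >= L:
                        continue
                    site.position %= L
                sites.append(site)
    return sites


def _scannable(seq: str, kind: str, mirna_len: int) -> tuple[str, int]:
    """For circles, expose the junction by doubling (bounded overhang)."""
    if kind == "circ":
        return seq + seq[: mirna_len + 8], len(seq)
    return seq, len(seq)


def _faces_adenine(seq: str, p: int) -> bool:
    return p + 7 < len(seq) and seq[p + 7] == "A"


def site_pairs(sites: list[TargetSite]) -> set[tuple[str, str]]:
    return {(s.mirna_id, s.target_id) for s in sites}


def intersect_predictions(miranda_sites: list[TargetSite],
                          seedmatch_sites: list[TargetSite]) -> list[TargetSite]:
    """Pair-level intersection: a (miRNA, target) pair survives iff both
    predictors report at least one site for it.  Surviving sites (the
    miRanda ones, which carry score and energy) are tagged source='both'."""
    keep = site_pairs(miranda_sites) & site_pairs(seedmatch_sites)
    out = []
    for s in miranda_sites:
        if (s.mirna_id, s.target_id) in keep:
            out.append(TargetSite(s.mirna_id, s.target_id, s.target_kind,
                                  s.position, s.site_type, "both",
                                  s.score, s.energy))
    return out
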
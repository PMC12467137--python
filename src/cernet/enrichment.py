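"""Hypergeometric over-representation analysis against a user-supplied term map.

Stands in for GO/KEGG enrichment of DEcircRNA source genes and DEmiRNA
target genes: for each term with K members in a universe of N genes and a
study set of n genes hitting k members, the p-value is the upper
hypergeometric tail P(X >= k).  Raw p-values are Benjamini-Hochberg
adjusted across tested terms; significance defaults to adjusted p < 0.05
(``use_adjusted=False`` applies the cutoff to raw p instead).
"""
from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    study_genes: set[str] | list[str],
    universe: set[str] | list[str],
    term_map: dict[str, tuple[str, set[str]]],
    alpha: float = ALPHA,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Over-representation of the study set in each term of the map.

    ``term_map`` maps term_id -> (term_name, member gene ids), as read from
    a GMT file.  Terms with no member in the universe are skipped.  Rows
    are ordered by (p, term_id) for determinism.
    """
    study = set(study_genes)
    uni = set(universe)
    if not study:
        raise ValueError("study gene set is empty")
    if not study <= uni:
        raise ValueError("study genes must be a subset of the universe")
    N, n = len(uni), len(study)
    rows = []
    for term_id, (term_name, members) in term_map.items():
        members_in = members & uni
        if not members_in:
            continue
        K = len(members_in)
        k = len(members_in & study)
        rows.append({
            "term_id": term_id,
            "term_name": term_name,
            "k": k, "K": K, "n": n, "N": N,
            "p": hypergeom_upper_tail(k, N, K, n),
        })
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p",
                     "p_adj", "significant"])
    res = pd.DataFrame(rows)
    res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
    which = "p_adj" if use_adjusted else "p"
    res["significant"] = res[which] < alpha
    return res.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
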
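"""Normalization and two-group NB differential expression.

circRNA counts are scaled to reads per million mapped reads (RPM); miRNA
counts to a per-million scale over counted miRNAs (their near-constant
mature length makes a length term superfluous).  Differential expression
between control (C) and grazing (G) groups is a negative-binomial Wald
test: median-of-ratios size factors, method-of-moments dispersion, and a
Wald statistic on the log difference of group means referred to a t
distribution with n1+n2-2 degrees of freedom.
Features are called up/down at |log2FC| >= 1 (inclusive) and p < 0.05
(strict), on raw p-values; a Benjamini-Hochberg column is reported for
information only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    method: str  # RPM | TPM

    def __post_init__(self) -> None:
        if self.method not in ("RPM", "TPM"):
            raise ValueError(f"unknown normalization {self.method!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized values must be >= 0")


def rpm(cm: CountMatrix) -> NormalizedMatrix:
    """Reads per million mapped reads: count / mapped_total * 1e6."""
    totals = cm.mapped_totals.reindex(cm.counts.columns)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero mapped-read total for sample(s) {bad}")
    return NormalizedMatrix(cm.counts / totals * 1e6, "RPM")


def tpm_mirna(cm: CountMatrix) -> NormalizedMatrix:
    """Per-million scaling over counted miRNAs (columns sum to 1e6)."""
    colsums = cm.counts.sum(axis=0)
    if (colsums == 0).any():
        bad = colsums.index[colsums == 0].tolist()
        raise ValueError(f"all-zero sample(s) {bad}")
    return NormalizedMatrix(cm.counts / colsums * 1e6, "TPM")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = geometric mean row)."""
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    usable = np.isfinite(log_arr).all(axis=1)
    if not usable.any():
        # no feature counted in every sample: fall back on library-size ratios
        libs = arr.sum(axis=0)
        sf = libs / np.exp(np.mean(np.log(libs)))
        return pd.Series(sf, index=counts.columns)
    log_ref = log_arr[usable].mean(axis=1)
    sf = np.exp(np.median(log_arr[usable] - log_ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def _mom_dispersion(norm: np.ndarray, idx_c: np.ndarray, idx_g: np.ndarray) -> np.ndarray:
    """Per-feature pooled method-of-moments NB dispersion, floored."""
    mc, mg = norm[:, idx_c].mean(axis=1), norm[:, idx_g].mean(axis=1)
    vc = norm[:, idx_c].var(axis=1, ddof=1)
    vg = norm[:, idx_g].var(axis=1, ddof=1)
    # pool within-group excess variance over the two groups
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (vc - mc) + (vg - mg)
        den = mc**2 + mg**2
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def de_test(cm: CountMatrix) -> pd.DataFrame:
    """NB Wald test of group G vs group C for every feature.

    Returns a frame with baseMeanC/baseMeanG (size-factor normalized group
    means), log2fc, p, p_adj (BH, informational) and the regulated label.
    Features with zero counts in all samples get p = 1, log2fc = 0.
    """
    samples = list(cm.counts.columns)
    group = np.array([cm.groups[s] for s in samples])
    idx_c = np.flatnonzero(group == "C")
    idx_g = np.flatnonzero(group == "G")
    if min(len(idx_c), len(idx_g)) < 2:
        raise ValueError("need >= 2 samples per group")

    sf = size_factors(cm.counts).to_numpy()
    norm = cm.counts.to_numpy(dtype=float) / sf
    mc = norm[:, idx_c].mean(axis=1)
    mg = norm[:, idx_g].mean(axis=1)
    alpha = _mom_dispersion(norm, idx_c, idx_g)

    log2fc = np.log2((mg + PSEUDOCOUNT) / (mc + PSEUDOCOUNT))

    # Var(log mean_g) ~ Var(mean_g) / mean_g^2 with
    # Var(mean_g) = (m * sum(1/sf_i) + alpha * m^2 * n) / n^2
    def _var_log(m: np.ndarray, idx: np.ndarray) -> np.ndarray:
        n = len(idx)
        inv_sf = np.sum(1.0 / sf[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(m > 0, inv_sf / (n**2 * m) + alpha / n, np.inf)

    var = _var_log(mc, idx_c) + _var_log(mg, idx_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var < np.inf, (np.log(mg + PSEUDOCOUNT) - np.log(mc + PSEUDOCOUNT))
                     / np.sqrt(var), 0.0)
    # t reference with n1+n2-2 df: the plug-in dispersion makes the plain
    # normal reference anticonservative at n=5 per group
    p = 2.0 * stats.t.sf(np.abs(z), df=len(idx_c) + len(idx_g) - 2)

    allzero = (cm.counts.to_numpy() == 0).all(axis=1)
    log2fc[allzero] = 0.0
    p[allzero] = 1.0
    p = np.clip(p, 0.0, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]

    res = pd.DataFrame(
        {
            "baseMeanC": mc,
            "baseMeanG": mg,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
        },
        index=cm.counts.index.rename("feature_id"),
    )
    return call_de(res)


def call_de(results: pd.DataFrame, lfc_thr: float = 1.0, p_thr: float = 0.05
            ) -> pd.DataFrame:
    """Label up/down/ns: |log2fc| >= lfc_thr (inclusive), p < p_thr (strict)."""
    if lfc_thr <= 0 or p_thr <= 0:
        raise ValueError("thresholds must be > 0")
    res = results.copy()
    sig = res["p"] < p_thr
    res["regulated"] = np.where(
        sig & (res["log2fc"] >= lfc_thr), "up",
        np.where(sig & (res["log2fc"] <= -lfc_thr), "down", "ns"),
    )
    return res


def de_summary(results: pd.DataFrame) -> dict[str, int]:
    reg = results["regulated"]
    return {"n_up": int((reg == "up").sum()), "n_down": int((reg == "down").sum())}
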
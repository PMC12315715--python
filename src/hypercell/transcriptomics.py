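"""Count-matrix QC, CPM, signed-KS differential expression, exon usage.

Count matrices are pandas DataFrames with features on the rows (gene
symbols, or ``gene:exonIndex`` keys at exon level) and cells on the
columns.  Differential expression between two cell groups uses the
two-sample Kolmogorov–Smirnov statistic with a sign attached from the
direction of the between-group difference, the convention used for
volcano-style plots of full-length single-cell RNA-seq data.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "qc_metrics",
    "filter_genes",
    "cpm_normalize",
    "read_counts_tsv",
    "write_counts_tsv",
    "signed_ks_de",
    "bh_adjust",
    "exon_usage",
    "parse_exon_key",
]

MT_THRESHOLD_DEFAULT = 0.25
MIN_CELLS_DEFAULT = 10
CPM_SCALE = 1_000_000.0

#: above comb(n+m, n) combinations the exact KS permutation null is not
#: enumerated and the asymptotic two-sided distribution is used instead
EXACT_KS_MAX_COMB = 20_000


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a features x cells count table (first column = feature key)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def qc_metrics(
    counts: pd.DataFrame,
    mt_prefix: str = "MT-",
    ribo_prefixes: tuple[str, ...] = ("RPS", "RPL"),
    mt_threshold: float = MT_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Per-cell QC: totals, detected genes, MT/ribosomal fractions, MT class.

    A cell is MT-high when its mitochondrial read fraction exceeds
    ``mt_threshold`` (default 25%), a low-viability indicator; otherwise
    MT-low.  Cells with zero total reads get NaN fractions and are flagged.
    """
    totals = counts.sum(axis=0)
    n_genes = (counts > 0).sum(axis=0)
    is_mt = counts.index.str.startswith(mt_prefix)
    is_ribo = counts.index.str.startswith(ribo_prefixes)
    mt_frac = counts.loc[is_mt].sum(axis=0) / totals.replace(0, np.nan)
    ribo_frac = counts.loc[is_ribo].sum(axis=0) / totals.replace(0, np.nan)
    mt_frac = mt_frac.fillna(0.0).where(totals > 0, np.nan)
    ribo_frac = ribo_frac.fillna(0.0).where(totals > 0, np.nan)
    qc = pd.DataFrame(
        {
            "total_reads": totals,
            "n_genes_detected": n_genes,
            "mt_fraction": mt_frac,
            "ribo_fraction": ribo_frac,
        }
    )
    qc["mt_class"] = np.where(qc["mt_fraction"] > mt_threshold, "MT-high", "MT-low")
    qc.loc[qc["mt_fraction"].isna(), "mt_class"] = "undefined"
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} cell(s) with zero total reads", stacklevel=2
        )
    return qc


def filter_genes(counts: pd.DataFrame, min_cells: int = MIN_CELLS_DEFAULT) -> pd.DataFrame:
    """Keep features detected (count > 0) in at least ``min_cells`` cells."""
    keep = (counts > 0).sum(axis=1) >= min_cells
    return counts.loc[keep]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each cell's column scaled to sum to 1e6.

    Cells with zero total reads are dropped with a warning.
    """
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} zero-total cell(s): {list(counts.columns[zero])}",
            stacklevel=2,
        )
        counts = counts.loc[:, ~zero]
        totals = totals[~zero]
    return counts / totals * CPM_SCALE


def _ks_d(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic sup|ECDF_a - ECDF_b| on pooled values."""
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
    return float(np.abs(cdf_a - cdf_b).max())


def _ks_pvalue(a: np.ndarray, b: np.ndarray, d: float) -> float:
    """Two-sided p for the KS D: exact label-permutation when the number of
    group assignments is enumerable, asymptotic Kolmogorov otherwise."""
    n, m = len(a), len(b)
    if math.comb(n + m, n) <= EXACT_KS_MAX_COMB:
        pooled = np.concatenate([a, b])
        idx = np.arange(n + m)
        total = 0
        exceed = 0
        for comb in itertools.combinations(idx, n):
            sel = np.zeros(n + m, dtype=bool)
            sel[list(comb)] = True
            d_perm = _ks_d(pooled[sel], pooled[~sel])
            total += 1
            if d_perm >= d - 1e-12:
                exceed += 1
        return exceed / total
    en = math.sqrt(n * m / (n + m))
    return float(np.clip(stats.kstwobign.sf(en * d), 0.0, 1.0))


def signed_ks_de(
    cpm: pd.DataFrame,
    group_a: list,
    group_b: list,
    median_filter: bool = True,
    fc_pseudocount: float = 1.0,
    sign_by: str = "mean",
) -> pd.DataFrame:
    """Signed-KS differential expression between two disjoint cell groups.

    Per gene: D = sup|ECDF_a − ECDF_b| of cpm values, signed by the
    direction of the group difference (means by default, medians via
    ``sign_by="median"``); log2 fold change of group means with a
    pseudocount; BH q-values over the genes that pass the median filter.
    Genes whose median cpm is 0 in either group are marked filtered
    (reason "zero_median") and excluded from testing and correction.

    Returns a DataFrame indexed by gene with columns log2_fc, signed_ks,
    p, q, filtered, filter_reason.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    A = cpm[group_a].to_numpy(dtype=float)
    B = cpm[group_b].to_numpy(dtype=float)
    n_genes = cpm.shape[0]
    log2_fc = np.log2((A.mean(axis=1) + fc_pseudocount) / (B.mean(axis=1) + fc_pseudocount))
    filtered = np.zeros(n_genes, dtype=bool)
    if median_filter:
        filtered = (np.median(A, axis=1) == 0) | (np.median(B, axis=1) == 0)
    signed = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)
    for g in range(n_genes):
        if filtered[g]:
            continue
        a, b = A[g], B[g]
        d = _ks_d(a, b)
        if sign_by == "mean":
            diff = a.mean() - b.mean()
        elif sign_by == "median":
            diff = np.median(a) - np.median(b)
        else:
            raise ValueError(f"unknown sign_by {sign_by!r}")
        signed[g] = d * np.sign(diff)
        pvals[g] = _ks_pvalue(a, b, d)
    qvals = np.full(n_genes, np.nan)
    tested = ~filtered
    if tested.any():
        qvals[tested] = bh_adjust(pvals[tested])
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "signed_ks": signed,
            "p": pvals,
            "q": qvals,
            "filtered": filtered,
            "filter_reason": np.where(filtered, "zero_median", ""),
        },
        index=cpm.index,
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def parse_exon_key(key: str) -> tuple[str, int]:
    """Split a ``geneID:exonIndex`` key; exon ordinals are 1-based."""
    gene, sep, exon = key.rpartition(":")
    if not sep or not gene:
        raise ValueError(f"malformed exon key {key!r} (expected 'gene:exonIndex')")
    try:
        idx = int(exon)
    except ValueError:
        raise ValueError(f"malformed exon key {key!r}: exon index {exon!r} not an integer")
    if idx < 1:
        raise ValueError(f"malformed exon key {key!r}: exon index must be >= 1")
    return gene, idx


def exon_usage(exon_counts: pd.DataFrame) -> pd.DataFrame:
    """Within-gene exon usage fractions per cell.

    usage[(g, e), c] = counts[(g, e), c] / sum over the gene's exons in
    cell c; NaN for cells where the gene has no reads.  Row keys must be
    ``gene:exonIndex``.
    """
    genes = [parse_exon_key(k)[0] for k in exon_counts.index]
    gene_totals = exon_counts.groupby(genes, sort=False).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = exon_counts / gene_totals.replace(0, np.nan)
    return usage
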
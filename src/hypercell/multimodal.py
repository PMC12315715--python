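"""Feature–expression association: Spearman correlations, binning, permutations.

These analyses connect per-cell imaging features (area, eccentricity,
channel intensities, channel ratios) to the same cells' expression or exon
usage.  They are restricted to MT-low cells by default, since MT-high
cells carry an apoptotic signature that would confound the correlations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptomics import MIN_CELLS_DEFAULT, parse_exon_key

__all__ = [
    "BinSpec",
    "feature_expression_correlation",
    "bin_cells",
    "binned_summary",
    "exon_correlation_extremes",
    "permutation_test",
]

BIN_SIZE_DEFAULT = 15
N_PERM_DEFAULT = 1000


def feature_expression_correlation(
    feature: pd.Series,
    cpm: pd.DataFrame,
    cells: list | None = None,
    min_cells: int = MIN_CELLS_DEFAULT,
) -> pd.DataFrame:
    """Spearman correlation of one per-cell feature with every gene's cpm.

    ``cells`` restricts the analysis (typically to MT-low cells); genes
    detected in fewer than ``min_cells`` of those cells are excluded.
    Ties receive average ranks; two-sided p-values use the t
    approximation.  Returns a DataFrame indexed by gene with columns rho,
    p, n.
    """
    if cells is None:
        cells = list(cpm.columns)
    cells = list(cells)
    feat = feature.loc[cells].to_numpy(dtype=float)
    if np.all(feat == feat[0]):
        raise ValueError("feature is constant over the selected cells; rho undefined")
    sub = cpm[cells]
    expressed = (sub > 0).sum(axis=1) >= min_cells
    sub = sub.loc[expressed]
    rows = []
    for gene, values in sub.iterrows():
        rho, p = stats.spearmanr(feat, values.to_numpy(dtype=float))
        rows.append((gene, rho, p, len(cells)))
    return pd.DataFrame(rows, columns=["gene", "rho", "p", "n"]).set_index("gene")


@dataclasses.dataclass
class BinSpec:
    """Cells ordered by a feature and cut into consecutive fixed-size bins.

    All bins have ``bin_size`` cells except possibly the last, which holds
    the remainder (e.g. 117 cells at size 15 → seven bins of 15 and one of
    12)."""

    ordered_cells: list
    bin_size: int
    bin_assignments: np.ndarray

    @property
    def bin_sizes(self) -> list[int]:
        return np.bincount(self.bin_assignments).tolist()


def bin_cells(feature: pd.Series, bin_size: int = BIN_SIZE_DEFAULT) -> BinSpec:
    """Sort cells ascending by feature (ties by cell id) and bin consecutively."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    order = sorted(feature.index, key=lambda c: (feature.loc[c], str(c)))
    n = len(order)
    assignments = np.arange(n) // bin_size
    return BinSpec(ordered_cells=order, bin_size=bin_size, bin_assignments=assignments)


def binned_summary(values: pd.Series, spec: BinSpec) -> pd.DataFrame:
    """Per-bin quartiles of a per-cell value (for box-plot style summaries)."""
    v = values.loc[spec.ordered_cells].to_numpy(dtype=float)
    rows = []
    for b in range(spec.bin_assignments.max() + 1):
        chunk = v[spec.bin_assignments == b]
        rows.append(
            {
                "bin": b + 1,
                "n": len(chunk),
                "q1": float(np.nanpercentile(chunk, 25)),
                "median": float(np.nanpercentile(chunk, 50)),
                "q3": float(np.nanpercentile(chunk, 75)),
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def exon_correlation_extremes(
    usage: pd.DataFrame,
    feature: pd.Series,
    cells: list | None = None,
    min_cells: int = MIN_CELLS_DEFAULT,
) -> pd.DataFrame:
    """Per-gene extremes of exon-usage vs feature correlations.

    For each gene, every exon's usage fraction is correlated (Spearman)
    with the feature over the cells expressing the gene (usage defined);
    the minimum and maximum rho and their exon ordinals are reported.
    Genes expressed in fewer than ``min_cells`` cells, and exons with
    constant usage (e.g. single-exon genes, usage ≡ 1), are excluded.
    """
    if cells is not None:
        usage = usage[list(cells)]
        feature = feature.loc[list(cells)]
    keys = [parse_exon_key(k) for k in usage.index]
    by_gene: dict[str, list[tuple[int, str]]] = {}
    for (gene, exon), row_key in zip(keys, usage.index):
        by_gene.setdefault(gene, []).append((exon, row_key))
    rows = []
    feat_all = feature
    for gene, exons in by_gene.items():
        sub = usage.loc[[rk for _, rk in exons]]
        # usage is defined for all exons of a gene in exactly the cells
        # where the gene has reads, so any exon row's notna works
        expressing = sub.iloc[0].notna()
        cells_g = sub.columns[expressing]
        if len(cells_g) < min_cells:
            continue
        feat = feat_all.loc[cells_g].to_numpy(dtype=float)
        best: list[tuple[float, int]] = []
        for exon, rk in exons:
            u = sub.loc[rk, cells_g].to_numpy(dtype=float)
            if np.all(u == u[0]):
                continue  # constant usage, rho undefined
            rho, _ = stats.spearmanr(feat, u)
            if np.isnan(rho):
                continue
            best.append((float(rho), exon))
        if not best:
            continue
        min_rho, argmin_exon = min(best)
        max_rho, argmax_exon = max(best)
        rows.append(
            {
                "gene": gene,
                "min_rho": min_rho,
                "max_rho": max_rho,
                "argmin_exon": argmin_exon,
                "argmax_exon": argmax_exon,
                "n_cells": int(len(cells_g)),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "min_rho", "max_rho", "argmin_exon", "argmax_exon", "n_cells"]).set_index("gene")


def permutation_test(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    statistic: str = "mean_difference",
    n_perm: int = N_PERM_DEFAULT,
    seed: int | None = None,
) -> dict:
    """Label-shuffle permutation test for a two-group difference.

    The default statistic is |mean(group 1) − mean(group 2)|.  Labels are
    shuffled ``n_perm`` times; ``exceed_count`` is the number of shuffles
    whose statistic strictly exceeds the observed one, and the empirical
    p-value is (exceed_count + 1) / (n_perm + 1).  The raw exceed count is
    reported alongside ("0 out of 1000"-style statements use it directly).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic != "mean_difference":
        raise ValueError(f"unknown statistic {statistic!r}")
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two groups")
    mask = lab == uniq[0]
    if mask.all() or not mask.any():
        raise ValueError("both groups must be nonempty")

    def stat(m: np.ndarray) -> float:
        return abs(v[m].mean() - v[~m].mean())

    observed = stat(mask)
    rng = np.random.default_rng(seed)
    exceed = 0
    n1 = int(mask.sum())
    n = len(v)
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n1, replace=False)] = True
        if stat(perm) > observed:
            exceed += 1
    result = {
        "observed": observed,
        "exceed_count": exceed,
        "empirical_p": (exceed + 1) / (n_perm + 1),
        "n_perm": n_perm,
        "degenerate": bool(observed == 0),
    }
    return result
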
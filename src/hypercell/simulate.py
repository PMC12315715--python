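"""Seeded generators for hyperspectral fields and count matrices with truth.

Every pipeline stage is validated against data with a known, recoverable
ground truth: disk-shaped cells from two spectral populations on a noisy
background (some with a bright membrane ring in one channel), and
negative-binomial count matrices whose gene ranks are coupled to a
per-cell feature through a Gaussian copula at a chosen Spearman rho.

All randomness flows from one spec-level seed through named substreams
(placement, brightness, noise, counts, ...) so partial re-runs are stable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .channels import ChannelTable, HyperspectralStack, default_channel_table

__all__ = ["ImageSimSpec", "CountsSimSpec", "simulate_field", "simulate_counts", "MT_GENES"]

#: human mitochondrial protein-coding gene symbols used for MT reads
MT_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP6", "MT-ATP8", "MT-CO3",
    "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6", "MT-CYB",
)


@dataclasses.dataclass
class ImageSimSpec:
    """Conditions for one simulated 15-channel field of view.

    Cells are non-overlapping disks at least 2 px from the field edge.
    Population brightness vectors are per-channel intensities *added* to
    the flat background (default populations differ mainly in channels 3
    and 13, mirroring the blue- vs red-emitting contrast that separates
    the two spectral groups).  For ringed cells, every pixel within
    ``ring_thickness`` of the cell boundary in ``ring_channel`` is
    multiplied by 2**ring_log2fc.
    """

    field_size: int = 320
    n_cells: int = 20
    radius_range: tuple[int, int] = (12, 18)
    ring_fraction: float = 0.34
    ring_channel: int = 13
    ring_log2fc: float = 1.0
    ring_thickness: float = 10.0
    background: float = 30.0
    noise_sigma: float = 1.0
    population_brightness: np.ndarray | None = None  # (n_pops, n_channels)
    population_fractions: tuple[float, ...] = (0.5, 0.5)
    brightness_jitter: float = 0.05
    seed: int = 0
    channel_table: ChannelTable | None = None


def _default_brightness(n_channels: int) -> np.ndarray:
    """Two populations: common lift of 20 counts over background, one
    population brighter in channel 3, the other in channel 13."""
    base = np.full(n_channels, 20.0)
    pop1 = base.copy()
    pop1[2] += 25.0  # channel 3
    pop2 = base.copy()
    pop2[12] += 25.0  # channel 13
    return np.stack([pop1, pop2])


def simulate_field(spec: ImageSimSpec) -> tuple[HyperspectralStack, np.ndarray, pd.DataFrame]:
    """Render one field: (raw stack, truth label image, truth table).

    The truth table (indexed by cell_id, which equals the label in the
    truth label image, assigned in raster order of the cells' bounding
    boxes) records population, ringed flag, radius and center.
    Deterministic for a fixed spec.
    """
    table = spec.channel_table or default_channel_table()
    n_ch = len(table)
    brightness = (
        _default_brightness(n_ch)
        if spec.population_brightness is None
        else np.asarray(spec.population_brightness, dtype=float)
    )
    n_pops = brightness.shape[0]
    fractions = np.asarray(spec.population_fractions, dtype=float)
    if len(fractions) != n_pops or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("population_fractions must match brightness rows and sum to 1")
    if not 0 <= spec.ring_fraction <= 1:
        raise ValueError("ring_fraction must be in [0, 1]")

    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_place = np.random.default_rng(streams[0])
    rng_assign = np.random.default_rng(streams[1])
    rng_bright = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])

    size = spec.field_size
    r_lo, r_hi = spec.radius_range
    placed: list[tuple[float, float, int]] = []  # (row, col, radius)
    attempts = 0
    max_attempts = 200 * spec.n_cells
    while len(placed) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {spec.n_cells} non-overlapping cells of radius "
                f"{spec.radius_range} in a {size}x{size} field after {max_attempts} tries"
            )
        r = int(rng_place.integers(r_lo, r_hi + 1))
        margin = r + 2
        row = rng_place.uniform(margin, size - margin)
        col = rng_place.uniform(margin, size - margin)
        if all(np.hypot(row - p[0], col - p[1]) >= r + p[2] + 3 for p in placed):
            placed.append((row, col, r))

    # label cells in raster order of their first pixel in a row-major scan,
    # the same rule the fallback segmenter uses, so labels line up
    def first_pixel(row: float, col: float, r: int) -> tuple[int, int]:
        r0 = int(np.ceil(row - r))
        half = np.sqrt(max(r**2 - (r0 - row) ** 2, 0.0))
        return r0, int(np.ceil(col - half))

    placed.sort(key=lambda p: first_pixel(*p))

    populations = rng_assign.choice(n_pops, size=spec.n_cells, p=fractions)
    ringed = rng_assign.random(spec.n_cells) < spec.ring_fraction

    pixels = np.full((n_ch, size, size), spec.background, dtype=float)
    labels = np.zeros((size, size), dtype=np.int32)
    rows_grid, cols_grid = np.mgrid[0:size, 0:size]
    ring_idx = table.index(spec.ring_channel)
    records = []
    for i, (row, col, r) in enumerate(placed):
        cell_id = i + 1
        disk = (rows_grid - row) ** 2 + (cols_grid - col) ** 2 <= r**2
        labels[disk] = cell_id
        jitter = rng_bright.lognormal(mean=0.0, sigma=spec.brightness_jitter)
        for c in range(n_ch):
            pixels[c][disk] = spec.background + brightness[populations[i], c] * jitter
        if ringed[i]:
            dist = ndimage.distance_transform_edt(disk)
            border = disk & (dist <= spec.ring_thickness)
            pixels[ring_idx][border] *= 2.0**spec.ring_log2fc
        records.append(
            {
                "cell_id": cell_id,
                "population": int(populations[i]) + 1,
                "ringed": bool(ringed[i]),
                "radius": r,
                "center_row": row,
                "center_col": col,
            }
        )
    pixels += rng_noise.normal(0.0, spec.noise_sigma, size=pixels.shape)
    np.clip(pixels, 0.0, None, out=pixels)
    stack = HyperspectralStack(pixels, table, normalized=False)
    truth = pd.DataFrame(records).set_index("cell_id")
    return stack, labels, truth


@dataclasses.dataclass
class CountsSimSpec:
    """Conditions for a simulated gene + exon count matrix.

    ``planted_rho`` couples named genes' expression ranks to the supplied
    per-cell feature at a target Spearman rho through a Gaussian copula;
    planted genes draw well-expressed NB marginals (mean in
    ``planted_mean_range``) so rank ties do not attenuate the coupling.
    ``planted_log2fc`` shifts named genes' NB means by 2**fc in the cells
    whose ``group_labels`` entry is truthy (for membrane-ring marker
    genes).  ``exon_genes`` maps gene name -> exon count; usage
    probabilities of planted (gene, exon, direction) gradients shift
    monotonically along the feature.  MT- reads are added on top of the
    nuclear genes to hit each cell's drawn mitochondrial fraction in
    expectation.
    """

    n_cells: int = 117
    n_genes: int = 300
    nb_mean_range: tuple[float, float] = (2.0, 150.0)
    planted_mean_range: tuple[float, float] = (50.0, 200.0)
    nb_dispersion: float = 3.0  # NB size parameter; var = mu + mu^2/size
    mt_fraction_range: tuple[float, float] = (0.02, 0.20)
    mt_high_fraction: float = 0.0
    mt_high_range: tuple[float, float] = (0.30, 0.60)
    mt_high_labels: np.ndarray | None = None  # per-cell override of the random draw
    planted_rho: dict[str, float] = dataclasses.field(default_factory=dict)
    planted_log2fc: dict[str, float] = dataclasses.field(default_factory=dict)
    group_labels: np.ndarray | None = None
    exon_genes: dict[str, int] = dataclasses.field(default_factory=dict)
    planted_exon_gradients: tuple[tuple[str, int, int], ...] = ()
    exon_gradient_strength: float = 2.0
    seed: int = 0

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]


def _nb_ppf(u: np.ndarray, mean: float, size: float) -> np.ndarray:
    p = size / (size + mean)
    return stats.nbinom.ppf(u, size, p)


def simulate_counts(
    spec: CountsSimSpec, features: pd.Series | np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Draw (gene counts, exon counts, truth tables) for one cohort.

    ``features`` is the per-cell covariate (e.g. cell area) the copula and
    the exon-usage gradients are tied to; its length fixes the cohort and
    must equal ``spec.n_cells``.  Cells are named C001..C{n}; the returned
    truth dict has "genes", "cells" and "exons" tables.
    """
    feat = np.asarray(features, dtype=float)
    if len(feat) != spec.n_cells:
        raise ValueError(f"features has {len(feat)} cells, spec.n_cells is {spec.n_cells}")
    for rho in spec.planted_rho.values():
        if not -1 < rho < 1:
            raise ValueError("planted Spearman targets must lie in (-1, 1)")
    n = spec.n_cells
    cells = [f"C{i:03d}" for i in range(1, n + 1)]
    genes = spec.gene_names()
    unknown = (set(spec.planted_rho) | set(spec.planted_log2fc) | set(spec.exon_genes)) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in the gene set: {sorted(unknown)}")

    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_marg = np.random.default_rng(streams[0])
    rng_cop = np.random.default_rng(streams[1])
    rng_mt = np.random.default_rng(streams[2])
    rng_exon = np.random.default_rng(streams[3])

    # rank-transform the feature to a latent normal score
    ranks = stats.rankdata(feat, method="average")
    z_feat = stats.norm.ppf(ranks / (n + 1))

    lo, hi = spec.nb_mean_range
    means = np.exp(rng_marg.uniform(np.log(lo), np.log(hi), size=spec.n_genes))
    plo, phi = spec.planted_mean_range
    gene_rows = np.empty((spec.n_genes, n))
    truth_rows = []
    group = (
        np.asarray(spec.group_labels, dtype=bool)
        if spec.group_labels is not None
        else np.zeros(n, dtype=bool)
    )
    for gi, gene in enumerate(genes):
        rho = spec.planted_rho.get(gene, 0.0)
        mu = means[gi]
        if gene in spec.planted_rho:
            mu = np.exp(rng_marg.uniform(np.log(plo), np.log(phi)))
        # Gaussian-copula latent: Pearson r that induces the target Spearman rho
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        eps = rng_cop.normal(size=n)
        z = r * z_feat + np.sqrt(1.0 - r**2) * eps
        u = stats.norm.cdf(z)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        fc = spec.planted_log2fc.get(gene)
        if fc is None:
            counts = _nb_ppf(u, mu, spec.nb_dispersion)
        else:
            counts = np.empty(n)
            counts[group] = _nb_ppf(u[group], mu * 2.0**fc, spec.nb_dispersion)
            counts[~group] = _nb_ppf(u[~group], mu, spec.nb_dispersion)
        gene_rows[gi] = counts
        truth_rows.append(
            {"gene": gene, "planted_rho": rho, "nb_mean": mu,
             "planted_log2fc": fc if fc is not None else 0.0}
        )

    gene_df = pd.DataFrame(gene_rows, index=genes, columns=cells).astype(np.int64)

    # mitochondrial reads on top of the nuclear counts
    if spec.mt_high_labels is not None:
        is_high = np.asarray(spec.mt_high_labels, dtype=bool)
        if len(is_high) != n:
            raise ValueError("mt_high_labels length must equal n_cells")
    else:
        is_high = rng_mt.random(n) < spec.mt_high_fraction
    f_lo = rng_mt.uniform(*spec.mt_fraction_range, size=n)
    f_hi = rng_mt.uniform(*spec.mt_high_range, size=n)
    mt_target = np.where(is_high, f_hi, f_lo)
    if np.any(mt_target >= 1):
        raise ValueError("mitochondrial fraction targets must be < 1")
    nuclear_totals = gene_df.sum(axis=0).to_numpy()
    mt_totals = rng_mt.poisson(nuclear_totals * mt_target / (1.0 - mt_target))
    mt_props = rng_mt.dirichlet(np.full(len(MT_GENES), 5.0))
    mt_counts = np.stack([rng_mt.multinomial(t, mt_props) for t in mt_totals], axis=1)
    mt_df = pd.DataFrame(mt_counts, index=list(MT_GENES), columns=cells)
    gene_df = pd.concat([gene_df, mt_df])

    # exon-level counts: multinomial split of each exon gene's reads
    grad = {(g, e): d for g, e, d in spec.planted_exon_gradients}
    u_feat = (ranks - 0.5) / n  # in (0, 1), monotone in the feature
    exon_rows = {}
    exon_truth = []
    for gene, n_ex in spec.exon_genes.items():
        base = rng_exon.dirichlet(np.full(n_ex, 5.0))
        logit = np.log(base)[:, None] * np.ones((1, n))
        for e in range(1, n_ex + 1):
            d = grad.get((gene, e), 0)
            if d:
                logit[e - 1] += spec.exon_gradient_strength * d * (u_feat - 0.5) * 2.0
            exon_truth.append({"gene": gene, "exon": e, "direction": d})
        probs = np.exp(logit)
        probs /= probs.sum(axis=0, keepdims=True)
        totals = gene_df.loc[gene].to_numpy()
        draws = np.stack(
            [rng_exon.multinomial(totals[c], probs[:, c]) for c in range(n)], axis=1
        )
        for e in range(1, n_ex + 1):
            exon_rows[f"{gene}:{e}"] = draws[e - 1]
    exon_df = pd.DataFrame(exon_rows, index=cells).T.astype(np.int64)

    truth = {
        "genes": pd.DataFrame(truth_rows).set_index("gene"),
        "cells": pd.DataFrame(
            {"cell_id": cells, "feature": feat, "mt_target": mt_target,
             "mt_high": is_high, "group": group},
        ).set_index("cell_id"),
        "exons": pd.DataFrame(exon_truth, columns=["gene", "exon", "direction"]),
    }
    return gene_df, exon_df, truth
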
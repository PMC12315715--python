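"""PCA of spectral fingerprints and density-based gating of the score plane.

The cells x 15-channel fingerprint matrix is decomposed by SVD after
column centering.  Squared loadings attribute variance to channels, the
largest gap in the explained-variance spectrum selects the number of
components to keep (two, in practice), and a 2-D Gaussian KDE thresholded
at a fixed density level splits the (PC1, PC2) plane into spectral groups.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from skimage.measure import label as cc_label

__all__ = [
    "PCAResult",
    "GateResult",
    "fit_spectral_pca",
    "squared_loadings",
    "select_components",
    "kde_gate",
]

GATE_LEVEL_DEFAULT = 0.18


@dataclasses.dataclass
class PCAResult:
    """scores: cells x K; loadings: channels x K (orthonormal columns);
    explained_variance_ratio: K-vector summing to 1; column_means: channel
    means removed before the SVD; n_selected: gap-selected component count."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray | None
    n_selected: int


@dataclasses.dataclass
class GateResult:
    """Per-cell spectral-group labels from the KDE super-level set.

    group_label holds 1 or 2 (0 = unassigned never occurs: cells outside
    every region fall back to the nearest region centroid)."""

    group_label: np.ndarray
    density_level: float
    kde_bandwidth: str | float
    n_regions: int


def fit_spectral_pca(features: np.ndarray, standardize: bool = False) -> PCAResult:
    """SVD-based PCA of a cells x channels matrix.

    Columns are mean-centered (and scaled to unit variance iff
    ``standardize``).  Sign convention: in every loading column the entry
    of largest magnitude is positive, which pins down the otherwise
    arbitrary component signs across linear-algebra backends.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 cells")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing/non-finite values in feature matrix")
    means = X.mean(axis=0)
    Xc = X - means
    scales = None
    if standardize:
        scales = Xc.std(axis=0, ddof=1)
        if np.any(scales == 0):
            bad = np.nonzero(scales == 0)[0]
            raise ValueError(f"zero-variance columns {bad.tolist()} cannot be standardized")
        Xc = Xc / scales
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|.| entry of each loading column positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    var = s**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    n_selected = _largest_relative_gap(ratio)
    return PCAResult(
        scores=U * s,
        loadings=Vt.T,
        explained_variance_ratio=ratio,
        column_means=means,
        column_scales=scales,
        n_selected=n_selected,
    )


def squared_loadings(pca: PCAResult, k: int) -> np.ndarray:
    """Squared loading of every channel on component k (1-based); sums to 1."""
    if not 1 <= k <= pca.loadings.shape[1]:
        raise ValueError(f"component {k} out of range")
    return pca.loadings[:, k - 1] ** 2


def _largest_relative_gap(ratio: np.ndarray) -> int:
    """Index j of the largest successive drop ratio[j]/ratio[j+1] (1-based).

    The relative drop locates the elbow where the variance spectrum falls
    off: (0.6, 0.3, 0.05) keeps 2 because 0.3 -> 0.05 is a sixfold drop,
    larger than the twofold drop 0.6 -> 0.3.  A zero follower counts as an
    infinite drop; the earliest one wins.
    """
    if len(ratio) < 2:
        return 1
    with np.errstate(divide="ignore"):
        drops = np.where(ratio[1:] > 0, ratio[:-1] / np.where(ratio[1:] > 0, ratio[1:], 1.0), np.inf)
    drops = np.where(ratio[:-1] == 0, 1.0, drops)  # 0/0 plateaus are no gap
    return int(np.argmax(drops)) + 1


def select_components(pca: PCAResult) -> int:
    """Number of components to keep (components 1..j up to the variance elbow)."""
    return _largest_relative_gap(pca.explained_variance_ratio)


def kde_gate(
    scores: np.ndarray,
    level: float = GATE_LEVEL_DEFAULT,
    bandwidth: str | float = "scott",
    grid_size: int = 256,
    relative: bool = False,
) -> GateResult:
    """Split cells into two spectral groups by thresholding a 2-D KDE.

    A Gaussian KDE is fitted on the (PC1, PC2) scores and evaluated on a
    ``grid_size`` x ``grid_size`` grid spanning the scores with a 5%
    margin.  Grid cells with density >= ``level`` form the super-level
    set; its two largest connected regions define the groups.  Group 1 is
    the region containing the cell with the smallest PC1 score.  Each cell
    is assigned to the region whose area contains it, otherwise to the
    nearest region centroid in score space.

    The level is a density in the KDE's own units, so the right value
    depends on the scale of the scores; the default is the published
    operating point for background-normalized fingerprints and should be
    re-tuned when the score scale differs.  With ``relative=True`` the
    threshold is instead ``level`` times the peak grid density (e.g. 0.5
    for half-maximum gating), which is invariant to the score scale.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("scores must be cells x 2")
    if S.shape[0] < 10:
        raise ValueError("need at least 10 cells to gate")
    kde = stats.gaussian_kde(S.T, bw_method=bandwidth)
    lo = S.min(axis=0)
    hi = S.max(axis=0)
    margin = 0.05 * (hi - lo)
    margin[margin == 0] = 1e-6
    gx = np.linspace(lo[0] - margin[0], hi[0] + margin[0], grid_size)
    gy = np.linspace(lo[1] - margin[1], hi[1] + margin[1], grid_size)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    density = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(grid_size, grid_size)
    threshold = level * density.max() if relative else level
    super_level = density >= threshold
    if not super_level.any():
        raise ValueError(
            f"super-level set empty at level {level}; max density is {density.max():.4g} — "
            "use a lower level"
        )
    regions = cc_label(super_level, connectivity=2)
    sizes = np.bincount(regions.ravel())
    sizes[0] = 0
    order = np.argsort(sizes)[::-1]
    keep = [int(lab) for lab in order[:2] if sizes[lab] > 0]
    n_regions = len(keep)

    # map each cell to its grid cell
    ix = np.clip(np.searchsorted(gx, S[:, 0]) - 1, 0, grid_size - 1)
    iy = np.clip(np.searchsorted(gy, S[:, 1]) - 1, 0, grid_size - 1)
    cell_region = regions[ix, iy]

    region_points = {}  # region label -> (k, 2) score-space coordinates
    for lab in keep:
        rr, cc = np.nonzero(regions == lab)
        region_points[lab] = np.column_stack([gx[rr], gy[cc]])

    assigned = np.zeros(S.shape[0], dtype=int)  # region label per cell
    for i in range(S.shape[0]):
        if cell_region[i] in keep:
            assigned[i] = cell_region[i]
        else:
            # outside every region: nearest region boundary in score space
            dists = {
                lab: float(np.min(np.linalg.norm(pts - S[i], axis=1)))
                for lab, pts in region_points.items()
            }
            assigned[i] = min(dists, key=dists.get)

    if n_regions == 1:
        warnings.warn("single density region at this level; all cells in group 1", stacklevel=2)
        group = np.ones(S.shape[0], dtype=int)
    else:
        anchor_region = assigned[int(np.argmin(S[:, 0]))]  # smallest PC1 → group 1
        group = np.where(assigned == anchor_region, 1, 2)
    return GateResult(
        group_label=group, density_level=level, kde_bandwidth=bandwidth, n_regions=n_regions
    )
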
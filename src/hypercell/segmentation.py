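"""Per-cell masks, membrane/inner annuli, and a fallback threshold segmenter.

The ring phenotype lives at the plasma membrane, so each cell mask is split
into a border annulus (all pixels within `thickness` of the background) and
the adjacent inner annulus (the next `thickness` of depth).  Depth is the
exact Euclidean distance from a pixel center to the nearest background
pixel center; a Chebyshev (erosion-count) variant is available.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .channels import HyperspectralStack

__all__ = ["CellMask", "AnnulusPair", "extract_cells", "annuli", "threshold_segment"]


@dataclasses.dataclass
class CellMask:
    """One cell's pixel set inside a label image.

    ``mask`` is a full-frame boolean array; ``bounding_box`` is the tight
    half-open (row0, col0, row1, col1) box around the pixel set.
    """

    mask: np.ndarray
    cell_id: int
    bounding_box: tuple[int, int, int, int]

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def pixel_coords(self) -> np.ndarray:
        """(n, 2) array of [row, col] pixel coordinates, row-major order."""
        return np.argwhere(self.mask)


@dataclasses.dataclass
class AnnulusPair:
    """Border and inner annuli of one cell, both boolean full-frame arrays.

    ``inner_empty`` flags cells too thin to contain an inner annulus; ring
    classification must report "undefined" for those.
    """

    border: np.ndarray
    inner: np.ndarray
    thickness: float
    inner_empty: bool


def extract_cells(label_image: np.ndarray) -> list[CellMask]:
    """Split an integer label image into per-cell masks, ascending label order."""
    label_image = np.asarray(label_image)
    if not np.issubdtype(label_image.dtype, np.integer):
        raise ValueError("label image must be integer-typed")
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    if labels.size == 0:
        warnings.warn("label image contains no cells", stacklevel=2)
        return []
    cells = []
    for lab in labels:
        mask = label_image == lab
        rows, cols = np.nonzero(mask)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        cells.append(CellMask(mask=mask, cell_id=int(lab), bounding_box=bbox))
    return cells


def annuli(mask: CellMask, thickness: float = 10, metric: str = "euclidean") -> AnnulusPair:
    """Border and inner annuli by distance-to-background.

    border = {p in mask : 0 < d(p) <= thickness}
    inner  = {p in mask : thickness < d(p) <= 2 * thickness}

    where d is the distance from the pixel center to the nearest background
    pixel center (exact Euclidean by default, Chebyshev optional).
    """
    if mask.area_px == 0:
        raise ValueError("mask is empty")
    m = mask.mask
    if metric == "euclidean":
        dist = ndimage.distance_transform_edt(m)
    elif metric == "chebyshev":
        dist = ndimage.distance_transform_cdt(m, metric="chessboard").astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    border = m & (dist <= thickness)
    inner = m & (dist > thickness) & (dist <= 2 * thickness)
    return AnnulusPair(
        border=border,
        inner=inner,
        thickness=float(thickness),
        inner_empty=not bool(inner.any()),
    )


def threshold_segment(
    stack: HyperspectralStack,
    channels: tuple[int, ...] = (1, 6, 13),
    min_area: int = 50,
) -> np.ndarray:
    """Fallback segmentation for synthetic fields: Otsu on a channel mean.

    Components are 8-connected; those with area >= min_area are relabeled
    1..K in raster order of their top-left-most pixel.  Meant for simulated
    disk-like cells on flat background, not for real micrographs (the
    original masks for those come from an external pixel classifier and are
    consumed, not produced, here).
    """
    if not stack.normalized:
        raise ValueError("threshold_segment expects a normalized stack")
    mean_img = np.mean([stack.channel(c) for c in channels], axis=0)
    thresh = threshold_otsu(mean_img)
    fg = mean_img > thresh
    raw = cc_label(fg, connectivity=2)
    out = np.zeros_like(raw, dtype=np.int32)
    comps = []
    for lab in range(1, raw.max() + 1):
        mask = raw == lab
        if mask.sum() < min_area:
            continue
        rows, cols = np.nonzero(mask)
        # raster order of the component's first pixel in row-major scan
        first = (int(rows.min()), int(cols[rows == rows.min()].min()))
        comps.append((first, mask))
    if not comps:
        warnings.warn("no component reached min_area; empty segmentation", stacklevel=2)
        return out
    comps.sort(key=lambda t: t[0])
    for k, (_, mask) in enumerate(comps, start=1):
        out[mask] = k
    return out
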
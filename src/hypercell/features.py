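"""Per-cell optical features: spectral fingerprints, morphology, ring calls.

A cell's spectral fingerprint is its 15-vector of mean per-channel
intensities over the segmentation mask (after a light Gaussian blur of the
full frame to suppress shot noise).  Morphology uses the pixel count as
area and a length/width ratio as eccentricity.  The ring call compares the
membrane annulus with the adjacent inner annulus in one channel.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .channels import HyperspectralStack
from .segmentation import AnnulusPair, CellMask, annuli

__all__ = [
    "cell_spectrum",
    "morphology",
    "intensity_ratio",
    "classify_ring",
    "compute_features",
    "report_percent",
]

RING_CHANNEL_DEFAULT = 13
RING_THRESHOLD_DEFAULT = 0.4
RING_THICKNESS_DEFAULT = 10
BLUR_SIGMA_DEFAULT = 1.0


def _blur(image: np.ndarray, sigma: float) -> np.ndarray:
    if sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if sigma == 0:
        return np.asarray(image, dtype=float)
    return ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma=sigma, mode="reflect")


def cell_spectrum(
    stack: HyperspectralStack, mask: CellMask, blur_sigma: float = BLUR_SIGMA_DEFAULT
) -> np.ndarray:
    """Mean blurred intensity over the mask, one value per channel.

    The Gaussian blur (sigma in pixels, reflect boundary) is applied to the
    full channel image before masking; sigma = 0 gives the plain masked
    mean.
    """
    if mask.area_px == 0:
        raise ValueError("mask is empty")
    m = mask.mask
    return np.array([_blur(plane, blur_sigma)[m].mean() for plane in stack.pixels])


def _principal_extents(coords: np.ndarray) -> tuple[float, float]:
    """Extents of the pixel cloud along its two principal axes (max − min + 1)."""
    centered = coords - coords.mean(axis=0)
    if len(coords) == 1:
        return 1.0, 1.0
    cov = centered.T @ centered / len(coords)
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0
    return float(extents.max()), float(extents.min())


def morphology(
    mask: CellMask, pixel_size: float | None = None, axes: str = "principal"
) -> tuple[int, float | None, float]:
    """(area_px, area_um2, eccentricity) of one cell mask.

    Area is the pixel count; area_um2 = area_px * pixel_size^2 when a pixel
    size (um per pixel side) is known.  Eccentricity is length/width − 1
    with length and width the larger and smaller extent of the pixel cloud
    along its principal axes (``axes="bbox"`` uses the bounding box
    instead); 0 for a round cell.
    """
    area_px = mask.area_px
    if area_px == 0:
        raise ValueError("mask is empty")
    coords = mask.pixel_coords.astype(float)
    if axes == "principal":
        y, x = _principal_extents(coords)
    elif axes == "bbox":
        r0, c0, r1, c1 = mask.bounding_box
        y, x = float(max(r1 - r0, c1 - c0)), float(min(r1 - r0, c1 - c0))
    else:
        raise ValueError(f"unknown axes {axes!r}")
    eccentricity = y / x - 1.0
    area_um2 = area_px * pixel_size**2 if pixel_size is not None else None
    return area_px, area_um2, eccentricity


def intensity_ratio(spectrum: np.ndarray, a: int = 4, b: int = 2) -> float:
    """Ratio of mean intensities between two channels (1-based ids).

    Returns NaN when the denominator channel mean is 0.  The (4, 2) default
    contrasts the free-NAD(P)H proxy channel with a blue-shifted one.
    """
    spectrum = np.asarray(spectrum)
    num, den = spectrum[a - 1], spectrum[b - 1]
    if den <= 0:
        return float("nan")
    return float(num / den)


def classify_ring(
    stack: HyperspectralStack,
    mask: CellMask,
    channel: int = RING_CHANNEL_DEFAULT,
    thickness: float = RING_THICKNESS_DEFAULT,
    threshold: float = RING_THRESHOLD_DEFAULT,
    annulus_pair: AnnulusPair | None = None,
) -> tuple[float, str]:
    """Ring log2 fold change and call for one cell.

    ring_log2fc = log2(mean(border) / mean(inner)) in the given channel;
    the call is "ringed" iff ring_log2fc > threshold (strict; a cell at
    exactly the threshold is unringed), "undefined" when the inner annulus
    is empty or either mean is 0.
    """
    pair = annulus_pair if annulus_pair is not None else annuli(mask, thickness=thickness)
    if pair.inner_empty:
        return float("nan"), "undefined"
    plane = stack.channel(channel)
    border_mean = float(plane[pair.border].mean())
    inner_mean = float(plane[pair.inner].mean())
    if border_mean <= 0 or inner_mean <= 0:
        return float("nan"), "undefined"
    log2fc = math.log2(border_mean / inner_mean)
    return log2fc, ("ringed" if log2fc > threshold else "unringed")


def compute_features(
    stack: HyperspectralStack,
    cells: list[CellMask],
    blur_sigma: float = BLUR_SIGMA_DEFAULT,
    ring_channel: int = RING_CHANNEL_DEFAULT,
    ring_thickness: float = RING_THICKNESS_DEFAULT,
    ring_threshold: float = RING_THRESHOLD_DEFAULT,
    ratio_pair: tuple[int, int] = (4, 2),
) -> pd.DataFrame:
    """Feature table for a field: one row per cell, indexed by cell_id.

    Columns: mean_ch01..mean_chNN, area_px, area_um2, eccentricity,
    ratio_chAA_chBB, ring_log2fc, ring_call.  Blurred channel planes are
    computed once per field and shared across cells (identical to per-cell
    calls of :func:`cell_spectrum`).
    """
    blurred = np.stack([_blur(plane, blur_sigma) for plane in stack.pixels])
    rows = []
    for cell in cells:
        m = cell.mask
        spectrum = blurred[:, m].mean(axis=1)
        area_px, area_um2, ecc = morphology(cell, pixel_size=stack.pixel_size)
        log2fc, call = classify_ring(
            stack, cell, channel=ring_channel, thickness=ring_thickness, threshold=ring_threshold
        )
        row: dict[str, object] = {"cell_id": cell.cell_id}
        for i, v in enumerate(spectrum, start=1):
            row[f"mean_ch{i:02d}"] = v
        row["area_px"] = area_px
        row["area_um2"] = area_um2 if area_um2 is not None else np.nan
        row["eccentricity"] = ecc
        a, b = ratio_pair
        row[f"ratio_ch{a:02d}_ch{b:02d}"] = intensity_ratio(spectrum, a, b)
        row["ring_log2fc"] = log2fc
        row["ring_call"] = call
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")


def report_percent(count: int, total: int) -> int:
    """Integer-truncated percentage used in summary reports: floor(100*count/total)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(100 * count // total)
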
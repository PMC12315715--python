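"""Excitation x emission spectra matrices and channel overlays.

Autofluorescence is optically incoherent, so the signal a camera sees at a
given (excitation, emission) wavelength pair is proportional to the product
of the fluorophore's excitation spectrum at the excitation wavelength and
its emission spectrum at the emission wavelength, each normalized to its
own peak:

    I(ex, em) = (I_ex(ex) / I_ex(Ex0)) * (I_em(em) / I_em(Em0))

with Ex0/Em0 the spectral peaks.  The resulting rank-1 matrix, overlaid
with the instrument's channel coordinates, identifies which channel best
proxies a given metabolite (channel 4 for free NAD(P)H).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .channels import ChannelTable

__all__ = [
    "FluorophoreSpectrum",
    "SpectraMatrix",
    "read_spectrum_tsv",
    "gaussian_spectrum",
    "free_nadh_spectrum",
    "bound_nadh_spectrum",
    "build_spectra_matrix",
    "overlay_channels",
]


def _validate_curve(wl: np.ndarray, inten: np.ndarray, what: str) -> None:
    if wl.ndim != 1 or wl.shape != inten.shape or wl.size < 2:
        raise ValueError(f"{what} spectrum needs matching 1-D arrays of >= 2 points")
    if not np.all(np.diff(wl) > 0):
        raise ValueError(f"{what} wavelengths must be strictly increasing")
    if np.any(inten < 0):
        raise ValueError(f"{what} intensities must be >= 0")


@dataclasses.dataclass
class FluorophoreSpectrum:
    """Tabulated excitation and emission curves of one fluorophore.

    Wavelengths in nm, strictly increasing; intensities in arbitrary
    units.  The spectral peaks Ex0/Em0 are the maxima; a tie breaks toward
    the smallest wavelength.
    """

    name: str
    excitation_nm: np.ndarray
    excitation_intensity: np.ndarray
    emission_nm: np.ndarray
    emission_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.excitation_nm = np.asarray(self.excitation_nm, dtype=float)
        self.excitation_intensity = np.asarray(self.excitation_intensity, dtype=float)
        self.emission_nm = np.asarray(self.emission_nm, dtype=float)
        self.emission_intensity = np.asarray(self.emission_intensity, dtype=float)
        _validate_curve(self.excitation_nm, self.excitation_intensity, "excitation")
        _validate_curve(self.emission_nm, self.emission_intensity, "emission")

    @property
    def ex_peak(self) -> float:
        """Ex0: excitation wavelength of maximum intensity (ties -> smallest)."""
        return float(self.excitation_nm[int(np.argmax(self.excitation_intensity))])

    @property
    def em_peak(self) -> float:
        return float(self.emission_nm[int(np.argmax(self.emission_intensity))])


def read_spectrum_tsv(ex_path, em_path, name: str = "") -> FluorophoreSpectrum:
    """Load excitation and emission curves from two-column TSVs
    (wavelength_nm, intensity)."""
    ex = pd.read_csv(ex_path, sep="\t")
    em = pd.read_csv(em_path, sep="\t")
    return FluorophoreSpectrum(
        name=name,
        excitation_nm=ex.iloc[:, 0].to_numpy(),
        excitation_intensity=ex.iloc[:, 1].to_numpy(),
        emission_nm=em.iloc[:, 0].to_numpy(),
        emission_intensity=em.iloc[:, 1].to_numpy(),
    )


def gaussian_spectrum(
    name: str,
    ex_peak: float,
    em_peak: float,
    ex_width: float = 30.0,
    em_width: float = 40.0,
    span: float = 3.5,
    step: float = 2.0,
) -> FluorophoreSpectrum:
    """Synthetic Gaussian-shaped spectrum with stated peaks (nm).

    A stand-in for digitized literature curves: single Gaussian bands with
    the given standard deviations, tabulated every ``step`` nm over
    ``span`` standard deviations.
    """
    kx = int(span * ex_width / step)
    km = int(span * em_width / step)
    ex_wl = ex_peak + np.arange(-kx, kx + 1) * step  # grid contains the peak exactly
    em_wl = em_peak + np.arange(-km, km + 1) * step
    ex_i = np.exp(-0.5 * ((ex_wl - ex_peak) / ex_width) ** 2)
    em_i = np.exp(-0.5 * ((em_wl - em_peak) / em_width) ** 2)
    return FluorophoreSpectrum(name, ex_wl, ex_i, em_wl, em_i)


def free_nadh_spectrum() -> FluorophoreSpectrum:
    """Synthetic free-NAD(P)H-shaped spectrum (ex peak ~340 nm, em ~460 nm)."""
    return gaussian_spectrum("free NAD(P)H (synthetic)", ex_peak=340, em_peak=460)


def bound_nadh_spectrum() -> FluorophoreSpectrum:
    """Synthetic protein-bound NAD(P)H spectrum: emission blue-shifted to ~445 nm."""
    return gaussian_spectrum("bound NAD(P)H (synthetic)", ex_peak=330, em_peak=445)


@dataclasses.dataclass
class SpectraMatrix:
    """Excitation x emission grid of normalized intensity in [0, 1].

    Rank 1 by construction (outer product of the normalized curves), with
    maximum 1 attained at (Ex0, Em0) when the grid contains the peaks.
    """

    ex_grid: np.ndarray
    em_grid: np.ndarray
    intensity: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensity, index=self.ex_grid, columns=self.em_grid)


def build_spectra_matrix(
    spectrum: FluorophoreSpectrum,
    ex_grid: np.ndarray | None = None,
    em_grid: np.ndarray | None = None,
) -> SpectraMatrix:
    """Evaluate the normalized product intensity on an (ex, em) grid.

    Curves are linearly interpolated between tabulated points; grid points
    outside the tabulated support raise (no extrapolation).  Default grids
    are the spectra's own tabulated wavelengths.
    """
    ex_grid = spectrum.excitation_nm.copy() if ex_grid is None else np.asarray(ex_grid, dtype=float)
    em_grid = spectrum.emission_nm.copy() if em_grid is None else np.asarray(em_grid, dtype=float)
    for grid, wl, what in (
        (ex_grid, spectrum.excitation_nm, "excitation"),
        (em_grid, spectrum.emission_nm, "emission"),
    ):
        if grid.min() < wl[0] or grid.max() > wl[-1]:
            raise ValueError(
                f"{what} grid [{grid.min()}, {grid.max()}] outside tabulated support "
                f"[{wl[0]}, {wl[-1]}]; extrapolation not supported"
            )
    ex_i = np.interp(ex_grid, spectrum.excitation_nm, spectrum.excitation_intensity)
    em_i = np.interp(em_grid, spectrum.emission_nm, spectrum.emission_intensity)
    ex_peak_i = spectrum.excitation_intensity.max()
    em_peak_i = spectrum.emission_intensity.max()
    if ex_peak_i <= 0 or em_peak_i <= 0:
        raise ValueError("spectrum has no positive peak intensity")
    intensity = np.outer(ex_i / ex_peak_i, em_i / em_peak_i)
    return SpectraMatrix(ex_grid=ex_grid, em_grid=em_grid, intensity=intensity)


def overlay_channels(matrix: SpectraMatrix, channels: ChannelTable) -> pd.DataFrame:
    """Evaluate the matrix at each channel's (lambda_ex, lambda_em), ranked.

    Bilinear interpolation on the grid; channels outside the grid support
    are kept with NaN intensity and flagged.  The top-ranked channel is
    the proposed proxy channel for the fluorophore.
    """
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (matrix.ex_grid, matrix.em_grid), matrix.intensity, bounds_error=False, fill_value=np.nan
    )
    rows = []
    for cid, ex, em in channels.entries:
        in_support = (
            matrix.ex_grid[0] <= ex <= matrix.ex_grid[-1]
            and matrix.em_grid[0] <= em <= matrix.em_grid[-1]
        )
        val = float(interp([[ex, em]])[0]) if in_support else float("nan")
        rows.append({"channel": cid, "lambda_ex": ex, "lambda_em": em, "intensity": val,
                     "in_support": in_support})
    df = pd.DataFrame(rows).set_index("channel")
    df = df.sort_values("intensity", ascending=False, na_position="last")
    df["rank"] = np.arange(1, len(df) + 1)
    return df
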
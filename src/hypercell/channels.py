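"""Hyperspectral stacks, channel metadata, background normalization, pseudo-RGB.

The imaging system records one frame per (excitation, emission) wavelength
pair; 15 such channels make up one field of view.  Most of the field is
background, so the modal intensity of each channel estimates the background
level; normalization divides each channel by its mode and rescales so that
background sits at a common value (30 counts by default).
"""

from __future__ import annotations

import dataclasses
import pathlib
import re
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelTable",
    "HyperspectralStack",
    "default_channel_table",
    "read_channel_table",
    "write_channel_table",
    "read_stack",
    "write_stack",
    "modal_intensity",
    "normalize_stack",
    "pseudo_rgb",
]


class FormatError(ValueError):
    """Raised when an on-disk stack or table does not match its contract."""


@dataclasses.dataclass(frozen=True)
class ChannelTable:
    """Instrument channel layout: (channel_id, lambda_ex_nm, lambda_em_nm).

    Channel ids are unique and contiguous from 1; emission exceeds
    excitation for every channel (Stokes shift).
    """

    entries: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("channel ids must be unique and contiguous from 1")
        for cid, ex, em in self.entries:
            if not em > ex:
                raise ValueError(f"channel {cid}: lambda_em ({em}) must exceed lambda_ex ({ex})")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[int]:
        return [e[0] for e in self.entries]

    def wavelengths(self, channel_id: int) -> tuple[float, float]:
        """Return (lambda_ex, lambda_em) in nm for one channel."""
        for cid, ex, em in self.entries:
            if cid == channel_id:
                return ex, em
        raise KeyError(f"no channel {channel_id} in table of {len(self)}")

    def index(self, channel_id: int) -> int:
        """0-based axis index of a channel in the stack's channel axis."""
        if channel_id not in self.ids:
            raise KeyError(f"no channel {channel_id} in table of {len(self)}")
        return channel_id - 1


#: Default 15-channel layout.  The three channels the downstream analyses
#: rely on carry their published wavelength pairs (ch3 = 370/414,
#: ch4 = 343/451, ch13 = 431/594); the remaining twelve are a synthetic but
#: instrument-plausible excitation ladder in the NAD(P)H/flavin range.
_DEFAULT_ENTRIES: tuple[tuple[int, float, float], ...] = (
    (1, 320, 410),
    (2, 331, 425),
    (3, 370, 414),
    (4, 343, 451),
    (5, 355, 455),
    (6, 375, 460),
    (7, 385, 470),
    (8, 395, 490),
    (9, 405, 500),
    (10, 415, 520),
    (11, 425, 540),
    (12, 428, 560),
    (13, 431, 594),
    (14, 440, 575),
    (15, 450, 600),
)


def default_channel_table() -> ChannelTable:
    """The default 15-channel excitation/emission layout."""
    return ChannelTable(_DEFAULT_ENTRIES)


def read_channel_table(path: str | pathlib.Path) -> ChannelTable:
    """Read a channel table from TSV with columns channel, lambda_ex_nm, lambda_em_nm."""
    df = pd.read_csv(path, sep="\t")
    required = {"channel", "lambda_ex_nm", "lambda_em_nm"}
    if not required.issubset(df.columns):
        raise FormatError(f"channel table must have columns {sorted(required)}")
    df = df.sort_values("channel")
    entries = tuple(
        (int(r.channel), float(r.lambda_ex_nm), float(r.lambda_em_nm)) for r in df.itertuples()
    )
    return ChannelTable(entries)


def write_channel_table(table: ChannelTable, path: str | pathlib.Path) -> None:
    df = pd.DataFrame(table.entries, columns=["channel", "lambda_ex_nm", "lambda_em_nm"])
    df.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class HyperspectralStack:
    """One field of view: [channel, row, col] pixel array plus channel metadata.

    ``pixels`` is non-negative and finite; the channel axis matches the
    channel table, first plane = channel 1.  ``pixel_size`` is the physical
    side length of a pixel in micrometres, when known.
    """

    pixels: np.ndarray
    channel_table: ChannelTable
    normalized: bool = False
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be [channel, row, col]")
        if self.pixels.shape[0] != len(self.channel_table):
            raise FormatError(
                f"stack has {self.pixels.shape[0]} channels but table has {len(self.channel_table)}"
            )
        if not np.issubdtype(self.pixels.dtype, np.number):
            raise FormatError("pixel data must be numeric")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def channel(self, channel_id: int) -> np.ndarray:
        """2-D image of one channel."""
        return self.pixels[self.channel_table.index(channel_id)]


_CHANNEL_FILE = re.compile(r"ch(\d+)\.(tif|tiff|png)$", re.IGNORECASE)


def read_stack(path: str | pathlib.Path, channel_table: ChannelTable | None = None) -> HyperspectralStack:
    """Read a stack from a multi-page TIFF (page order = channel order) or a
    directory of per-channel files named ``ch<id>.tif``."""
    if channel_table is None:
        channel_table = default_channel_table()
    path = pathlib.Path(path)
    if path.is_dir():
        found: dict[int, pathlib.Path] = {}
        for f in path.iterdir():
            m = _CHANNEL_FILE.match(f.name)
            if m:
                found[int(m.group(1))] = f
        missing = [c for c in channel_table.ids if c not in found]
        if missing:
            raise FormatError(f"missing per-channel files for channels {missing}")
        planes = [np.asarray(tifffile.imread(found[c])) for c in channel_table.ids]
        pixels = np.stack(planes, axis=0)
    else:
        pixels = np.asarray(tifffile.imread(path))
        if pixels.ndim == 2:
            pixels = pixels[None]
        if pixels.shape[0] != len(channel_table):
            raise FormatError(
                f"TIFF has {pixels.shape[0]} pages but channel table has {len(channel_table)}"
            )
    if not np.issubdtype(pixels.dtype, np.number):
        raise FormatError("pixel data must be numeric")
    return HyperspectralStack(pixels, channel_table, normalized=False)


def write_stack(stack: HyperspectralStack, path: str | pathlib.Path) -> None:
    """Write a stack as a multi-page TIFF, one page per channel."""
    tifffile.imwrite(path, stack.pixels)


def modal_intensity(channel: np.ndarray) -> float:
    """Most frequent intensity of a channel after rounding to nearest integer.

    Ties among modal bins break toward the smallest intensity so the result
    is deterministic on camera-count data.
    """
    rounded = np.rint(np.asarray(channel, dtype=float)).astype(np.int64).ravel()
    counts = np.bincount(rounded)
    return float(np.argmax(counts))  # argmax returns first (smallest) maximal bin


def normalize_stack(stack: HyperspectralStack, scale: float = 30.0) -> HyperspectralStack:
    """Divide each channel by its modal (background) intensity and rescale.

    out[c] = in[c] / mode(in[c]) * scale, channel by channel.  The default
    scale of 30 puts the background near typical raw camera background
    counts.  A channel whose modal intensity is 0 has no usable background
    estimate and raises.
    """
    out = np.empty_like(stack.pixels, dtype=float)
    for i, cid in enumerate(stack.channel_table.ids):
        mode = modal_intensity(stack.pixels[i])
        if mode == 0:
            raise ValueError(f"channel {cid}: modal intensity is 0 (degenerate background)")
        out[i] = stack.pixels[i] / mode * scale
    return HyperspectralStack(out, stack.channel_table, normalized=True, pixel_size=stack.pixel_size)


def pseudo_rgb(
    stack: HyperspectralStack,
    channels: Sequence[int] = (1, 6, 13),
    clip_percentile: float = 99.5,
    clip_max: float | None = None,
) -> np.ndarray:
    """Compose a [row, col, 3] display image from three channels.

    Each plane is clipped to [0, clip_max] (default: its own 99.5th
    percentile) and linearly rescaled to [0, 1].
    """
    if not stack.normalized:
        raise ValueError("pseudo_rgb expects a normalized stack")
    if len(channels) != 3:
        raise ValueError("exactly three channels required")
    planes = []
    for cid in channels:
        plane = stack.channel(cid).astype(float)
        top = float(np.percentile(plane, clip_percentile)) if clip_max is None else float(clip_max)
        if top <= 0:
            planes.append(np.zeros_like(plane))
        else:
            planes.append(np.clip(plane, 0, top) / top)
    return np.stack(planes, axis=-1)
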
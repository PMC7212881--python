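"""Reading, tiling and downsampling of multiphoton channel images.

A scan is stored as one single-plane grayscale TIFF per channel (CARS, TPEF
or SHG).  Large tiled scans are cut into non-overlapping fields of view
(FoVs) of a fixed shape — by default 104×208 pixels, i.e. 104 µm × 208 µm at
the nominal 1 µm pixel size — which are the unit of texture extraction and
classification downstream.  Block-average downsampling supports resolution
experiments (e.g. 0.5 µm/px data reduced to 1 µm/px).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

#: Default FoV shape (rows, cols) in pixels.
DEFAULT_FOV_SHAPE = (104, 208)

MANIFEST_COLUMNS = ("sample_id", "channel", "path", "label")


class Channel(str, Enum):
    """Multiphoton imaging modality of one channel."""

    CARS = "CARS"  # coherent anti-Stokes Raman scattering (lipids / structure)
    TPEF = "TPEF"  # two-photon excited autofluorescence
    SHG = "SHG"    # second-harmonic generation (fibrillar collagen)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ImagingError(Exception):
    """Base class for image I/O and geometry errors."""


class NotSingleChannelError(ImagingError):
    """Raster is RGB / multi-plane rather than single-channel grayscale."""


class TileError(ImagingError):
    """Image cannot be cut into at least one full tile."""


def _validate_pixels(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise ImagingError(f"expected a 2-D intensity grid, got ndim={pixels.ndim}")
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ImagingError(f"image must be at least 1×1 pixels, got {pixels.shape}")
    if not np.all(np.isfinite(pixels)):
        raise ImagingError("image contains non-finite intensities")
    if pixels.min() < 0:
        raise ImagingError("image contains negative intensities")
    return pixels


@dataclass(frozen=True)
class Image2D:
    """A single-channel intensity image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float
    channel: Channel

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _validate_pixels(self.pixels))
        object.__setattr__(self, "channel", Channel(self.channel))
        if not (self.pixel_size_um > 0):
            raise ImagingError(f"pixel size must be positive, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FieldOfView:
    """One tile of a scan: the unit of feature extraction.

    ``grid_row``/``grid_col`` locate the tile on the scan's tile grid
    (0-based, row-major, origin at the top-left of the scan).
    """

    pixels: np.ndarray
    grid_row: int = 0
    grid_col: int = 0
    sample_id: str = ""
    channel: Channel = Channel.CARS
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _validate_pixels(self.pixels))
        object.__setattr__(self, "channel", Channel(self.channel))
        if self.grid_row < 0 or self.grid_col < 0:
            raise ImagingError("grid indices must be nonnegative")
        if not (self.pixel_size_um > 0):
            raise ImagingError(f"pixel size must be positive, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def provenance(self) -> tuple[str, int, int, str]:
        return (self.sample_id, self.grid_row, self.grid_col, self.channel.value)


def read_channel_image(path: str | Path, channel: Channel | str,
                       pixel_size_um: float = 1.0) -> Image2D:
    """Read a single-plane grayscale TIFF as an :class:`Image2D`.

    Intensities are returned exactly as stored; no normalization happens at
    read time.  RGB or multi-plane rasters are rejected.
    """
    path = Path(path)
    if not (pixel_size_um > 0):
        raise ImagingError(f"pixel size must be positive, got {pixel_size_um}")
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise ImagingError(f"file not found: {path}") from None
    except Exception as exc:  # corrupt / non-TIFF
        raise ImagingError(f"unreadable image file {path}: {exc}") from exc
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim != 2:
        raise NotSingleChannelError(
            f"{path} is not single-channel: shape {arr.shape}")
    return Image2D(pixels=arr, pixel_size_um=pixel_size_um, channel=channel)


def tile(image: Image2D, fov_rows: int = DEFAULT_FOV_SHAPE[0],
         fov_cols: int = DEFAULT_FOV_SHAPE[1], sample_id: str = "") -> list[FieldOfView]:
    """Cut an image into non-overlapping FoVs on a regular grid.

    The grid is anchored at the top-left pixel; partial tiles at the right
    and bottom edges are discarded (padding would inject artificial texture
    into the feature statistics).  Tiles are returned in row-major order.
    """
    if fov_rows < 1 or fov_cols < 1:
        raise TileError("tile shape must be positive")
    rows, cols = image.shape
    n_r, n_c = rows // fov_rows, cols // fov_cols
    if n_r == 0 or n_c == 0:
        raise TileError(
            f"image of shape {image.shape} is smaller than one {fov_rows}×{fov_cols} tile")
    dropped = (rows - n_r * fov_rows, cols - n_c * fov_cols)
    if dropped != (0, 0):
        log.debug("tile: dropping %d trailing rows, %d trailing cols", *dropped)
    out = []
    for i in range(n_r):
        for j in range(n_c):
            block = image.pixels[i * fov_rows:(i + 1) * fov_rows,
                                 j * fov_cols:(j + 1) * fov_cols]
            out.append(FieldOfView(pixels=block, grid_row=i, grid_col=j,
                                   sample_id=sample_id, channel=image.channel,
                                   pixel_size_um=image.pixel_size_um))
    return out


def downsample(image: Image2D, factor: int) -> Image2D:
    """Block-average downsampling by an integer factor.

    Each output pixel is the arithmetic mean of the corresponding
    ``factor×factor`` block; the pixel size is multiplied accordingly.
    Trailing rows/cols that do not fill a block are dropped (and logged).
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ImagingError(f"downsampling factor must be a positive integer, got {factor}")
    if factor == 1:
        return image
    rows, cols = image.shape
    n_r, n_c = rows // factor, cols // factor
    if n_r < 1 or n_c < 1:
        raise ImagingError(
            f"downsampling {image.shape} by {factor} leaves no pixels")
    if (rows % factor, cols % factor) != (0, 0):
        log.warning("downsample: dropping %d trailing rows, %d trailing cols",
                    rows % factor, cols % factor)
    block = image.pixels[:n_r * factor, :n_c * factor]
    out = block.reshape(n_r, factor, n_c, factor).mean(axis=(1, 3))
    return Image2D(pixels=out, pixel_size_um=image.pixel_size_um * factor,
                   channel=image.channel)


def downsample_fov(fov: FieldOfView, factor: int) -> FieldOfView:
    """Block-average a FoV, keeping its provenance."""
    img = Image2D(pixels=fov.pixels, pixel_size_um=fov.pixel_size_um,
                  channel=fov.channel)
    out = downsample(img, factor)
    return FieldOfView(pixels=out.pixels, grid_row=fov.grid_row,
                       grid_col=fov.grid_col, sample_id=fov.sample_id,
                       channel=fov.channel, pixel_size_um=out.pixel_size_um)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV.

    Required columns: ``sample_id, channel, path, label``; optional
    ``grid_row, grid_col`` locate each file on the sample's tile grid
    (default 0,0 for single-FoV files).  Paths are resolved relative to the
    manifest's directory.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "channel": str,
                                      "path": str, "label": str})
    except FileNotFoundError:
        raise ImagingError(f"manifest not found: {path}") from None
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ImagingError(f"manifest {path} lacks columns: {sorted(missing)}")
    if df.empty:
        raise ImagingError(f"manifest {path} is empty")
    for col, default in (("grid_row", 0), ("grid_col", 0)):
        if col not in df.columns:
            df[col] = default
    df["channel"] = df["channel"].map(lambda c: Channel(c).value)
    root = path.parent
    df["path"] = df["path"].map(lambda p: str((root / p) if not Path(p).is_absolute() else Path(p)))
    return df
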
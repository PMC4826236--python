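"""Raster data model and image/table I/O.

Two tiny containers are shared by every analysis module: :class:`ImageGrid`,
a single 2-D intensity channel with explicit bit depth, and
:class:`LabelMask`, an integer segmentation map (label 0 = background).
Coordinates are (row, col), 0-based, origin top-left, half-open bounds.

Images are read/written as greyscale or multichannel TIFF (via tifffile)
or PNG (via imageio); tables as UTF-8 comma-separated CSV with "." decimals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageGrid",
    "LabelMask",
    "TEXTURE_TABLE_COLUMNS",
    "read_image",
    "write_image",
    "to_8bit",
    "write_table",
    "read_table",
]

#: Fixed column order of the per-nucleus texture table.
TEXTURE_TABLE_COLUMNS = [
    "sample_id",
    "group",
    "nucleus_id",
    "area_px",
    "asm",
    "contrast",
    "correlation",
    "idm",
    "entropy",
    "correlation_defined",
]


@dataclass(frozen=True)
class ImageGrid:
    """One 2-D channel of non-negative integer intensities.

    Parameters
    ----------
    values
        2-D array of intensities; stored as uint8 or uint16.
    bit_depth
        8 or 16; all values must lie in ``[0, 2**bit_depth - 1]``.
    """

    values: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"ImageGrid needs a non-empty 2-D array, got shape {arr.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if np.issubdtype(arr.dtype, np.floating):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("ImageGrid intensities must be integers")
            arr = np.round(arr)
        if arr.size and (arr.min() < 0 or arr.max() > 2**self.bit_depth - 1):
            raise ValueError(
                f"values outside [0, {2**self.bit_depth - 1}] for bit_depth {self.bit_depth}"
            )
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        object.__setattr__(self, "values", arr.astype(dtype, copy=False))

    @property
    def height(self) -> int:
        return int(self.values.shape[0])

    @property
    def width(self) -> int:
        return int(self.values.shape[1])

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class LabelMask:
    """Integer-labelled segmentation map; 0 is background.

    After :meth:`compact`, the label set is {0} ∪ {1..K} with no gaps.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"LabelMask needs a non-empty 2-D array, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("labels must be integers")
        if arr.size and arr.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", arr.astype(np.int32, copy=False))

    @property
    def height(self) -> int:
        return int(self.labels.shape[0])

    @property
    def width(self) -> int:
        return int(self.labels.shape[1])

    @property
    def n_labels(self) -> int:
        """Number of foreground objects."""
        return int(len(self.label_ids()))

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def compact(self) -> "LabelMask":
        """Renumber labels to 1..K preserving order of first appearance of sorted ids."""
        out = np.zeros_like(self.labels)
        for new, old in enumerate(self.label_ids(), start=1):
            out[self.labels == old] = new
        return LabelMask(out)


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    # Fall back on the value range for e.g. int32 PNG reads.
    return 8 if arr.size == 0 or arr.max() <= 255 else 16


def read_image(path: str | os.PathLike, channel_index: int = 0) -> ImageGrid:
    """Read one channel of a TIFF or PNG file as an :class:`ImageGrid`.

    Multichannel files may be stored channel-first ``(C, H, W)`` or
    channel-last ``(H, W, C)``; the channel axis is taken to be the smaller
    of the first/last axes when the array is 3-D.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        if channel_index != 0:
            raise ValueError(f"channel_index {channel_index} out of range for single-channel image")
        channel = arr
    elif arr.ndim == 3:
        axis = 0 if arr.shape[0] <= arr.shape[-1] else 2
        n_channels = arr.shape[axis]
        if not 0 <= channel_index < n_channels:
            raise ValueError(f"channel_index {channel_index} out of range for {n_channels} channels")
        channel = arr[channel_index] if axis == 0 else arr[..., channel_index]
    else:
        raise IOError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return ImageGrid(channel, bit_depth=_infer_bit_depth(channel))


def write_image(path: str | os.PathLike, image: ImageGrid | Sequence[ImageGrid]) -> None:
    """Write one ImageGrid (greyscale) or several (channel-first stack) to TIFF/PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, ImageGrid):
        data = image.values
    else:
        data = np.stack([ch.values for ch in image], axis=0)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, data, photometric="minisblack")
        else:
            iio.imwrite(path, data)
    except Exception as exc:  # pragma: no cover
        raise IOError(f"could not write image {path}: {exc}") from exc


def to_8bit(image: ImageGrid) -> ImageGrid:
    """Convert to 8-bit by linear min-max rescaling onto [0, 255].

    8-bit input is returned unchanged. The rescale maps the observed input
    range linearly onto [0, 255] with round-half-up; a constant image maps
    to the constant 0 by convention. Pixel ordering is preserved (monotone).
    """
    if image.bit_depth == 8:
        return image
    vals = image.values.astype(np.float64)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return ImageGrid(np.zeros_like(image.values, dtype=np.uint8), bit_depth=8)
    scaled = (vals - lo) * (255.0 / (hi - lo))
    # round-half-up, not banker's rounding
    out = np.floor(scaled + 0.5).astype(np.uint8)
    return ImageGrid(out, bit_depth=8)


def write_table(rows: Iterable[Mapping] | pd.DataFrame, path: str | os.PathLike,
                columns: Sequence[str] | None = None) -> None:
    """Write records to CSV with a fixed column order and full float precision.

    ``columns`` fixes the column order; when omitted, a DataFrame keeps its
    own order and a record list uses the key order of the first record.
    An empty record list with explicit ``columns`` yields a header-only CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows, columns=columns if columns is not None else None)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        for c in missing:
            df[c] = pd.Series(dtype=object)
        df = df[list(columns)]
    try:
        # %.17g guarantees binary round trip of IEEE doubles through text
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise IOError(f"could not write table {path}: {exc}") from exc


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`."""
    return pd.read_csv(path, float_precision="round_trip")
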
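"""Reading multichannel 2-D images and writing RGB montages.

Native read support is TIFF / OME-TIFF via :mod:`tifffile`.  Proprietary
formats (nd2, oif, czi, zvi, ...) can be plugged in through a *reader hook*:
any callable ``hook(path) -> (planes, DimensionInfo)``.

The reader never rejects multi-z / multi-t / multi-series files itself; it
reports the full dimensionality in :class:`DimensionInfo` and returns the
planes of the first z-slice / time point / series.  Filtering against the
user-declared dataset shape is the discovery layer's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Tuple, Union

import numpy as np
import tifffile
from PIL import Image

from .errors import ImageReadError, PicmontageError

__all__ = [
    "ChannelPlane",
    "DimensionInfo",
    "ReaderHook",
    "read_image",
    "write_montage",
]

_DTYPE_TO_DEPTH = {1: 8, 2: 16}

#: axes letters treated as "channel-like" when unpacking a TIFF series.
#: C = channel, S = sample (interleaved RGB) or shaped sequence,
#: I = generic image sequence, Q = unknown — plain multipage TIFFs surface
#: their page axis as one of S/I/Q and pages are interpreted as channels.
_CHANNEL_AXES = "CSIQ"


@dataclass(frozen=True)
class ChannelPlane:
    """One grayscale intensity plane of a field of view.

    Parameters
    ----------
    pixels:
        2-D array of unsigned integers (``uint8`` or ``uint16``).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise PicmontageError(f"channel plane must be 2-D, got shape {arr.shape}")
        if arr.dtype not in (np.uint8, np.uint16):
            raise PicmontageError(
                f"unsupported pixel dtype {arr.dtype}; only uint8/uint16 planes are handled"
            )
        object.__setattr__(self, "pixels", arr)

    @property
    def bit_depth(self) -> int:
        return _DTYPE_TO_DEPTH[self.pixels.dtype.itemsize]

    @property
    def max_value(self) -> int:
        """Largest representable intensity (255 or 65535)."""
        return (1 << self.bit_depth) - 1

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class DimensionInfo:
    """Dimensional metadata of an image file as stored on disk."""

    n_channels: int
    n_z: int = 1
    n_t: int = 1
    n_series: int = 1
    bit_depth: int = 16
    width: int = 0
    height: int = 0

    def __post_init__(self) -> None:
        for name in ("n_channels", "n_z", "n_t", "n_series"):
            if getattr(self, name) < 1:
                raise PicmontageError(f"{name} must be >= 1")

    @property
    def is_plain_multichannel(self) -> bool:
        """True when the file is a simple 2-D multichannel image."""
        return self.n_z == 1 and self.n_t == 1 and self.n_series == 1


ReaderHook = Callable[[Union[str, Path]], Tuple[List[ChannelPlane], DimensionInfo]]


def read_image(
    path: Union[str, Path],
    reader_hook: Optional[ReaderHook] = None,
) -> Tuple[List[ChannelPlane], DimensionInfo]:
    """Read a TIFF/OME-TIFF file into channel planes plus dimension metadata.

    Returns the planes of the first z-slice, frame and series; the returned
    :class:`DimensionInfo` still reports the file's full dimensionality so
    callers can apply their own exclusion rules.

    Raises
    ------
    ImageReadError
        If the file is missing, unreadable or uses an unsupported pixel type.
    """
    path = Path(path)
    if reader_hook is not None:
        return reader_hook(path)
    if not path.is_file():
        raise ImageReadError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            n_series = len(tf.series)
            series = tf.series[0]
            axes = series.axes
            arr = series.asarray()
    except ImageReadError:
        raise
    except Exception as exc:  # noqa: BLE001 - any tifffile failure is a read error
        raise ImageReadError(f"cannot read {path}: {exc}") from exc
    return _unpack_series(arr, axes, n_series, path)


def _unpack_series(
    arr: np.ndarray, axes: str, n_series: int, path: Path
) -> Tuple[List[ChannelPlane], DimensionInfo]:
    if arr.dtype.kind != "u" or arr.dtype.itemsize not in _DTYPE_TO_DEPTH:
        raise ImageReadError(f"{path}: unsupported pixel type {arr.dtype}")
    if "Y" not in axes or "X" not in axes:
        raise ImageReadError(f"{path}: series without spatial axes ({axes!r})")

    n_z = n_t = 1
    n_channels = 1
    index: list = []
    for ax, size in zip(axes, arr.shape):
        if ax == "Z":
            n_z = size
            index.append(0)
        elif ax == "T":
            n_t = size
            index.append(0)
        elif ax in ("Y", "X"):
            index.append(slice(None))
        elif ax in _CHANNEL_AXES:
            n_channels *= size
            index.append(slice(None))
        else:  # any other axis: keep first hyperplane, count as extra series
            n_series = max(n_series, size)
            index.append(0)
    sub = arr[tuple(index)]

    # move any channel-like axes in front of Y, X
    kept = [ax for ax in axes if ax in _CHANNEL_AXES or ax in "YX"]
    order = [i for i, ax in enumerate(kept) if ax in _CHANNEL_AXES]
    order += [i for i, ax in enumerate(kept) if ax == "Y"]
    order += [i for i, ax in enumerate(kept) if ax == "X"]
    sub = np.transpose(sub, order)
    height, width = sub.shape[-2], sub.shape[-1]
    sub = sub.reshape(-1, height, width)

    planes = [ChannelPlane(np.ascontiguousarray(p)) for p in sub]
    info = DimensionInfo(
        n_channels=n_channels,
        n_z=n_z,
        n_t=n_t,
        n_series=n_series,
        bit_depth=planes[0].bit_depth,
        width=width,
        height=height,
    )
    return planes, info


_FORMAT_EXT = {"png": "png", "jpeg": "jpg", "tiff": "tif"}


def montage_extension(export_format: str) -> str:
    """File extension (without dot) used for a given export format."""
    try:
        return _FORMAT_EXT[export_format]
    except KeyError:
        raise PicmontageError(f"unknown export format: {export_format!r}") from None


def write_montage(
    pixels: np.ndarray,
    path: Union[str, Path],
    export_format: str = "png",
    quality: int = 90,
) -> Path:
    """Write an 8-bit RGB montage to disk.

    PNG and TIFF are lossless (read-back equals input); JPEG is written at
    the given quality (default 90) and is lossy.
    """
    path = Path(path)
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.dtype != np.uint8:
        raise PicmontageError("montage must be an 8-bit RGB (H, W, 3) array")
    img = Image.fromarray(pixels, mode="RGB")
    if export_format == "png":
        img.save(path, format="PNG")
    elif export_format == "jpeg":
        img.save(path, format="JPEG", quality=quality)
    elif export_format == "tiff":
        img.save(path, format="TIFF")
    else:
        raise PicmontageError(f"unknown export format: {export_format!r}")
    return path
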
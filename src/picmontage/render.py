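"""Tile rendering: colorization, channel merging, labels, montage assembly.

Single-channel tiles are shown as grayscale; the merge tile combines the
included channels in their palette colors by saturating additive blending
(component-wise sum clamped to 255), the usual fluorescence-composite
convention.  Montages are grids of same-sized tiles separated by a 2-px
black border; horizontal orientation puts fields of view on rows and
channels/merge on columns, vertical is the transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .errors import ConfigurationError, RenderError
from .image_io import ChannelPlane

__all__ = [
    "COLOR_VECTORS",
    "RenderOptions",
    "default_palette",
    "colorize",
    "merge_channels",
    "label_tile",
    "assemble_montage",
]

COLOR_VECTORS: Dict[str, Tuple[int, int, int]] = {
    "red": (1, 0, 0),
    "green": (0, 1, 0),
    "blue": (0, 0, 1),
    "gray": (1, 1, 1),
    "cyan": (0, 1, 1),
    "magenta": (1, 0, 1),
    "yellow": (1, 1, 0),
}

#: default channel → color assignment (channel 1 blue, 2 green, 3 red, ...),
#: matching the common DAPI/GFP/RFP ordering; single-channel datasets get gray.
_DEFAULT_ORDER = ("blue", "green", "red", "gray", "cyan", "magenta", "yellow")

TILE_SEPARATOR_PX = 2
ORIENTATIONS = ("horizontal", "vertical")
EXPORT_FORMATS = ("png", "jpeg", "tiff")


def default_palette(n_channels: int) -> Dict[int, str]:
    if n_channels == 1:
        return {1: "gray"}
    return {c: _DEFAULT_ORDER[(c - 1) % len(_DEFAULT_ORDER)] for c in range(1, n_channels + 1)}


@dataclass(frozen=True)
class RenderOptions:
    """Montage appearance settings.

    ``palette`` maps 1-based channel indices to one of the seven color names;
    channels omitted from the mapping fall back to the default assignment.
    ``omit_from_singles`` / ``omit_from_merge`` drop channels from the
    single-channel columns / the merge tile respectively; the merge must keep
    at least one channel.
    """

    palette: Optional[Dict[int, str]] = None
    label_tiles: bool = True
    orientation: str = "horizontal"
    export_format: str = "png"
    omit_from_singles: FrozenSet[int] = frozenset()
    omit_from_merge: FrozenSet[int] = frozenset()

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if self.export_format not in EXPORT_FORMATS:
            raise ConfigurationError(
                f"export_format must be one of {EXPORT_FORMATS}, got {self.export_format!r}"
            )
        if self.palette is not None:
            for channel, color in self.palette.items():
                if color not in COLOR_VECTORS:
                    raise ConfigurationError(
                        f"unknown color {color!r} for channel {channel}; "
                        f"choose from {sorted(COLOR_VECTORS)}"
                    )
        object.__setattr__(self, "omit_from_singles", frozenset(self.omit_from_singles))
        object.__setattr__(self, "omit_from_merge", frozenset(self.omit_from_merge))

    def validate_for(self, n_channels: int) -> None:
        """Check channel indices against the dataset's channel count."""
        all_channels = set(range(1, n_channels + 1))
        if self.palette:
            bad = set(self.palette) - all_channels
            if bad:
                raise ConfigurationError(f"palette references unknown channels: {sorted(bad)}")
        for name, omitted in (
            ("omit_from_singles", self.omit_from_singles),
            ("omit_from_merge", self.omit_from_merge),
        ):
            bad = set(omitted) - all_channels
            if bad:
                raise ConfigurationError(f"{name} references unknown channels: {sorted(bad)}")
        if not all_channels - self.omit_from_merge:
            raise ConfigurationError("omit_from_merge must leave at least one channel in the merge")

    def resolved_palette(self, n_channels: int) -> Dict[int, str]:
        palette = default_palette(n_channels)
        if self.palette:
            palette.update(self.palette)
        return palette

    def shown_channels(self, n_channels: int) -> List[int]:
        """Channels rendered as single-channel tiles, in channel order."""
        return [c for c in range(1, n_channels + 1) if c not in self.omit_from_singles]

    def merged_channels(self, n_channels: int) -> List[int]:
        return [c for c in range(1, n_channels + 1) if c not in self.omit_from_merge]


def _to_display(plane: ChannelPlane) -> np.ndarray:
    """Scale a plane to the 8-bit display range (round half-up)."""
    if plane.bit_depth == 8:
        return plane.pixels.copy()
    scaled = plane.pixels.astype(np.float64) * (255.0 / plane.max_value)
    return np.floor(scaled + 0.5).astype(np.uint8)


def colorize(plane: ChannelPlane, color: str) -> np.ndarray:
    """Render one channel as an RGB tile in the given color.

    Intensity is scaled to 8-bit and multiplied into the color's unit RGB
    vector; ``gray`` therefore reproduces the plane as a grayscale tile.
    """
    try:
        vec = COLOR_VECTORS[color]
    except KeyError:
        raise ConfigurationError(
            f"unknown color {color!r}; choose from {sorted(COLOR_VECTORS)}"
        ) from None
    display = _to_display(plane)
    tile = np.zeros(display.shape + (3,), dtype=np.uint8)
    for component, on in enumerate(vec):
        if on:
            tile[..., component] = display
    return tile


def merge_channels(
    planes: Sequence[ChannelPlane],
    options: RenderOptions,
) -> np.ndarray:
    """Compose the merge tile: clamped component-wise sum of colorized channels."""
    n = len(planes)
    included = options.merged_channels(n)
    if not included:
        raise ConfigurationError("merge must include at least one channel")
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise RenderError(f"merge planes differ in size: {sorted(shapes)}")
    palette = options.resolved_palette(n)
    acc = np.zeros(planes[0].shape + (3,), dtype=np.uint16)
    for c in included:
        acc += colorize(planes[c - 1], palette[c])
    return np.minimum(acc, 255).astype(np.uint8)


def label_font_height(tile_height: int) -> int:
    return max(8, tile_height // 24)


def label_tile(
    tile: np.ndarray,
    channel_token: str,
    folder: str,
    file: str,
    enabled: bool = True,
) -> np.ndarray:
    """Draw "<channel_token> <folder> <file>" in white at the tile's top-left.

    Font height is max(8 px, tile height / 24); text wider than the tile is
    truncated with an ellipsis.  With ``enabled=False`` the tile is returned
    unmodified.
    """
    if not enabled:
        return tile
    text = f"{channel_token} {folder} {file}"
    height = label_font_height(tile.shape[0])
    img = Image.fromarray(tile, mode="RGB")
    draw = ImageDraw.Draw(img)
    try:
        font = ImageFont.load_default(size=height)
    except TypeError:  # pragma: no cover - very old Pillow
        font = ImageFont.load_default()
    max_width = tile.shape[1] - 4
    if draw.textlength(text, font=font) > max_width:
        while text and draw.textlength(text + "...", font=font) > max_width:
            text = text[:-1]
        text += "..."
    draw.text((2, 2), text, fill=(255, 255, 255), font=font)
    return np.asarray(img, dtype=np.uint8)


def assemble_montage(
    tiles: Sequence[Sequence[np.ndarray]],
    options: RenderOptions,
) -> np.ndarray:
    """Abut a rectangular grid of same-sized RGB tiles into one montage.

    ``tiles`` is the logical grid — rows are fields of view, columns are the
    shown channels followed by the merge.  Vertical orientation transposes
    the grid.  Tiles are separated by a 2-px black border and never rescaled;
    inconsistent tile sizes are a fatal error.
    """
    grid = [list(row) for row in tiles]
    if not grid or not grid[0]:
        raise RenderError("montage grid is empty")
    n_cols = len(grid[0])
    if any(len(row) != n_cols for row in grid):
        raise RenderError("montage grid is not rectangular")
    shape = grid[0][0].shape
    for r, row in enumerate(grid):
        for c, tile in enumerate(row):
            if tile.shape != shape:
                raise RenderError(
                    f"tile at row {r + 1}, column {c + 1} has size "
                    f"{tile.shape[1]}x{tile.shape[0]}, expected {shape[1]}x{shape[0]}; "
                    "mixed image sizes are not rescaled silently"
                )

    if options.orientation == "vertical":
        grid = [list(col) for col in zip(*grid)]

    rows, cols = len(grid), len(grid[0])
    th, tw = shape[0], shape[1]
    sep = TILE_SEPARATOR_PX
    out = np.zeros(
        (rows * th + (rows - 1) * sep, cols * tw + (cols - 1) * sep, 3), dtype=np.uint8
    )
    for r, row in enumerate(grid):
        for c, tile in enumerate(row):
            y = r * (th + sep)
            x = c * (tw + sep)
            out[y : y + th, x : x + tw] = tile
    return out
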
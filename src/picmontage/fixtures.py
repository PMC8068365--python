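"""Synthetic dataset generation.

Builds experiment directory trees of multichannel TIFF images with
controlled per-channel intensity structure, in both on-disk layouts
(multichannel file per field of view, or one file per channel).  Also
builds the four-picture "contrast pitfall" scene of flat squares used to
demonstrate how individual-scope stretching invalidates intensity
comparisons.

Everything is seeded: the same spec and seed produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile

from .errors import ConfigurationError, PicmontageError
from .image_io import ChannelPlane

__all__ = [
    "FixtureSpec",
    "Square",
    "SquareSceneSpec",
    "generate_dataset",
    "generate_pitfall_set",
    "pitfall_demo_scene",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a synthetic experiment directory."""

    n_subfolders: int
    images_per_subfolder: int
    n_channels: int
    bit_depth: int = 16
    width: int = 64
    height: int = 64
    structure: str = "single_file"
    extension: str = "tif"
    noise_sd: float = 0.0
    seed: int = 0
    channel_identifiers: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        for name in ("n_subfolders", "images_per_subfolder", "n_channels", "width", "height"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        if self.structure not in ("single_file", "separated_channels"):
            raise ConfigurationError(f"unknown structure {self.structure!r}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.channel_identifiers is None:
            ids = tuple(f"C{i}" for i in range(1, self.n_channels + 1))
            object.__setattr__(self, "channel_identifiers", ids)

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


def _noisy(
    field_values: np.ndarray, noise_sd: float, rng: np.random.Generator, max_value: int
) -> np.ndarray:
    if noise_sd > 0:
        field_values = field_values + rng.normal(0.0, noise_sd, field_values.shape)
    return np.clip(np.rint(field_values), 0, max_value)


def _channel_plane(
    spec: FixtureSpec, rng: np.random.Generator, channel: int
) -> np.ndarray:
    """One synthetic channel: low background plus a bright centered square."""
    full = spec.max_value
    background = float(rng.integers(0, max(1, full // 20)))
    mean = float(rng.integers(full // 8, full // 2))
    values = np.full((spec.height, spec.width), background, dtype=np.float64)
    side = max(2, min(spec.height, spec.width) // (2 + channel))
    y0 = (spec.height - side) // 2
    x0 = (spec.width - side) // 2
    values[y0 : y0 + side, x0 : x0 + side] = mean
    return _noisy(values, spec.noise_sd, rng, full).astype(spec.dtype)


def generate_dataset(spec: FixtureSpec, parent_dir: Union[str, Path]) -> Path:
    """Write a full experiment tree under ``parent_dir`` and return its path.

    Subfolders are named ``cond01..condNN`` and fields of view ``img01..``;
    in separated mode each channel file is ``img01_<identifier>.<ext>``.
    """
    parent = Path(parent_dir)
    parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    for s in range(1, spec.n_subfolders + 1):
        sub = parent / f"cond{s:02d}"
        sub.mkdir(exist_ok=True)
        for i in range(1, spec.images_per_subfolder + 1):
            channels = np.stack(
                [_channel_plane(spec, rng, c) for c in range(1, spec.n_channels + 1)]
            )
            if spec.structure == "single_file":
                path = sub / f"img{i:02d}.{spec.extension}"
                tifffile.imwrite(
                    path, channels, photometric="minisblack", metadata={"axes": "CYX"}
                )
            else:
                for c, ident in enumerate(spec.channel_identifiers):
                    path = sub / f"img{i:02d}_{ident}.{spec.extension}"
                    tifffile.imwrite(path, channels[c])
    return parent


@dataclass(frozen=True)
class Square:
    """A flat square region: top-left corner, side length, mean intensity."""

    x: int
    y: int
    side: int
    mean: float

    def slices(self) -> Tuple[slice, slice]:
        return slice(self.y, self.y + self.side), slice(self.x, self.x + self.side)

    def overlaps(self, other: "Square") -> bool:
        return not (
            self.x + self.side <= other.x
            or other.x + other.side <= self.x
            or self.y + self.side <= other.y
            or other.y + other.side <= self.y
        )


@dataclass(frozen=True)
class SquareSceneSpec:
    """Multiple pictures of non-overlapping flat squares on a flat background."""

    pictures: Tuple[Tuple[Square, ...], ...]
    width: int = 128
    height: int = 128
    bit_depth: int = 16
    background_mean: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        pictures = tuple(tuple(p) for p in self.pictures)
        object.__setattr__(self, "pictures", pictures)
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        full = (1 << self.bit_depth) - 1
        for p, squares in enumerate(pictures, start=1):
            for i, sq in enumerate(squares):
                if not (0 <= sq.mean <= full) or not (0 <= self.background_mean <= full):
                    raise ConfigurationError(
                        f"picture {p}: intensities must lie within the {self.bit_depth}-bit range"
                    )
                if sq.x < 0 or sq.y < 0 or sq.x + sq.side > self.width or sq.y + sq.side > self.height:
                    raise ConfigurationError(f"picture {p}: square {i + 1} exceeds the frame")
                for other in squares[i + 1 :]:
                    if sq.overlaps(other):
                        raise ConfigurationError(f"picture {p}: squares overlap")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


def generate_pitfall_set(scene: SquareSceneSpec) -> List[ChannelPlane]:
    """Render the scene's pictures as single-channel planes.

    With ``noise_sd = 0`` region means equal the specified means exactly,
    enabling exact assertions about contrast-enhancement behavior.
    """
    rng = np.random.default_rng(scene.seed)
    dtype = np.uint8 if scene.bit_depth == 8 else np.uint16
    planes = []
    for squares in scene.pictures:
        values = np.full((scene.height, scene.width), scene.background_mean, dtype=np.float64)
        for sq in squares:
            values[sq.slices()] = sq.mean
        plane = _noisy(values, scene.noise_sd, rng, scene.max_value).astype(dtype)
        planes.append(ChannelPlane(plane))
    return planes


def pitfall_demo_scene(noise_sd: float = 0.0, seed: int = 0) -> SquareSceneSpec:
    """The canonical four-picture pitfall scene.

    Square 1 (the largest) has the same mean in pictures 1 and 4 and a
    3-fold lower mean in pictures 2 and 3; in picture 3 the small square 4
    is brighter than every other square of that picture.
    """
    def row(means: Sequence[float], extra: Optional[float] = None) -> Tuple[Square, ...]:
        squares = [
            Square(x=8, y=8, side=48, mean=means[0]),
            Square(x=72, y=8, side=32, mean=means[1]),
            Square(x=72, y=56, side=24, mean=means[2]),
        ]
        if extra is not None:
            squares.append(Square(x=16, y=72, side=12, mean=extra))
        return tuple(squares)

    pictures = (
        row((9000, 6000, 3000)),
        row((3000, 2000, 1000)),
        row((3000, 2000, 1000), extra=12000),
        row((9000, 6000, 3000)),
    )
    scene = SquareSceneSpec(
        pictures=pictures, width=128, height=96, bit_depth=16,
        background_mean=0.0, noise_sd=noise_sd, seed=seed,
    )
    _check_pitfall_relations(scene)
    return scene


def _check_pitfall_relations(scene: SquareSceneSpec) -> None:
    p = scene.pictures
    sq1 = [pics[0].mean for pics in p]
    if not (sq1[0] == sq1[3] and sq1[0] == 3 * sq1[1] and sq1[0] == 3 * sq1[2]):
        raise PicmontageError("pitfall scene violates the square-1 mean relations")
    pic3 = p[2]
    if len(pic3) < 4 or any(pic3[3].mean <= sq.mean for sq in pic3[:3]):
        raise PicmontageError("pitfall scene: square 4 must outshine picture 3")
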
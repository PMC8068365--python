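from pathlib import Path

import numpy as np
import pytest
import tifffile

from picmontage.image_io import ChannelPlane


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def plane8(values) -> ChannelPlane:
    return ChannelPlane(np.asarray(values, dtype=np.uint8))


def plane16(values) -> ChannelPlane:
    return ChannelPlane(np.asarray(values, dtype=np.uint16))


def write_multichannel(path: Path, channels: np.ndarray) -> Path:
    """Write a (C, H, W) stack as a multichannel TIFF."""
    tifffile.imwrite(path, channels, photometric="minisblack", metadata={"axes": "CYX"})
    return path


def write_stack(path: Path, stack: np.ndarray, axes: str) -> Path:
    tifffile.imwrite(path, stack, photometric="minisblack", metadata={"axes": axes})
    return path


def montage_grid_shape(montage_path: Path, tile_w: int, tile_h: int, sep: int = 2):
    """Recover (rows, cols) of a montage from its pixel dimensions."""
    from PIL import Image

    with Image.open(montage_path) as img:
        width, height = img.size
    assert (width + sep) % (tile_w + sep) == 0, "montage width is not a whole tile grid"
    assert (height + sep) % (tile_h + sep) == 0, "montage height is not a whole tile grid"
    return (height + sep) // (tile_h + sep), (width + sep) // (tile_w + sep)
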
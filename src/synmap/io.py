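"""File input/output: TIFF images, tile directories, puncta CSV.

Images travel as single-channel TIFF; intensities are clipped to the
configured bit depth and stored in a uint16 container on write (12-bit
data in 16-bit TIFF, matching the acquisition convention).  Tiles of a
mosaic live in one directory as ``<stem>_r{row}_c{col}.tif``.  Puncta
tables and ground truth are plain CSV via their own classes' to_csv /
from_csv.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import tifffile

from .micrograph import Micrograph, TileGrid

__all__ = [
    "read_tiff",
    "write_tiff",
    "read_tile_dir",
    "write_tile_dir",
]

_TILE_RE = re.compile(r"_r(\d+)_c(\d+)\.tiff?$", re.IGNORECASE)


def write_tiff(image: Micrograph, path) -> None:
    """Write a micrograph as uint16 TIFF, clipped to its bit depth."""
    data = np.clip(np.rint(image.pixels), 0, image.max_value).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "pixel_size_nm": image.pixel_size_nm,
            "bit_depth": image.bit_depth,
            "channel_label": image.channel_label,
        },
    )


def read_tiff(
    path,
    pixel_size_nm: float | None = None,
    bit_depth: int | None = None,
    channel_label: str | None = None,
) -> Micrograph:
    """Read a single-channel TIFF; explicit arguments override metadata."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D single-channel image, got {data.shape}")
    return Micrograph(
        data.astype(np.float64),
        pixel_size_nm=pixel_size_nm or float(meta.get("pixel_size_nm", 68.0)),
        bit_depth=bit_depth or int(meta.get("bit_depth", 12)),
        channel_label=channel_label
        if channel_label is not None
        else str(meta.get("channel_label", "")),
    )


def write_tile_dir(grid: TileGrid, directory, stem: str = "tile") -> list[Path]:
    """Write each tile as ``<stem>_r{row}_c{col}.tif`` in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for (r, c), tile in sorted(grid.tiles.items()):
        p = directory / f"{stem}_r{r}_c{c}.tif"
        write_tiff(tile, p)
        paths.append(p)
    return paths


def read_tile_dir(directory, pixel_size_nm: float | None = None) -> TileGrid:
    """Read a directory of ``*_r{row}_c{col}.tif`` tiles into a TileGrid."""
    directory = Path(directory)
    tiles = {}
    for p in sorted(directory.iterdir()):
        m = _TILE_RE.search(p.name)
        if not m:
            continue
        pos = (int(m.group(1)), int(m.group(2)))
        if pos in tiles:
            raise ValueError(f"duplicate tile position {pos} in {directory}")
        tiles[pos] = read_tiff(p, pixel_size_nm=pixel_size_nm)
    if not tiles:
        raise ValueError(f"no files matching '*_r<row>_c<col>.tif' in {directory}")
    return TileGrid(tiles=tiles)
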
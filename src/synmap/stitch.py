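"""Montage assembly from a dense grid of non-overlapping tiles.

The mosaic acquisition scans adjacent tiles without overlap, so stitching
is pure abutment in row-major order from the top-left: no registration,
blending or flat-field correction, and pixel values pass through
unmodified.  ``stitch_tiles`` is the exact inverse of
:func:`synmap.synthgen.tile_montage`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .micrograph import Micrograph, TileGrid

__all__ = ["Montage", "stitch_tiles"]


@dataclass
class Montage:
    """A stitched image plus the provenance of its tile layout."""

    image: Micrograph
    grid_shape: tuple[int, int]
    tile_shape_px: tuple[int, int]

    @property
    def pixels(self) -> np.ndarray:
        return self.image.pixels


def stitch_tiles(grid: TileGrid, row_major: bool = True) -> Montage:
    """Abut the tiles of a dense grid into one montage.

    ``row_major=True`` places tile (r, c) with its top-left corner at
    pixel (r * tile_height, c * tile_width); set False to transpose the
    layout for microscopes that scan column-major.  TileGrid construction
    already enforces density and uniform shape/pixel size/channel.
    """
    rows, cols = grid.grid_shape
    th, tw = grid.tile_shape_px
    if not row_major:
        rows, cols = cols, rows
    out = np.empty((rows * th, cols * tw), dtype=np.float64)
    for (r, c), tile in grid.tiles.items():
        rr, cc = (r, c) if row_major else (c, r)
        out[rr * th : (rr + 1) * th, cc * tw : (cc + 1) * tw] = tile.pixels
    ref = grid.tiles[(0, 0)]
    return Montage(
        image=Micrograph(
            out,
            pixel_size_nm=ref.pixel_size_nm,
            bit_depth=ref.bit_depth,
            channel_label=ref.channel_label,
        ),
        grid_shape=(rows, cols),
        tile_shape_px=(th, tw),
    )
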
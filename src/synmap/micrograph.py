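"""Core image containers: single-channel micrographs and dense tile grids.

Coordinate convention used throughout the package: continuous physical
coordinates in micrometres, origin at the top-left corner of the top-left
pixel, x along columns and y along rows.  The centre of pixel ``(i, j)``
(row i, column j) is at ``((j + 0.5) * s, (i + 0.5) * s)`` where ``s`` is
the pixel size in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Micrograph", "TileGrid"]

#: Pixel pitch of the spinning-disk acquisition this package targets (nm).
DEFAULT_PIXEL_SIZE_NM = 68.0

#: Acquisition bit depth: 12-bit data stored in a 16-bit container.
DEFAULT_BIT_DEPTH = 12

#: Native tile shape (rows, cols) of the mosaic acquisition.
DEFAULT_TILE_SHAPE = (942, 920)


@dataclass
class Micrograph:
    """One channel of a 2-D fluorescence image with physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities in arbitrary units (a.u.).
        Stored as float64 internally; quantised to uint16 only on TIFF
        export.
    pixel_size_nm
        Physical edge length of a (square) pixel in nanometres.
    bit_depth
        Bit depth of the acquisition; intensities must lie in
        ``[0, 2**bit_depth - 1]``.
    channel_label
        Marker name recorded for provenance (e.g. ``"SV2A"``).
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    bit_depth: int = DEFAULT_BIT_DEPTH
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={self.pixels.ndim}")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        if not (1 <= int(self.bit_depth) <= 16):
            raise ValueError(f"bit_depth must be in [1, 16], got {self.bit_depth}")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixels.size and self.pixels.max() > self.max_value:
            raise ValueError(
                f"intensities exceed {self.max_value} allowed by bit_depth={self.bit_depth}"
            )

    @property
    def max_value(self) -> int:
        return 2 ** int(self.bit_depth) - 1

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(width, height) of the imaged field in micrometres."""
        h, w = self.pixels.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)

    def copy(self) -> "Micrograph":
        return Micrograph(
            self.pixels.copy(), self.pixel_size_nm, self.bit_depth, self.channel_label
        )

    def same_frame(self, other: "Micrograph") -> bool:
        """True when two micrographs share shape and pixel geometry."""
        return (
            self.pixels.shape == other.pixels.shape
            and np.isclose(self.pixel_size_nm, other.pixel_size_nm)
        )


@dataclass
class TileGrid:
    """A dense (row, col)-indexed grid of abutting, non-overlapping tiles.

    All tiles must share shape, pixel size, bit depth and channel, and
    every grid position must be present (the mosaic acquisition scans
    adjacent tiles without overlap, so reassembly is pure abutment).
    """

    tiles: dict[tuple[int, int], Micrograph] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tiles:
            raise ValueError("TileGrid requires at least one tile")
        rows = sorted({r for r, _ in self.tiles})
        cols = sorted({c for _, c in self.tiles})
        if rows[0] != 0 or cols[0] != 0:
            raise ValueError("tile indices must start at (0, 0)")
        expected = {(r, c) for r in range(rows[-1] + 1) for c in range(cols[-1] + 1)}
        missing = expected - set(self.tiles)
        if missing:
            raise ValueError(f"grid is not dense; missing positions {sorted(missing)}")
        ref = self.tiles[(0, 0)]
        for pos, t in self.tiles.items():
            if t.pixels.shape != ref.pixels.shape:
                raise ValueError(
                    f"tile {pos} shape {t.pixels.shape} != {ref.pixels.shape}"
                )
            if not np.isclose(t.pixel_size_nm, ref.pixel_size_nm):
                raise ValueError(f"tile {pos} pixel size differs from tile (0, 0)")
            if t.channel_label != ref.channel_label:
                raise ValueError(
                    f"tile {pos} channel {t.channel_label!r} != {ref.channel_label!r}"
                )

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            max(r for r, _ in self.tiles) + 1,
            max(c for _, c in self.tiles) + 1,
        )

    @property
    def tile_shape_px(self) -> tuple[int, int]:
        return self.tiles[(0, 0)].pixels.shape  # type: ignore[return-value]

    @property
    def pixel_size_nm(self) -> float:
        return self.tiles[(0, 0)].pixel_size_nm

    @property
    def channel_label(self) -> str:
        return self.tiles[(0, 0)].channel_label
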
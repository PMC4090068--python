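"""Minimal single-band raster container with text (ESRI ASCII grid) I/O.

Grid convention: row-major array, top-left map origin ``(x0, y0)``,
pixel-is-area with square cells of ``pixel_m``; the extent is half-open so
map point (x, y) falls in column ``floor((x - x0)/pixel)`` and row
``floor((y0 - y)/pixel)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid"]


@dataclass
class Raster:
    data: np.ndarray      # 2D float array, row 0 = northernmost
    x0: float             # map x of the left edge
    y0: float             # map y of the TOP edge
    pixel_m: float

    def __post_init__(self) -> None:
        if self.pixel_m <= 0:
            raise ValueError("pixel_m must be > 0")
        self.data = np.asarray(self.data, np.float64)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.pixel_m, other.pixel_m)
        )

    def rowcol_to_xy(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of pixel centres."""
        x = self.x0 + (np.asarray(col, float) + 0.5) * self.pixel_m
        y = self.y0 - (np.asarray(row, float) + 0.5) * self.pixel_m
        return x, y

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x, float) - self.x0) / self.pixel_m).astype(int)
        row = np.floor((self.y0 - np.asarray(y, float)) / self.pixel_m).astype(int)
        return row, col

    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        nrows, ncols = self.shape
        yll = self.y0 - nrows * self.pixel_m
        header = (
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {self.x0!r}\nyllcorner {yll!r}\n"
            f"cellsize {self.pixel_m!r}\nNODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows = int(head["nrows"])
    ncols = int(head["ncols"])
    data = data.reshape(nrows, ncols)
    pixel = head["cellsize"]
    return Raster(
        data=data,
        x0=head["xllcorner"],
        y0=head["yllcorner"] + nrows * pixel,
        pixel_m=pixel,
    )
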
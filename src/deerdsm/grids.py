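"""Axis-aligned covariate grids on a planar (metre) coordinate system.

All grids of one synthetic landscape share origin, resolution and extent.
Row 0 is the southernmost row; cell centres sit at
``origin + (index + 0.5) * resolution``.  Rasters are stored as ESRI ASCII
grid files (plain text) so every artifact in the pipeline is inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["CovariateGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class CovariateGrid:
    """A single named covariate on a regular grid.

    Parameters
    ----------
    name : str
        Covariate label (e.g. ``"coniferous"``, ``"win_mean_temp"``).
    kind : {"continuous", "fraction"}
        Fraction grids hold per-cell cover fractions in [0, 1]; all fraction
        grids of one compositional family sum to at most 1 per cell.
    resolution : float
        Cell edge length in metres.
    origin : tuple of float
        (x, y) of the lower-left corner of the grid, metres.
    values : ndarray
        2-D array, shape (ny, nx); row 0 is the southernmost row.
    """

    name: str
    kind: str
    resolution: float
    origin: tuple[float, float]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "fraction"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.kind == "fraction":
            v = self.values
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError(f"fraction grid {self.name!r} outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the grid in metres."""
        ny, nx = self.values.shape
        return nx * self.resolution, ny * self.resolution

    def cell_index(self, x: float | np.ndarray, y: float | np.ndarray):
        """(row, col) of the cell containing planar point(s) (x, y).

        Points outside the grid are clipped to the border cell.
        """
        ny, nx = self.values.shape
        col = np.clip(((np.asarray(x) - self.origin[0]) // self.resolution).astype(int), 0, nx - 1)
        row = np.clip(((np.asarray(y) - self.origin[1]) // self.resolution).astype(int), 0, ny - 1)
        return row, col

    def value_at(self, x, y):
        """Nearest-cell lookup of the grid value at planar point(s)."""
        row, col = self.cell_index(x, y)
        return self.values[row, col]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-centre coordinates, shape (ny, nx)."""
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.resolution
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def compatible_with(self, other: "CovariateGrid") -> bool:
        return (
            self.shape == other.shape
            and self.resolution == other.resolution
            and np.allclose(self.origin, other.origin)
        )


def write_ascii_grid(grid: CovariateGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a grid as an ESRI ASCII raster (text)."""
    ny, nx = grid.values.shape
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.resolution:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        vals = np.where(np.isfinite(grid.values), grid.values, nodata)
        # ASCII grids are written north-to-south
        for row in vals[::-1]:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path: str | Path, name: str | None = None, kind: str = "continuous") -> CovariateGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    values = np.array(rows[::-1], dtype=float)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    return CovariateGrid(
        name=name or path.stem,
        kind=kind,
        resolution=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        values=values,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True
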
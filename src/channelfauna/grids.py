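"""Grid geometry and raster containers.

All analysis happens on regular square-cell grids over an abstract equal-area
plane. A :class:`GridSpec` fixes the geometry (rows, columns, cell size, origin
at the *outer* top-left corner, row-major orientation with y decreasing down
rows); a :class:`RasterLayer` couples one such spec with a named 2-D array of
values. In memory, missing cells are ``NaN``; the spec's ``nodata`` sentinel is
used only on disk.

Rasters are exchanged as ESRI ASCII grids (.asc), a plain-text single-band
format readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "RasterLayer", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square-cell grid.

    ``origin_x``/``origin_y`` locate the outer corner of the top-left cell;
    cell centers are at ``origin_x + (j + 0.5) * cell_size`` and
    ``origin_y - (i + 0.5) * cell_size`` for row ``i``, column ``j``.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError("grid must be at least 3x3")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of shape (n_rows, n_cols) with cell-center coords."""
        j = np.arange(self.n_cols)
        i = np.arange(self.n_rows)
        xs = self.origin_x + (j + 0.5) * self.cell_size
        ys = self.origin_y - (i + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its (row, col) under half-open cells.

        Cells are [x0, x0+d) x (y0-d, y0], so every in-bounds point belongs to
        exactly one cell; points outside raise ``ValueError``.
        """
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        # y decreases down rows; top edge inclusive
        row = int(np.ceil((self.origin_y - y) / self.cell_size)) - 1
        if y == self.origin_y:
            row = 0
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        try:
            self.cell_of(x, y)
        except ValueError:
            return False
        return True

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.origin_y - self.n_rows * self.cell_size


@dataclass
class RasterLayer:
    """A named single-band raster tied to a :class:`GridSpec`.

    ``values`` is float with NaN marking nodata; all finite values are data.
    """

    spec: GridSpec
    name: str
    values: np.ndarray
    units: str = ""
    season: str | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid {self.spec.shape}"
            )
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise ValueError("raster holds non-finite, non-NaN values")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~np.isnan(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        out = replace(self, values=np.asarray(values, dtype=float))
        if name is not None:
            out.name = name
        return out


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (.asc)."""
    spec = layer.spec
    vals = np.where(np.isnan(layer.values), spec.nodata, layer.values)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.y_min!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {spec.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, name: str | None = None) -> RasterLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        nodata=header["nodata_value"],
    )
    values = np.asarray(values, dtype=float).reshape(spec.shape)
    values = np.where(values == spec.nodata, np.nan, values)
    return RasterLayer(spec=spec, name=name or path.stem, values=values)
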
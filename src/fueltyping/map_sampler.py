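"""Categorical fuel-type grids: construction, point sampling, ASCII I/O.

Reproduces the provincial (50 m) versus national (250 m) map-extraction
mechanics: a polygon landscape is rasterized at each resolution by the
cell-center rule, and per-plot fuel types are extracted by point sampling.
Cell membership is half-open — a cell covers [left, left+size) x
[bottom, bottom+size) — and rows are stored north-up, which fixes every
boundary case for bit-exact tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely

from .errors import ExtentError, GeometryError
from .plot_model import FUEL_CODES, validate_code

#: Fixed code <-> integer registry for grid storage (Esri ASCII carries ints).
CODE_TO_INT: dict[str, int] = {code: i + 1 for i, code in enumerate(FUEL_CODES)}
CODE_TO_INT["O-1"] = len(FUEL_CODES) + 1
INT_TO_CODE: dict[int, str] = {v: k for k, v in CODE_TO_INT.items()}

_NODATA = -9999


@dataclass(frozen=True)
class FuelGrid:
    """North-up categorical raster of fuel-type codes.

    ``origin_x``/``origin_y`` locate the lower-left corner (m); ``cells`` is
    a (n_rows, n_cols) integer array in the CODE_TO_INT registry with row 0
    the northernmost row.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    cells: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GeometryError(f"cell size must be positive, got {self.cell_size}")
        if self.cells.ndim != 2:
            raise GeometryError("cells must be a 2-D array")
        bad = set(np.unique(self.cells)) - set(INT_TO_CODE)
        if bad:
            raise GeometryError(f"cells contain unregistered codes: {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    @classmethod
    def full(
        cls,
        code: str,
        origin_x: float,
        origin_y: float,
        cell_size: float,
        n_cols: int,
        n_rows: int,
    ) -> "FuelGrid":
        validate_code(code)
        cells = np.full((n_rows, n_cols), CODE_TO_INT[code], dtype=np.int16)
        return cls(origin_x, origin_y, cell_size, cells)

    def code_at(self, row: int, col: int) -> str:
        return INT_TO_CODE[int(self.cells[row, col])]


def sample_at(grid: FuelGrid, x: float, y: float) -> str:
    """Fuel-type code of the cell containing (x, y).

    Half-open convention: a point on a shared vertical edge belongs to the
    cell on its right; on a shared horizontal edge, to the cell above.
    """
    xmin, ymin, xmax, ymax = grid.extent
    if not (xmin <= x < xmax and ymin <= y < ymax):
        raise ExtentError(
            f"point ({x}, {y}) outside grid extent [{xmin}, {xmax}) x [{ymin}, {ymax})"
        )
    col = int(math.floor((x - grid.origin_x) / grid.cell_size))
    row_from_bottom = int(math.floor((y - grid.origin_y) / grid.cell_size))
    row = grid.n_rows - 1 - row_from_bottom
    return grid.code_at(row, col)


def sample_points(grid: FuelGrid, points: Iterable[tuple[float, float]]) -> list[str]:
    return [sample_at(grid, x, y) for x, y in points]


@dataclass(frozen=True)
class PolygonPatch:
    """One landscape patch: an exterior ring and its fuel-type code."""

    ring: tuple[tuple[float, float], ...]
    code: str

    def __post_init__(self) -> None:
        if len(self.ring) < 3:
            raise GeometryError(f"degenerate ring with {len(self.ring)} vertices")
        validate_code(self.code)

    def geometry(self) -> shapely.Polygon:
        poly = shapely.Polygon(self.ring)
        if not poly.is_valid or poly.area == 0:
            raise GeometryError(f"invalid polygon ring for code {self.code}")
        return poly


def square_patch(cx: float, cy: float, half_side: float, code: str) -> PolygonPatch:
    """Axis-aligned square patch centered on (cx, cy)."""
    h = half_side
    ring = ((cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h))
    return PolygonPatch(ring=ring, code=code)


def rasterize_polygons(
    polygons: Sequence[PolygonPatch],
    cell_size: float,
    extent: tuple[float, float, float, float] | None = None,
    background: str = "NF",
) -> FuelGrid:
    """Rasterize ordered polygons by the cell-center rule.

    Each cell takes the code of the last polygon (in list order) covering its
    center; uncovered cells get ``background``.  When no extent is given, the
    union bounds of the polygons are padded out to whole cells.
    """
    geoms = [p.geometry() for p in polygons]
    if extent is None:
        if not geoms:
            raise GeometryError("cannot infer an extent from an empty polygon list")
        xmin = min(g.bounds[0] for g in geoms)
        ymin = min(g.bounds[1] for g in geoms)
        xmax = max(g.bounds[2] for g in geoms)
        ymax = max(g.bounds[3] for g in geoms)
    else:
        xmin, ymin, xmax, ymax = extent
    n_cols = max(1, int(math.ceil((xmax - xmin) / cell_size)))
    n_rows = max(1, int(math.ceil((ymax - ymin) / cell_size)))
    cells = np.full((n_rows, n_cols), CODE_TO_INT[background], dtype=np.int16)
    # Cell centers, row 0 = northernmost.
    cx = xmin + (np.arange(n_cols) + 0.5) * cell_size
    cy = ymin + (n_rows - 1 - np.arange(n_rows) + 0.5) * cell_size
    cxx, cyy = np.meshgrid(cx, cy)
    for patch, geom in zip(polygons, geoms):
        mask = shapely.intersects_xy(geom, cxx, cyy)
        cells[mask] = CODE_TO_INT[patch.code]
    return FuelGrid(origin_x=xmin, origin_y=ymin, cell_size=cell_size, cells=cells)


# --- Esri ASCII grid I/O ----------------------------------------------------


def write_ascii_grid(grid: FuelGrid, path: str | Path) -> None:
    """Write an Esri ASCII grid (.asc) with the integer code registry."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        for row in grid.cells:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> FuelGrid:
    """Read an Esri ASCII grid written by :func:`write_ascii_grid`."""
    with open(path, encoding="utf-8") as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        cells = np.loadtxt(fh, dtype=np.int16, ndmin=2)
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    if cells.shape != (n_rows, n_cols):
        raise GeometryError(
            f"grid body shape {cells.shape} does not match header ({n_rows}, {n_cols})"
        )
    return FuelGrid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        cells=cells,
    )
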
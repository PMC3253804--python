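"""Geographic analysis grid and circular-neighborhood re-sampling.

The central device of the pipeline: every georeferenced tree is copied
("re-sampled") into all grid cells whose centers fall inside a circle of
fixed diameter around the tree, so that each cell's statistics summarize
the surrounding landscape rather than the handful of trees that happen to
fall inside the cell itself.  With 10-arcminute cells and a one-degree
circle the stencil contains exactly 32 cells, so n trees yield 32·n
re-sampled records.

Coordinates are WGS84 decimal degrees throughout; distances are measured
in degree space (no geodesic correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .genotype_io import GenotypeTable

__all__ = [
    "GridSpec",
    "Raster",
    "NeighborhoodMask",
    "CellAssignment",
    "make_grid",
    "neighborhood_mask",
    "resample_trees",
    "cell_counts",
    "align_raster",
]

DEFAULT_CELL_SIZE = 1.0 / 6.0  # 10 arcminutes in degrees
NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid with half-open cells.

    Cell (col, row) spans [xll + col·Δ, xll + (col+1)·Δ) ×
    [yll + row·Δ, yll + (row+1)·Δ); row 0 is the southernmost row.
    A point on a cell boundary therefore belongs to the cell on its
    east/north side.
    """

    xll: float
    yll: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def xur(self) -> float:
        return self.xll + self.n_cols * self.cell_size

    @property
    def yur(self) -> float:
        return self.yll + self.n_rows * self.cell_size

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(col, row) of the half-open cell containing each point."""
        col = np.floor((np.asarray(lon, dtype=float) - self.xll) / self.cell_size)
        row = np.floor((np.asarray(lat, dtype=float) - self.yll) / self.cell_size)
        return col.astype(np.int64), row.astype(np.int64)

    def nearest_node(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Index of the grid node (cell corner) nearest to each point.

        Ties (a point exactly halfway between nodes, i.e. on a cell
        center) resolve to the east/north node, mirroring the half-open
        cell rule.
        """
        col = np.floor((np.asarray(lon, dtype=float) - self.xll) / self.cell_size + 0.5)
        row = np.floor((np.asarray(lat, dtype=float) - self.yll) / self.cell_size + 0.5)
        return col.astype(np.int64), row.astype(np.int64)

    def cell_id(self, col, row):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def cell_col_row(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id % self.n_cols, cell_id // self.n_cols

    def cell_center(self, col, row) -> tuple[np.ndarray, np.ndarray]:
        lon = self.xll + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.yll + (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.xll)
            & (lon < self.xur)
            & (lat >= self.yll)
            & (lat < self.yur)
        )

    def cell_polygon(self, col: int, row: int) -> list[tuple[float, float]]:
        """Corner ring of a cell (closed, counter-clockwise)."""
        x0 = self.xll + col * self.cell_size
        y0 = self.yll + row * self.cell_size
        d = self.cell_size
        return [(x0, y0), (x0 + d, y0), (x0 + d, y0 + d), (x0, y0 + d), (x0, y0)]


@dataclass
class Raster:
    """One value per grid cell; ``values[row, col]`` with row 0 southernmost."""

    grid: GridSpec
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )

    def value_at(self, lon, lat) -> np.ndarray:
        """Raster value at each point; nodata outside the extent."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        col, row = self.grid.cell_index(lon, lat)
        inside = self.grid.contains(lon, lat)
        out = np.full(lon.shape, self.nodata, dtype=float)
        out[inside] = self.values[row[inside], col[inside]]
        return out

    def is_nodata(self) -> np.ndarray:
        return np.isclose(self.values, self.nodata) | ~np.isfinite(self.values)


@dataclass(frozen=True)
class NeighborhoodMask:
    """Fixed stencil of cell offsets around a grid node.

    Offsets are (col, row) cell indices relative to the anchor node: the
    cell with offset (i, j) spans [iΔ, (i+1)Δ) × [jΔ, (j+1)Δ) in node
    coordinates.  A cell belongs to the mask iff its center lies strictly
    within diameter/2 of the node.
    """

    offsets: tuple[tuple[int, int], ...]
    cell_size: float
    diameter: float

    def __len__(self) -> int:
        return len(self.offsets)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.offsets)


def make_grid(
    extent: Sequence[float],
    cell_size: float = DEFAULT_CELL_SIZE,
    origin_snap: bool = True,
) -> GridSpec:
    """Build the grid covering ``extent`` = (xmin, ymin, xmax, ymax).

    With ``origin_snap`` the lower-left origin is pulled down to the
    largest multiple of ``cell_size`` not exceeding the extent minimum,
    which makes cell boundaries (and hence all per-cell statistics)
    independent of the exact sampling extent.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    xmin, ymin, xmax, ymax = map(float, extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent is degenerate")
    if origin_snap:
        xll = math.floor(xmin / cell_size + 1e-9) * cell_size
        yll = math.floor(ymin / cell_size + 1e-9) * cell_size
    else:
        xll, yll = xmin, ymin
    n_cols = max(1, math.ceil((xmax - xll) / cell_size - 1e-9))
    n_rows = max(1, math.ceil((ymax - yll) / cell_size - 1e-9))
    return GridSpec(xll=xll, yll=yll, cell_size=cell_size, n_cols=n_cols, n_rows=n_rows)


def neighborhood_mask(
    cell_size: float = DEFAULT_CELL_SIZE, diameter: float = 1.0
) -> NeighborhoodMask:
    """Cells whose centers lie strictly within diameter/2 of a grid node.

    For cell_size = 1/6° and diameter = 1° this is the 6×6 block of cells
    around the node minus its four corners: 32 cells.
    """
    if diameter < cell_size:
        raise ValueError("diameter must be at least one cell size")
    radius = diameter / 2.0
    m = math.ceil(radius / cell_size) + 1
    offsets = []
    for i in range(-m, m):
        for j in range(-m, m):
            cx = (i + 0.5) * cell_size
            cy = (j + 0.5) * cell_size
            if cx * cx + cy * cy < radius * radius - 1e-12:
                offsets.append((i, j))
    offsets.sort()
    return NeighborhoodMask(
        offsets=tuple(offsets), cell_size=cell_size, diameter=diameter
    )


@dataclass
class CellAssignment:
    """Record-level mapping of re-sampled trees to grid cells.

    One record per (tree, cell) pair.  The grid is extended (never
    clipped) so border trees still contribute a full stencil of records;
    ``grid`` is therefore the possibly-extended grid, and
    ``len(assignment) == n_samples × |mask|`` always holds under the
    node-anchored stencil.
    """

    grid: GridSpec
    sample_index: np.ndarray  # (n_records,) index into the genotype table
    cell_col: np.ndarray
    cell_row: np.ndarray
    sample_ids: tuple[str, ...]
    mask: NeighborhoodMask
    _cell_id: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._cell_id = np.asarray(self.grid.cell_id(self.cell_col, self.cell_row))

    def __len__(self) -> int:
        return len(self.sample_index)

    @property
    def cell_id(self) -> np.ndarray:
        return self._cell_id

    def cells_of(self, sample_id: str) -> np.ndarray:
        idx = self.sample_ids.index(sample_id)
        return np.sort(self._cell_id[self.sample_index == idx])

    def samples_in(self, cell_id: int) -> list[str]:
        sel = self.sample_index[self._cell_id == cell_id]
        return [self.sample_ids[i] for i in sel]

    def occupied_cells(self) -> np.ndarray:
        return np.unique(self._cell_id)


def resample_trees(
    table: "GenotypeTable",
    grid: GridSpec,
    mask: NeighborhoodMask,
    anchor: str = "node",
) -> CellAssignment:
    """Copy each tree into every cell of its circular neighborhood.

    ``anchor="node"`` (default) snaps each tree to its nearest grid node
    and applies the fixed stencil, so every tree lands in exactly
    ``len(mask)`` cells regardless of its position within its cell.
    ``anchor="tree"`` centers the circle on the tree itself (a cell is
    included iff its center lies strictly within diameter/2 of the tree),
    which yields a position-dependent 29–32 cells for the default
    geometry.
    """
    if anchor not in ("node", "tree"):
        raise ValueError(f"unknown anchor rule: {anchor!r}")
    n = len(table)
    if anchor == "node":
        node_col, node_row = grid.nearest_node(table.lon, table.lat)
        di = np.array([o[0] for o in mask.offsets], dtype=np.int64)
        dj = np.array([o[1] for o in mask.offsets], dtype=np.int64)
        cols = (node_col[:, None] + di[None, :]).ravel()
        rows = (node_row[:, None] + dj[None, :]).ravel()
        samples = np.repeat(np.arange(n, dtype=np.int64), len(mask))
    else:
        radius = mask.diameter / 2.0
        d = grid.cell_size
        cols_l, rows_l, samples_l = [], [], []
        for i in range(n):
            # candidate block around the tree, then strict center-in-circle
            c0 = math.floor((table.lon[i] - grid.xll) / d - radius / d) - 1
            r0 = math.floor((table.lat[i] - grid.yll) / d - radius / d) - 1
            span = int(math.ceil(2 * radius / d)) + 3
            cc, rr = np.meshgrid(
                np.arange(c0, c0 + span), np.arange(r0, r0 + span), indexing="ij"
            )
            cx = grid.xll + (cc + 0.5) * d - table.lon[i]
            cy = grid.yll + (rr + 0.5) * d - table.lat[i]
            keep = cx * cx + cy * cy < radius * radius - 1e-12
            cols_l.append(cc[keep].ravel())
            rows_l.append(rr[keep].ravel())
            samples_l.append(np.full(int(keep.sum()), i, dtype=np.int64))
        cols = np.concatenate(cols_l) if cols_l else np.empty(0, dtype=np.int64)
        rows = np.concatenate(rows_l) if rows_l else np.empty(0, dtype=np.int64)
        samples = np.concatenate(samples_l) if samples_l else np.empty(0, dtype=np.int64)

    # extend the grid so no record falls outside
    pad_w = max(0, -int(cols.min(initial=0)))
    pad_s = max(0, -int(rows.min(initial=0)))
    pad_e = max(0, int(cols.max(initial=grid.n_cols - 1)) - (grid.n_cols - 1))
    pad_n = max(0, int(rows.max(initial=grid.n_rows - 1)) - (grid.n_rows - 1))
    if pad_w or pad_s or pad_e or pad_n:
        grid = GridSpec(
            xll=grid.xll - pad_w * grid.cell_size,
            yll=grid.yll - pad_s * grid.cell_size,
            cell_size=grid.cell_size,
            n_cols=grid.n_cols + pad_w + pad_e,
            n_rows=grid.n_rows + pad_s + pad_n,
        )
        cols = cols + pad_w
        rows = rows + pad_s
    return CellAssignment(
        grid=grid,
        sample_index=samples,
        cell_col=cols,
        cell_row=rows,
        sample_ids=tuple(table.ids),
        mask=mask,
    )


def align_raster(raster: Raster, grid: GridSpec) -> Raster:
    """Re-index a raster onto another grid of the same cell size.

    Values are looked up at cell centers, so the two grids must share the
    cell size (and, to be meaningful, origin alignment — as snapped grids
    do); target cells outside the source extent become nodata.
    """
    if not math.isclose(raster.grid.cell_size, grid.cell_size):
        raise ValueError("align_raster requires equal cell sizes")
    cols, rows = np.meshgrid(np.arange(grid.n_cols), np.arange(grid.n_rows))
    lon, lat = grid.cell_center(cols, rows)
    values = raster.value_at(lon.ravel(), lat.ravel()).reshape(grid.n_rows, grid.n_cols)
    return Raster(grid=grid, values=values, nodata=raster.nodata)


def cell_counts(assignment: CellAssignment, grid: GridSpec | None = None) -> Raster:
    """Raster of re-sampled tree counts per cell; empty cells are nodata."""
    grid = grid or assignment.grid
    if grid is not assignment.grid and (
        grid.cell_size != assignment.grid.cell_size
        or grid.xll != assignment.grid.xll
        or grid.yll != assignment.grid.yll
        or grid.n_cols != assignment.grid.n_cols
        or grid.n_rows != assignment.grid.n_rows
    ):
        raise ValueError("assignment was not built on the supplied grid")
    counts = np.bincount(assignment.cell_id, minlength=grid.n_cells).astype(float)
    values = counts.reshape(grid.n_rows, grid.n_cols)
    values[values == 0] = NODATA
    return Raster(grid=grid, values=values, nodata=NODATA)
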
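"""Geographic grids and raster stacks.

All layers in a run share one :class:`GridSpec` (geographic coordinates,
row 0 = north).  Nodata is carried as an explicit boolean mask alongside the
value array; any arithmetic on nodata cells yields nodata.  On disk, grids are
stored as single-band ESRI ASCII rasters (a plain-text format readable by any
GIS package).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

# mean length of one degree of latitude, km (spherical earth)
KM_PER_DEGREE = 111.195


class GridError(ValueError):
    """Invalid grid specification or mismatched grids."""


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid.

    ``origin_lon``/``origin_lat`` locate the *north-west corner* of the grid
    (not a cell center).  ``cell_size`` is in decimal degrees; the grid is
    square-celled.  ``nodata`` is the sentinel written to disk for masked
    cells.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lon: float
    origin_lat: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError(f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # -- extent ------------------------------------------------------------
    @property
    def lon_max(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @property
    def lat_min(self) -> float:
        return self.origin_lat - self.n_rows * self.cell_size

    def contains(self, lon: float, lat: float) -> bool:
        return (self.origin_lon <= lon <= self.lon_max
                and self.lat_min <= lat <= self.origin_lat)

    # -- cell geometry -----------------------------------------------------
    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size
        lat = self.origin_lat - (rows + 0.5) * self.cell_size
        return np.broadcast_to(lon, self.shape).copy(), np.broadcast_to(lat[:, None], self.shape).copy()

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell containing a point.

        Half-open convention: a point lying exactly on an interior cell edge
        resolves to the north-west cell of that edge.
        """
        if not self.contains(lon, lat):
            raise GridError(f"point ({lon}, {lat}) outside grid extent")
        x = (lon - self.origin_lon) / self.cell_size
        y = (self.origin_lat - lat) / self.cell_size
        col = int(math.floor(x))
        row = int(math.floor(y))
        if col == x and col > 0:   # on a vertical edge -> west cell
            col -= 1
        if row == y and row > 0:   # on a horizontal edge -> north cell
            row -= 1
        col = min(col, self.n_cols - 1)
        row = min(row, self.n_rows - 1)
        return row, col

    def cell_areas_km2(self) -> np.ndarray:
        """Per-cell area in km^2, with a cos(latitude) correction at the
        cell-center latitude (geographic grids shrink east-west towards the
        poles)."""
        _, lat = self.cell_centers()
        dy = self.cell_size * KM_PER_DEGREE
        dx = self.cell_size * KM_PER_DEGREE * np.cos(np.radians(lat))
        return dx * dy


@dataclass
class Raster:
    """A single-band grid: float values plus a nodata mask (True = nodata)."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise GridError("mask shape does not match grid shape")

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.mask.copy())

    def value_at(self, lon: float, lat: float) -> float:
        """Value of the cell whose center is nearest the point (i.e. the cell
        containing it); NaN when that cell is nodata."""
        row, col = self.grid.cell_index(lon, lat)
        if self.mask[row, col]:
            return float("nan")
        return float(self.values[row, col])


class RasterStack:
    """Named co-registered environmental layers for one scenario x date.

    Each layer carries a *kind* ('temperature', 'precipitation' or
    'seasonality') that determines how climate-change deltas apply to it:
    additive for temperatures and seasonality, multiplicative for
    precipitation.
    """

    def __init__(self, grid: GridSpec, scenario_id: str = "baseline",
                 date: str = "2000") -> None:
        self.grid = grid
        self.scenario_id = scenario_id
        self.date = date
        self._layers: dict[str, Raster] = {}
        self.layer_kinds: dict[str, str] = {}

    def add_layer(self, name: str, raster: Raster, kind: str) -> None:
        if kind not in ("temperature", "precipitation", "seasonality"):
            raise GridError(f"unknown layer kind {kind!r}")
        if raster.grid != self.grid:
            raise GridError(f"layer {name!r} does not share the stack GridSpec")
        self._layers[name] = raster
        self.layer_kinds[name] = kind

    @property
    def layer_names(self) -> list[str]:
        return list(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> Raster:
        try:
            return self._layers[name]
        except KeyError:
            raise KeyError(f"stack has no layer {name!r}; has {self.layer_names}") from None

    def __iter__(self) -> Iterator[tuple[str, Raster]]:
        return iter(self._layers.items())

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def mask(self) -> np.ndarray:
        """Union of the layer nodata masks."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for r in self._layers.values():
            m |= r.mask
        return m

    def env_matrix(self, rows: np.ndarray, cols: np.ndarray,
                   variables: list[str] | None = None) -> np.ndarray:
        """Environment vectors at cell indices: shape (n_points, n_variables)."""
        names = variables if variables is not None else self.layer_names
        out = np.empty((len(rows), len(names)))
        for j, name in enumerate(names):
            out[:, j] = self[name].values[rows, cols]
        return out

    def copy(self, scenario_id: str | None = None, date: str | None = None) -> "RasterStack":
        out = RasterStack(self.grid,
                          scenario_id if scenario_id is not None else self.scenario_id,
                          date if date is not None else self.date)
        for name, r in self._layers.items():
            out.add_layer(name, r.copy(), self.layer_kinds[name])
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    g = raster.grid
    vals = np.where(raster.mask, g.nodata, raster.values)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_lon!r}\n"
        f"yllcorner {g.lat_min!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {g.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", -9999.0)
    grid = GridSpec(
        n_rows=n_rows, n_cols=n_cols, cell_size=header["cellsize"],
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * header["cellsize"],
        nodata=nodata,
    )
    mask = vals == nodata
    return Raster(grid, vals, mask)
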
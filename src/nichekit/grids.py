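"""Gridded data containers: georeferenced raster stacks and suitability grids.

Rasters are stored as plain 2-D numpy arrays with row 0 at the top (north)
edge, matching the ESRI ASCII grid convention used for on-disk exchange.
The grid origin is the lower-left corner of the lower-left cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    ``origin_x``/``origin_y`` are the coordinates of the lower-left corner;
    ``cell_size`` is the edge length of a (square) cell in map units.
    ``crs_label`` is free text; labels containing ``"4326"`` or ``"wgs"``
    (case-insensitive) mark geographic degrees, anything else is treated as
    planar (km) for distance purposes.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs_label: str = "planar_km"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def is_geographic(self) -> bool:
        label = self.crs_label.lower()
        return "4326" in label or "wgs" in label or "degree" in label

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Per-row cell-center y coordinates (row 0 = northernmost)."""
        return self.origin_y + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) by the floor((coord-origin)/cell) rule.

        Points on an interior cell boundary belong to the cell on the
        greater-coordinate side, by the floor convention. Out-of-extent points
        yield indices outside [0, n_rows) / [0, n_cols).
        """
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size).astype(int)
        row_from_bottom = np.floor(
            (np.asarray(y, float) - self.origin_y) / self.cell_size
        ).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y


@dataclass
class Layer:
    """One environmental raster band."""

    name: str
    kind: str  # continuous | categorical
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"layer kind must be continuous or categorical, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("layer values must be a 2-D array")


@dataclass
class RasterStack:
    """An aligned set of environmental layers on a shared grid.

    ``nodata_mask`` is True where cells are invalid; masked cells are
    excluded from every downstream sum.
    """

    grid: GridSpec
    layers: list[Layer]
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        for layer in self.layers:
            if layer.values.shape != self.grid.shape:
                raise ValueError(
                    f"layer {layer.name!r} shape {layer.values.shape} does not match "
                    f"grid {self.grid.shape}"
                )
            if layer.kind == CATEGORICAL:
                vals = layer.values[~self.nodata_mask]
                if not np.allclose(vals, np.round(vals)):
                    raise ValueError(f"categorical layer {layer.name!r} has non-integer codes")

    @property
    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    @property
    def kinds(self) -> dict[str, str]:
        return {layer.name: layer.kind for layer in self.layers}

    def get(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(f"no layer named {name!r}; have {self.layer_names}")

    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def env_table(self) -> "np.ndarray":
        """Stack layer values into an (n_cells, n_layers) array, C row order."""
        return np.column_stack([layer.values.ravel() for layer in self.layers])


@dataclass
class SuitabilityGrid:
    """Nonnegative per-cell habitat suitability on a grid."""

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        valid = self.values[~self.nodata_mask]
        if valid.size and (np.any(~np.isfinite(valid)) or np.any(valid < 0)):
            raise ValueError("suitability must be finite and nonnegative on unmasked cells")


@dataclass
class ProbabilityGrid:
    """A suitability surface normalized to sum to one over its valid cells.

    The operand of the overlap statistics: both grids in a comparison must
    share the same valid-cell set.
    """

    grid: GridSpec
    values: np.ndarray  # 2-D; zero on masked cells
    nodata_mask: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        total = self.values[~self.nodata_mask].sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities must sum to 1 over valid cells, got {total}")

    def flat(self) -> np.ndarray:
        """Probabilities over valid cells, in C row order."""
        return self.values[~self.nodata_mask]


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec,
                     nodata_mask: np.ndarray | None = None,
                     nodata_value: float = -9999.0) -> None:
    """Write one band as an ESRI ASCII grid (.asc)."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if nodata_mask is not None:
        out[np.asarray(nodata_mask, bool)] = nodata_value
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {float(grid.origin_x)!r}\n"
        f"yllcorner {float(grid.origin_y)!r}\n"
        f"cellsize {float(grid.cell_size)!r}\n"
        f"NODATA_value {float(nodata_value)!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path, crs_label: str = "planar_km"
                    ) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; returns (values, grid, nodata_mask)."""
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in keys:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    data = data.reshape(n_rows, n_cols)
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header.get("xllcorner", 0.0),
        origin_y=header.get("yllcorner", 0.0),
        cell_size=header.get("cellsize", 1.0),
        crs_label=crs_label,
    )
    nodata = header.get("nodata_value")
    mask = np.zeros(data.shape, bool) if nodata is None else (data == nodata)
    return data, grid, mask


def write_stack(directory: str | Path, stack: RasterStack) -> list[Path]:
    """Write every layer of a stack as <name>.asc under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for layer in stack.layers:
        p = directory / f"{layer.name}.asc"
        write_ascii_grid(p, layer.values, stack.grid, stack.nodata_mask)
        paths.append(p)
    return paths


def read_stack(paths: Iterable[str | Path], kinds: dict[str, str] | None = None,
               crs_label: str = "planar_km") -> RasterStack:
    """Assemble a RasterStack from ASCII grids sharing one geometry.

    ``kinds`` maps layer name (file stem) to continuous/categorical;
    unlisted layers default to continuous. Nodata masks are unioned.
    """
    kinds = kinds or {}
    layers: list[Layer] = []
    grid: GridSpec | None = None
    mask: np.ndarray | None = None
    for path in paths:
        path = Path(path)
        values, g, m = read_ascii_grid(path, crs_label=crs_label)
        if grid is None:
            grid, mask = g, m
        else:
            if (g.n_rows, g.n_cols, g.origin_x, g.origin_y, g.cell_size) != (
                    grid.n_rows, grid.n_cols, grid.origin_x, grid.origin_y, grid.cell_size):
                raise ValueError(f"raster {path.name} is not aligned with the reference grid")
            mask = mask | m
        layers.append(Layer(path.stem, kinds.get(path.stem, CONTINUOUS), values))
    if grid is None:
        raise ValueError("no raster paths given")
    return RasterStack(grid=grid, layers=layers, nodata_mask=mask)
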
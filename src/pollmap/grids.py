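"""Planar grids and raster stacks.

All spatial data in this package live on a single projected, planar grid of
square cells (default 1 km). Cells are indexed ``(row, col)`` with row 0 the
southernmost row; a cell covers the half-open square
``[x, x + cell_size) x [y, y + cell_size)`` so that every point belongs to
exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["GridSpec", "PredictorStack"]

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid of square cells.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; must be >= 1.
    cell_size
        Cell edge length in km (default 1).
    origin
        ``(easting, northing)`` of the lower-left corner, km.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid dimensions must be positive, got {self.n_rows}x{self.n_cols}"
            )
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Easting and northing of every cell centre, each shaped like the grid."""
        cs = self.cell_size
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * cs
        ys = y0 + (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def centers_of(self, cells: np.ndarray) -> np.ndarray:
        """Centres of ``cells`` (an ``(n, 2)`` array of (row, col)) as (easting, northing)."""
        cells = np.atleast_2d(np.asarray(cells))
        cs = self.cell_size
        x0, y0 = self.origin
        east = x0 + (cells[:, 1] + 0.5) * cs
        north = y0 + (cells[:, 0] + 0.5) * cs
        return np.column_stack([east, north])

    def point_to_cell(self, easting: np.ndarray, northing: np.ndarray) -> np.ndarray:
        """Map points (km) to (row, col); half-open cell intervals."""
        easting = np.asarray(easting, dtype=float)
        northing = np.asarray(northing, dtype=float)
        col = np.floor((easting - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((northing - self.origin[1]) / self.cell_size).astype(int)
        return np.column_stack([np.atleast_1d(row), np.atleast_1d(col)])

    def contains_cells(self, cells: np.ndarray) -> np.ndarray:
        cells = np.atleast_2d(np.asarray(cells))
        return (
            (cells[:, 0] >= 0)
            & (cells[:, 0] < self.n_rows)
            & (cells[:, 1] >= 0)
            & (cells[:, 1] < self.n_cols)
        )

    def all_cells(self) -> np.ndarray:
        """Every (row, col) pair, shape ``(n_cells, 2)``."""
        rows, cols = np.indices(self.shape)
        return np.column_stack([rows.ravel(), cols.ravel()])

    def coarsen(self, factor: int) -> "GridSpec":
        if self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"grid {self.shape} not divisible by coarsening factor {factor}"
            )
        return GridSpec(
            self.n_rows // factor,
            self.n_cols // factor,
            self.cell_size * factor,
            self.origin,
        )

    def refine(self, factor: int) -> "GridSpec":
        return GridSpec(
            self.n_rows * factor,
            self.n_cols * factor,
            self.cell_size / factor,
            self.origin,
        )


@dataclass
class PredictorStack:
    """Named raster layers sharing one :class:`GridSpec`.

    Layers are 2-D float arrays; ``kinds`` marks each layer ``continuous`` or
    ``categorical``. NaN encodes nodata.
    """

    spec: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            self._check_layer(name, arr)
            self.kinds.setdefault(name, "continuous")

    def _check_layer(self, name: str, arr: np.ndarray) -> None:
        if arr.shape != self.spec.shape:
            raise ValueError(
                f"layer {name!r} has shape {arr.shape}, grid is {self.spec.shape}"
            )
        if np.all(np.isnan(arr)):
            raise ValueError(f"layer {name!r} is all nodata")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def add(self, name: str, arr: np.ndarray, kind: str = "continuous") -> None:
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        arr = np.asarray(arr, dtype=float)
        self._check_layer(name, arr)
        self.layers[name] = arr
        self.kinds[name] = kind

    def matrix(self, cells: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Raw predictor values at ``cells`` as an ``(n_cells, n_layers)`` matrix."""
        cells = np.atleast_2d(np.asarray(cells))
        names = self.names if names is None else names
        cols = [self.layers[n][cells[:, 0], cells[:, 1]] for n in names]
        return np.column_stack(cols) if cols else np.empty((len(cells), 0))

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"unknown layers: {missing}")
        return PredictorStack(
            self.spec,
            {n: self.layers[n] for n in names},
            {n: self.kinds[n] for n in names},
        )


def as_mapping(stack: PredictorStack | Mapping[str, np.ndarray]) -> Mapping[str, np.ndarray]:
    if isinstance(stack, PredictorStack):
        return stack.layers
    return stack
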
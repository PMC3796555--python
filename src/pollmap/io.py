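"""Raster and table I/O.

Rasters are exchanged as single-band ESRI ASCII grids (``.asc``): a plain-text
format with a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by rows of cell values written north to south. Values
are stored at float32 precision with nodata = -9999. Occurrence and apiary
tables are CSV with a header row.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import NODATA, GridSpec, PredictorStack

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
    "read_occurrence_csv",
    "write_occurrence_csv",
]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_ascii_grid(
    path: str | Path, values: np.ndarray, spec: GridSpec, nodata: float = NODATA
) -> Path:
    """Write one layer as an ESRI ASCII grid; NaN cells become ``nodata``."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float32)
    if values.shape != spec.shape:
        raise ValueError(f"values shape {values.shape} != grid {spec.shape}")
    out = values.copy()
    out[np.isnan(out)] = np.float32(nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin[0]!r}\n")
        fh.write(f"yllcorner {spec.origin[1]!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        # rows on disk run north->south; row 0 in memory is the southernmost
        np.savetxt(fh, out[::-1], fmt="%.9g")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise ValueError(f"{path}: malformed ASCII grid header, missing {missing}")
        body = np.loadtxt(fh, dtype=np.float32, ndmin=2)
    spec = GridSpec(
        int(header["nrows"]),
        int(header["ncols"]),
        header["cellsize"],
        (header["xllcorner"], header["yllcorner"]),
    )
    if body.shape != spec.shape:
        raise ValueError(f"{path}: body shape {body.shape} != header {spec.shape}")
    values = body[::-1].astype(np.float32)
    nodata = header["nodata_value"]
    values[values == np.float32(nodata)] = np.nan
    return values, spec, nodata


def write_stack(directory: str | Path, stack: PredictorStack) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [
        write_ascii_grid(directory / f"{name}.asc", stack[name], stack.spec)
        for name in stack.names
    ]


def read_stack(paths: dict[str, str | Path]) -> PredictorStack:
    """Read named layers into one stack; all files must share one grid."""
    stack: PredictorStack | None = None
    first_name = ""
    for name, path in paths.items():
        values, spec, _ = read_ascii_grid(path)
        if stack is None:
            stack = PredictorStack(spec, {name: values.astype(float)})
            first_name = name
        else:
            if spec != stack.spec:
                raise ValueError(
                    f"grid mismatch between layers {first_name!r} ({stack.spec}) "
                    f"and {name!r} ({spec})"
                )
            stack.add(name, values.astype(float))
    if stack is None:
        raise ValueError("no layers given")
    return stack


# CSV columns for occurrence tables on disk; coordinates in metres there,
# in km in memory.
OCC_COLUMNS = ["species", "easting_m", "northing_m", "year", "accuracy_m"]


def write_occurrence_csv(path: str | Path, records: pd.DataFrame) -> Path:
    out = pd.DataFrame(
        {
            "species": records["species"],
            "easting_m": records["easting"] * 1000.0,
            "northing_m": records["northing"] * 1000.0,
            "year": records["year"],
            "accuracy_m": records["accuracy"],
        }
    )
    out.to_csv(path, index=False)
    return Path(path)


def read_occurrence_csv(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    missing = [c for c in OCC_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: occurrence CSV missing columns {missing}")
    if (raw["accuracy_m"] <= 0).any():
        warnings.warn(f"{path}: dropping records with non-positive accuracy")
        raw = raw[raw["accuracy_m"] > 0]
    return pd.DataFrame(
        {
            "species": raw["species"],
            "easting": raw["easting_m"] / 1000.0,
            "northing": raw["northing_m"] / 1000.0,
            "year": raw["year"].astype(int),
            "accuracy": raw["accuracy_m"].astype(float),
        }
    )
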
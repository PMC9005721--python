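"""ESRI ASCII grid I/O and per-point covariate extraction.

A :class:`Grid` is a single raster (row 0 = northernmost row) with a NODATA
mask; an :class:`EnvStack` is an ordered set of header-aligned grids keyed by
variable name (e.g. ``BIO1``..``BIO19`` bioclimatic layers plus soil
properties).  Stacking requires exact header equality — no resampling is
performed; all layers are assumed pre-unified to one grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GridHeader",
    "Grid",
    "EnvStack",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "extract_values",
]


class GridFormatError(ValueError):
    """Raised when an ASCII grid file violates the format contract."""


@dataclass(frozen=True)
class GridHeader:
    """Geometry of an ESRI ASCII grid.

    ``xllcorner``/``yllcorner`` are the west/south corner of the extent in
    decimal degrees (WGS84); ``cellsize`` is the square cell edge in degrees.
    Header equality is the alignment criterion for stacking.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("ncols and nrows must be >= 1")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be > 0")

    @property
    def ytop(self) -> float:
        """Latitude of the northern edge."""
        return self.yllcorner + self.nrows * self.cellsize

    @property
    def xright(self) -> float:
        return self.xllcorner + self.ncols * self.cellsize

    def aligned_with(self, other: "GridHeader") -> bool:
        """Exact geometry match (NODATA sentinel may differ)."""
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and self.xllcorner == other.xllcorner
            and self.yllcorner == other.yllcorner
            and self.cellsize == other.cellsize
        )

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        """Lon/lat of cell centres for (row, col) arrays, row 0 = north."""
        lon = self.xllcorner + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.ytop - (np.asarray(row) + 0.5) * self.cellsize
        return lon, lat


@dataclass
class Grid:
    """A single raster layer: header, values and NODATA mask.

    ``values[0, :]`` is the northernmost row.  ``mask`` is True on NODATA
    cells; masked cells never enter statistics.
    """

    header: GridHeader
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.header.nrows, self.header.ncols):
            raise ValueError(
                f"values shape {self.values.shape} does not match header "
                f"({self.header.nrows}, {self.header.ncols})"
            )
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    @property
    def unmasked(self) -> np.ndarray:
        """Flat array of valid cell values."""
        return self.values[~self.mask]

    def copy(self) -> "Grid":
        return Grid(self.header, self.values.copy(), self.mask.copy())


class EnvStack:
    """Ordered map variable name -> Grid with identical headers."""

    def __init__(self, variables: Mapping[str, Grid] | Iterable[tuple[str, Grid]]):
        items = list(variables.items()) if isinstance(variables, Mapping) else list(variables)
        if not items:
            raise ValueError("EnvStack requires at least one variable")
        self._grids: dict[str, Grid] = {}
        ref = items[0][1].header
        for name, grid in items:
            if not grid.header.aligned_with(ref):
                raise ValueError(f"grid {name!r} is not aligned with the stack header")
            self._grids[name] = grid
        self.header = ref

    @property
    def names(self) -> list[str]:
        return list(self._grids)

    def __len__(self) -> int:
        return len(self._grids)

    def __contains__(self, name: str) -> bool:
        return name in self._grids

    def __getitem__(self, name: str) -> Grid:
        return self._grids[name]

    def items(self):
        return self._grids.items()

    @property
    def union_mask(self) -> np.ndarray:
        """True where any member grid is NODATA."""
        mask = np.zeros((self.header.nrows, self.header.ncols), dtype=bool)
        for grid in self._grids.values():
            mask |= grid.mask
        return mask

    def subset(self, names: Sequence[str]) -> "EnvStack":
        missing = [n for n in names if n not in self._grids]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return EnvStack({n: self._grids[n] for n in names})

    def replace(self, name: str, grid: Grid) -> None:
        if not grid.header.aligned_with(self.header):
            raise ValueError(f"replacement grid {name!r} is not aligned")
        self._grids[name] = grid


_HEADER_FIELDS = {
    "ncols": int,
    "nrows": int,
    "xllcorner": float,
    "yllcorner": float,
    "cellsize": float,
    "nodata_value": float,
}


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid (.asc).

    Header keys are parsed case-insensitively; cells equal to the NODATA
    sentinel (exact float equality after parse) are masked.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    fields: dict[str, float] = {}
    n_header = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) != 2 or parts[0].lower() not in _HEADER_FIELDS:
            break
        key = parts[0].lower()
        try:
            fields[key] = _HEADER_FIELDS[key](float(parts[1]) if key not in ("ncols", "nrows") else int(parts[1]))
        except ValueError as exc:
            raise GridFormatError(f"malformed header line {line!r} in {path}") from exc
        n_header += 1
    required = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
    missing = [k for k in required if k not in fields]
    if missing:
        raise GridFormatError(f"header of {path} is missing fields {missing}")
    header = GridHeader(
        ncols=int(fields["ncols"]),
        nrows=int(fields["nrows"]),
        xllcorner=fields["xllcorner"],
        yllcorner=fields["yllcorner"],
        cellsize=fields["cellsize"],
        nodata_value=fields.get("nodata_value", -9999.0),
    )
    body = " ".join(lines[n_header:])
    try:
        data = np.array(body.split(), dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"non-numeric data token in {path}") from exc
    if data.size != header.nrows * header.ncols:
        raise GridFormatError(
            f"{path}: expected {header.nrows * header.ncols} data values, found {data.size}"
        )
    values = data.reshape(header.nrows, header.ncols)
    mask = values == header.nodata_value
    if not np.isfinite(values[~mask]).all():
        raise GridFormatError(f"{path}: non-finite values outside NODATA cells")
    return Grid(header, values, mask)


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a Grid as a 6-line-header ESRI ASCII file.

    Masked cells are written as the header's NODATA sentinel.  Values are
    formatted with repr-level precision so a round trip is lossless to at
    least 1e-6 relative tolerance.
    """
    h = grid.header
    out = grid.values.copy()
    out[grid.mask] = h.nodata_value
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {h.ncols}\n")
        fh.write(f"nrows {h.nrows}\n")
        fh.write(f"xllcorner {_fmt(h.xllcorner)}\n")
        fh.write(f"yllcorner {_fmt(h.yllcorner)}\n")
        fh.write(f"cellsize {_fmt(h.cellsize)}\n")
        fh.write(f"NODATA_value {_fmt(h.nodata_value)}\n")
        for row in out:
            fh.write(" ".join(_fmt(v) for v in row))
            fh.write("\n")


def _fmt(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def point_cell_indices(header: GridHeader, lon: np.ndarray, lat: np.ndarray):
    """Map lon/lat arrays to (row, col) cell indices plus an in-extent flag.

    Cell (r, c) covers the half-open box
    ``[xll + c*cs, xll + (c+1)*cs) x (ytop - (r+1)*cs, ytop - r*cs]`` —
    closed on the west and north edges.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    col = np.floor((lon - header.xllcorner) / header.cellsize).astype(int)
    row = np.floor((header.ytop - lat) / header.cellsize).astype(int)
    # point exactly on the northern edge belongs to row 0
    row = np.where(lat == header.ytop, 0, row)
    inside = (
        (lon >= header.xllcorner)
        & (lon < header.xright)
        & (lat > header.yllcorner)
        & (lat <= header.ytop)
    )
    row = np.clip(row, 0, header.nrows - 1)
    col = np.clip(col, 0, header.ncols - 1)
    return row, col, inside


def extract_values(stack: EnvStack, points) -> tuple[np.ndarray, np.ndarray]:
    """Extract the covariate vector of each lon/lat point from the stack.

    Parameters
    ----------
    stack : EnvStack
    points : (n, 2) array-like of (lon, lat), or a sequence of objects with
        ``lon``/``lat`` attributes.

    Returns
    -------
    features : (n, n_vars) float array, columns ordered as ``stack.names``;
        rows of invalid points are NaN.
    valid : (n,) boolean array.  A point outside the extent, or falling on a
        NODATA cell of *any* variable, is invalid for all variables (single
        shared validity decision).
    """
    if len(stack) == 0:  # pragma: no cover - EnvStack forbids this
        raise ValueError("empty stack")
    pts = _as_lonlat_array(points)
    n = pts.shape[0]
    features = np.full((n, len(stack)), np.nan)
    if n == 0:
        return features, np.zeros(0, dtype=bool)
    row, col, inside = point_cell_indices(stack.header, pts[:, 0], pts[:, 1])
    valid = inside & ~stack.union_mask[row, col]
    for j, (_, grid) in enumerate(stack.items()):
        features[valid, j] = grid.values[row[valid], col[valid]]
    return features, valid


def _as_lonlat_array(points) -> np.ndarray:
    if hasattr(points, "__len__") and len(points) and hasattr(points[0], "lon"):
        return np.array([[p.lon, p.lat] for p in points], dtype=float)
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    return arr.reshape(-1, 2)
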
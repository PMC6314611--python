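"""Co-registered environmental raster stacks on a WGS84 lon/lat grid.

An :class:`EnvStack` holds named 2-D layers sharing one affine grid
(upper-left origin, square cells in decimal degrees) and one joint
validity mask. Layers are stored dense (float64) with NaN on invalid
cells; every modeling routine consumes the valid-cell table produced by
:meth:`EnvStack.table`.

I/O uses the ESRI ASCII grid format (one ``.asc`` file per variable),
a plain-text raster interchange format that preserves the grid
registration (ncols/nrows/xllcorner/yllcorner/cellsize/nodata).
No reprojection is performed: inputs must already be WGS84 lon/lat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geo import arc_degrees

log = logging.getLogger(__name__)

NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Affine registration of a north-up lon/lat grid.

    ``(x_origin, y_origin)`` is the OUTER corner of cell (0, 0), i.e. the
    upper-left edge; cells are square with side ``cell_size`` degrees.
    Cell (row, col) covers the half-open box
    ``[x_origin + col*cs, x_origin + (col+1)*cs) x (y_origin - (row+1)*cs, y_origin - row*cs]``.
    """

    x_origin: float
    y_origin: float
    cell_size: float

    def cell_center(self, row, col):
        lon = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def index_of(self, lon, lat):
        """Row/col of the cell containing each point (half-open intervals)."""
        col = np.floor((np.asarray(lon, dtype=float) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(lat, dtype=float)) / self.cell_size).astype(int)
        return row, col


@dataclass
class EnvStack:
    """Named co-registered raster variables with a shared validity mask."""

    layers: dict[str, np.ndarray]
    transform: GridTransform
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.layers:
            raise ValueError("EnvStack needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers are not co-registered: shapes {shapes}")
        shape = shapes.pop()
        finite = np.ones(shape, dtype=bool)
        for arr in self.layers.values():
            finite &= np.isfinite(arr)
        if self.mask is None:
            self.mask = finite
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & finite
        for name, arr in self.layers.items():
            bad = ~np.isfinite(arr) & self.mask
            if bad.any():  # cannot happen after the intersection above; belt & braces
                raise ValueError(f"non-finite values on valid cells in {name!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def cell_centers(self):
        """(lon, lat) 2-D arrays of every cell center."""
        nrow, ncol = self.shape
        rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
        return self.transform.cell_center(rows, cols)

    def same_grid(self, other: "EnvStack") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    # -- tabular access -------------------------------------------------
    def table(self, names: Sequence[str] | None = None, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid-cell matrix, one row per cell (row-major order), one column per variable."""
        names = list(names) if names is not None else self.names
        m = self.mask if mask is None else (np.asarray(mask, dtype=bool) & self.mask)
        return np.column_stack([self.layers[n][m] for n in names])

    def subset(self, names: Iterable[str]) -> "EnvStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return EnvStack({n: self.layers[n] for n in names}, self.transform, self.mask.copy())

    def with_layers(self, layers: Mapping[str, np.ndarray]) -> "EnvStack":
        return EnvStack(dict(layers), self.transform, self.mask.copy())

    # -- I/O -------------------------------------------------------------
    def write(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in self.names:
            p = directory / f"{name}.asc"
            write_ascii_grid(p, self.layers[name], self.transform, self.mask)
            paths.append(p)
        return paths


def write_ascii_grid(path: str | Path, grid: np.ndarray, transform: GridTransform, mask: np.ndarray) -> None:
    nrow, ncol = grid.shape
    yll = transform.y_origin - nrow * transform.cell_size
    out = np.where(mask, grid, NODATA)
    header = (
        f"ncols {ncol}\nnrows {nrow}\n"
        f"xllcorner {transform.x_origin!r}\nyllcorner {yll!r}\n"
        f"cellsize {transform.cell_size!r}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path):
    """Read one ESRI ASCII grid; returns (array with NaN nodata, GridTransform)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nrow, ncol = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrow, ncol):
        raise ValueError(f"{path}: data shape {data.shape} != header ({nrow}, {ncol})")
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    tr = GridTransform(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrow * header["cellsize"],
        cell_size=header["cellsize"],
    )
    return data, tr


def read_stack(paths: Sequence[str | Path]) -> EnvStack:
    """Load co-registered ASCII grids into one stack; layer names from file stems.

    The joint validity mask is the intersection of per-layer nodata masks.
    Raises on misaligned grids.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("need at least one raster")
    layers: dict[str, np.ndarray] = {}
    transform = None
    for p in paths:
        arr, tr = read_ascii_grid(p)
        if transform is None:
            transform = tr
            shape = arr.shape
        elif arr.shape != shape or not _close_transform(tr, transform):
            raise ValueError(f"{p}: grid not aligned with {paths[0]}")
        layers[p.stem] = arr
    mask = np.ones(shape, dtype=bool)
    for arr in layers.values():
        mask &= np.isfinite(arr)
    return EnvStack(layers, transform, mask)


def _close_transform(a: GridTransform, b: GridTransform, tol: float = 1e-9) -> bool:
    return (
        abs(a.x_origin - b.x_origin) < tol
        and abs(a.y_origin - b.y_origin) < tol
        and abs(a.cell_size - b.cell_size) < tol
    )


def build_m_mask(occ, env: EnvStack, buffer_deg: float = 7.0, region_mask: np.ndarray | None = None) -> np.ndarray:
    """Accessible-area (M) mask: cells within ``buffer_deg`` degrees of arc of any occurrence.

    M is the dispersal-accessible region over which the niche model is
    calibrated; the default 7 degrees (~770 km) follows the working
    hypothesis used for wide-ranging tick hosts. The buffer is measured
    as great-circle central angle from cell centers to occurrence
    points, then intersected with the stack's validity mask and an
    optional region (e.g. country) mask.
    """
    if buffer_deg <= 0:
        raise ValueError("buffer_deg must be positive")
    lons, lats = occ.lonlat()
    if len(lons) == 0:
        raise ValueError("no occurrences supplied")
    clon, clat = env.cell_centers()
    inside = np.zeros(env.shape, dtype=bool)
    # chunk over occurrences to bound memory on big grids
    for i in range(0, len(lons), 256):
        d = arc_degrees(clon[..., None], clat[..., None], lons[None, None, i : i + 256], lats[None, None, i : i + 256])
        inside |= (d <= buffer_deg).any(axis=-1)
    mask = inside & env.mask
    if region_mask is not None:
        mask &= np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no occurrence falls within the valid grid: empty M mask")
    return mask


def extract_values(env: EnvStack, occ, names: Sequence[str] | None = None):
    """Nearest-cell-center environmental values per occurrence record.

    Returns ``(matrix, kept_index)``: records falling off-grid or on
    invalid cells are excluded (count logged) and not represented in the
    matrix.
    """
    names = list(names) if names is not None else env.names
    lons, lats = occ.lonlat()
    if len(lons) == 0:
        raise ValueError("no occurrences to extract")
    row, col = env.transform.index_of(lons, lats)
    nrow, ncol = env.shape
    on_grid = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    ok = on_grid.copy()
    ok[on_grid] &= env.mask[row[on_grid], col[on_grid]]
    dropped = int((~ok).sum())
    if dropped:
        log.info("extract_values: excluded %d record(s) off-grid or on nodata cells", dropped)
    if not ok.any():
        raise ValueError("all records fall outside the valid grid")
    r, c = row[ok], col[ok]
    mat = np.column_stack([env.layers[n][r, c] for n in names])
    return mat, np.flatnonzero(ok)
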
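"""Lightweight georeferenced raster container and ESRI ASCII grid I/O.

A :class:`Grid` is a 2-D float array with a north-up affine georeference
(west edge, north edge, square pixel size) in a projected metre CRS.  Nodata
is represented internally as NaN.  Rasters are read and written as ESRI
ASCII grids (``.asc``), a plain-text single-band format understood by every
GIS package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AlignmentError, ParameterError

__all__ = ["Grid", "GridSpec", "common_spec", "resample_nearest"]


@dataclass(frozen=True)
class GridSpec:
    """Georeference only: origin (west, north), pixel size, shape."""

    x0: float
    y0: float
    res: float
    nrows: int
    ncols: int

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0 - self.nrows * self.res,
            self.x0 + self.ncols * self.res,
            self.y0,
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate arrays (xs[ncols], ys[nrows]); ys descend north->south."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.res
        ys = self.y0 - (np.arange(self.nrows) + 0.5) * self.res
        return xs, ys


@dataclass
class Grid:
    """North-up single-band raster; ``data[0, 0]`` is the northwest pixel."""

    data: np.ndarray
    x0: float
    y0: float
    res: float
    crs: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("grid data must be 2-D")
        if self.res <= 0:
            raise ParameterError(f"pixel size must be positive, got {self.res}")

    # -- georeference -------------------------------------------------------

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.x0, self.y0, self.res, *self.data.shape)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.spec.bounds

    @property
    def pixel_area_m2(self) -> float:
        return self.res * self.res

    def same_georeference(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.res - other.res) <= tol
        )

    # -- lookup -------------------------------------------------------------

    def rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the pixel containing each point (may be out of range)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.res).astype(int)
        row = np.floor((self.y0 - y) / self.res).astype(int)
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Value of the containing pixel at each point; NaN outside the grid."""
        row, col = self.rowcol(np.atleast_1d(x), np.atleast_1d(y))
        nrows, ncols = self.data.shape
        inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        out = np.full(row.shape, np.nan)
        out[inside] = self.data[row[inside], col[inside]]
        return out

    # -- derived grids ------------------------------------------------------

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    def like(self, data: np.ndarray) -> "Grid":
        """New grid sharing this grid's georeference."""
        if data.shape != self.data.shape:
            raise AlignmentError("replacement data has a different shape")
        return Grid(np.asarray(data, dtype=float), self.x0, self.y0, self.res, self.crs)

    # -- I/O ----------------------------------------------------------------

    def write_asc(self, path: str | Path, nodata: float = -9999.0) -> None:
        path = Path(path)
        data = np.where(np.isfinite(self.data), self.data, nodata)
        nrows, ncols = data.shape
        yll = self.y0 - nrows * self.res
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.res!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt="%.8g")

    @classmethod
    def read_asc(cls, path: str | Path, crs: str | None = None) -> "Grid":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                pos = fh.tell()
                parts = fh.readline().split()
                if len(parts) != 2 or not parts[0][0].isalpha():
                    fh.seek(pos)
                    break
                header[parts[0].lower()] = float(parts[1])
            else:
                pos = fh.tell()
            fh.seek(pos)
            data = np.loadtxt(fh, ndmin=2)
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        res = header["cellsize"]
        if "xllcorner" in header:
            x0 = header["xllcorner"]
            y0 = header["yllcorner"] + nrows * res
        else:  # xllcenter variant
            x0 = header["xllcenter"] - res / 2
            y0 = header["yllcenter"] - res / 2 + nrows * res
        if data.shape != (nrows, ncols):
            raise ParameterError(
                f"{path.name}: data shape {data.shape} != header ({nrows}, {ncols})"
            )
        nodata = header.get("nodata_value")
        if nodata is not None:
            data = np.where(data == nodata, np.nan, data)
        return cls(data, x0, y0, res, crs)


def common_spec(grids: list[Grid | GridSpec], res: float | None = None) -> GridSpec:
    """Union-extent grid spec at ``res`` (default: finest input resolution).

    The origin is snapped outward to multiples of ``res`` so that inputs whose
    own origins sit on the same lattice resample without phase shift.
    """
    specs = [g.spec if isinstance(g, Grid) else g for g in grids]
    if not specs:
        raise ParameterError("no grids supplied")
    if res is None:
        res = min(s.res for s in specs)
    if res <= 0:
        raise ParameterError("target resolution must be positive")
    xmin = min(s.bounds[0] for s in specs)
    ymin = min(s.bounds[1] for s in specs)
    xmax = max(s.bounds[2] for s in specs)
    ymax = max(s.bounds[3] for s in specs)
    x0 = np.floor(xmin / res) * res
    y0 = np.ceil(ymax / res) * res
    ncols = int(np.ceil((xmax - x0) / res - 1e-9))
    nrows = int(np.ceil((y0 - ymin) / res - 1e-9))
    return GridSpec(float(x0), float(y0), float(res), nrows, ncols)


def resample_nearest(grid: Grid, target: GridSpec) -> Grid:
    """Resample onto ``target`` by sampling source pixels at target pixel
    centers (no interpolation: output values are a subset of input values).
    Target pixels outside the source extent become nodata."""
    xs, ys = target.pixel_centers()
    col = np.floor((xs - grid.x0) / grid.res).astype(int)
    row = np.floor((grid.y0 - ys) / grid.res).astype(int)
    nrows, ncols = grid.data.shape
    out = np.full((target.nrows, target.ncols), np.nan)
    rok = (row >= 0) & (row < nrows)
    cok = (col >= 0) & (col < ncols)
    if rok.any() and cok.any():
        rr = row[rok][:, None]
        cc = col[cok][None, :]
        sub = grid.data[rr, cc]
        out[np.ix_(rok, cok)] = sub
    return Grid(out, target.x0, target.y0, target.res, grid.crs)
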
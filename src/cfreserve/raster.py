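"""Grid raster container and plain-text (ESRI ASCII grid) I/O.

All layers in the pipeline — elevation, land cover, loss risk, carbon,
protection masks, resistance, kernel density — are rectangular single-band
grids sharing one cell size and origin. :class:`GridRaster` is the common
currency; every operation that combines layers first checks alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["GridRaster", "read_ascii_grid", "write_ascii_grid"]

_DEFAULT_NODATA = -9999.0


@dataclass
class GridRaster:
    """A rectangular grid of cell values with georeferencing metadata.

    Parameters
    ----------
    values
        2-D array, row 0 at the top (north). Stored as float64 unless an
        integer array is passed for categorical layers.
    cell_size
        Cell edge length in metres (> 0).
    nodata
        Sentinel for missing cells; excluded from all statistics.
    origin
        (x, y) of the lower-left corner in metres.
    """

    values: np.ndarray
    cell_size: float = 500.0
    nodata: float = _DEFAULT_NODATA
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got ndim={self.values.ndim}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError(f"non-positive grid dimensions {self.values.shape}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata (NaN counts as nodata)."""
        v = self.values
        mask = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            mask &= np.isfinite(v)
        return mask

    def aligned_with(self, other: "GridRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_aligned(self, *others: "GridRaster") -> None:
        for o in others:
            if not self.aligned_with(o):
                raise ValueError(
                    f"misaligned rasters: {self.shape}@{self.cell_size} m vs "
                    f"{o.shape}@{o.cell_size} m"
                )

    def like(self, values: np.ndarray) -> "GridRaster":
        """New raster with the same grid geometry but different values."""
        if np.asarray(values).shape != self.shape:
            raise ValueError("values shape does not match raster geometry")
        return replace(self, values=np.asarray(values))

    def copy(self) -> "GridRaster":
        return replace(self, values=self.values.copy())


def write_ascii_grid(raster: GridRaster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text, widely readable)."""
    path = Path(path)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata:g}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any tool)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        values = np.loadtxt(fh, ndmin=2)
    ncols = int(header.get("ncols", values.shape[1]))
    nrows = int(header.get("nrows", values.shape[0]))
    if values.shape != (nrows, ncols):
        raise ValueError(f"grid body {values.shape} disagrees with header ({nrows},{ncols})")
    return GridRaster(
        values=values,
        cell_size=header.get("cellsize", 500.0),
        nodata=header.get("nodata_value", _DEFAULT_NODATA),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
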
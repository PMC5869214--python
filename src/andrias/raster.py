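"""Lightweight georeferenced raster grids.

A :class:`RasterGrid` is a single-band, regularly spaced 2-D grid with an
upper-left origin, square cells, a nodata sentinel and an opaque CRS tag.
Grids are stored row 0 = north, cell-centre registered, with half-open pixel
footprints. Persistence uses the ESRI ASCII grid format (plain text), which
round-trips everything the package needs: shape, georeference, nodata and
values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RasterGrid",
    "GridAlignmentError",
    "align_layers",
    "read_ascii_grid",
]

DEFAULT_NODATA = -9999.0


class GridAlignmentError(ValueError):
    """Raised when an operation requires grids on an identical georeference."""


@dataclass
class RasterGrid:
    """Single-band raster with georeference and nodata handling.

    Parameters
    ----------
    values
        2-D array (float for continuous layers, integer-valued for
        categorical/label layers; stored as float64 internally so the nodata
        sentinel is representable).
    origin
        (x, y) of the upper-left *corner* of the grid.
    cell_size
        Side length of a (square) cell, in the CRS units.
    nodata
        Sentinel marking missing cells. Must not collide with a valid
        category id for categorical layers.
    crs_tag
        Opaque identifier; operations refuse to mix grids with different tags.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got {self.values.ndim}-D")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    # -- basic geometry -------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data (True = valid)."""
        mask = self.values != self.nodata
        return mask & np.isfinite(self.values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, each shaped (nrows, ncols)."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        rows = y0 - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)

    def same_grid(self, other: "RasterGrid", *, check_crs: bool = True) -> bool:
        """Whether ``other`` shares this grid's shape and georeference."""
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.cell_size, other.cell_size)
            and (not check_crs or self.crs_tag == other.crs_tag)
        )

    def like(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """New grid on this georeference holding ``values``."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            nodata=self.nodata if nodata is None else nodata,
        )

    # -- persistence (ESRI ASCII grid) ----------------------------------
    def to_ascii(self, path: str | Path) -> None:
        """Write the grid as an ESRI ASCII grid (text; nodata tagged)."""
        x0, y0 = self.origin
        yll = y0 - self.nrows * self.cell_size
        buf = io.StringIO()
        buf.write(f"ncols {self.ncols}\n")
        buf.write(f"nrows {self.nrows}\n")
        buf.write(f"xllcorner {x0!r}\n")
        buf.write(f"yllcorner {yll!r}\n")
        buf.write(f"cellsize {self.cell_size!r}\n")
        buf.write(f"NODATA_value {self.nodata!r}\n")
        np.savetxt(buf, self.values, fmt="%.10g")
        Path(path).write_text(buf.getvalue())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RasterGrid({self.nrows}x{self.ncols}, origin={self.origin}, "
            f"cell_size={self.cell_size}, crs={self.crs_tag!r})"
        )


def read_ascii_grid(path: str | Path, crs_tag: str = "local") -> RasterGrid:
    """Read an ESRI ASCII grid written by :meth:`RasterGrid.to_ascii`."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(io.StringIO("\n".join(lines[i:])), ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"grid body {values.shape} does not match header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return RasterGrid(
        values,
        origin=origin,
        cell_size=cell,
        nodata=header.get("nodata_value", DEFAULT_NODATA),
        crs_tag=crs_tag,
    )


# -- resampling / alignment ---------------------------------------------

def _fractional_index(target: RasterGrid, source: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """Fractional (row, col) position of each target cell centre in source index space."""
    xs, ys = target.cell_centers()
    sx0, sy0 = source.origin
    col = (xs - sx0) / source.cell_size - 0.5
    row = (sy0 - ys) / source.cell_size - 0.5
    return row, col


def _resample_nearest(source: RasterGrid, target: RasterGrid) -> np.ndarray:
    row, col = _fractional_index(target, source)
    r = np.clip(np.rint(row).astype(int), 0, source.nrows - 1)
    c = np.clip(np.rint(col).astype(int), 0, source.ncols - 1)
    out = source.values[r, c]
    outside = (row < -0.5) | (row > source.nrows - 0.5) | (col < -0.5) | (col > source.ncols - 0.5)
    out[outside] = target.nodata
    return out


def _resample_bilinear(source: RasterGrid, target: RasterGrid) -> np.ndarray:
    row, col = _fractional_index(target, source)
    r0 = np.clip(np.floor(row).astype(int), 0, source.nrows - 1)
    c0 = np.clip(np.floor(col).astype(int), 0, source.ncols - 1)
    r1 = np.clip(r0 + 1, 0, source.nrows - 1)
    c1 = np.clip(c0 + 1, 0, source.ncols - 1)
    fr = np.clip(row - r0, 0.0, 1.0)
    fc = np.clip(col - c0, 0.0, 1.0)
    corners = np.stack(
        [source.values[r0, c0], source.values[r0, c1],
         source.values[r1, c0], source.values[r1, c1]]
    )
    weights = np.stack(
        [(1 - fr) * (1 - fc), (1 - fr) * fc, fr * (1 - fc), fr * fc]
    )
    out = (corners * weights).sum(axis=0)
    # nodata in any contributing corner with positive weight poisons the cell
    invalid = ((corners == source.nodata) & (weights > 0)).any(axis=0)
    outside = (row < -0.5) | (row > source.nrows - 0.5) | (col < -0.5) | (col > source.ncols - 0.5)
    out[invalid | outside] = target.nodata
    return out


def align_layers(
    layers: dict[str, RasterGrid],
    target: RasterGrid,
    methods: dict[str, str] | None = None,
) -> dict[str, RasterGrid]:
    """Resample named layers onto the georeference of ``target``.

    ``methods`` maps layer name to ``"nearest"`` (categorical) or
    ``"bilinear"`` (continuous); unlisted layers default to bilinear.
    Layers already on the target grid are returned unchanged. No
    reprojection is attempted: a ``crs_tag`` mismatch is an error.
    """
    methods = methods or {}
    out: dict[str, RasterGrid] = {}
    for name, layer in layers.items():
        if layer.crs_tag != target.crs_tag:
            raise GridAlignmentError(
                f"layer {name!r} has crs_tag {layer.crs_tag!r}, "
                f"target has {target.crs_tag!r}; reprojection is not supported"
            )
        if layer.same_grid(target):
            out[name] = layer
            continue
        method = methods.get(name, "bilinear")
        if method == "nearest":
            vals = _resample_nearest(layer, target)
        elif method == "bilinear":
            vals = _resample_bilinear(layer, target)
        else:
            raise ValueError(f"unknown resampling method {method!r} for layer {name!r}")
        out[name] = RasterGrid(
            vals,
            origin=target.origin,
            cell_size=target.cell_size,
            nodata=target.nodata,
            crs_tag=target.crs_tag,
        )
    return out
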
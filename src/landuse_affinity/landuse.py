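"""Land-use rasters: reclassification, point queries and buffer composition.

The analysis works on the coarsest (level-1) Corine Land Cover tier, lumped
into three studied land-use types — urban (artificial surfaces, including
green urban areas), agricultural, and natural (forests and semi-natural
areas together with wetlands) — while water bodies are excluded from the
typology but still count toward buffer area.

Rasters are regular, axis-aligned grids in planar metre coordinates
(an equal-area projection is assumed upstream); all distances are Euclidean.
The text format is the ESRI ASCII grid dialect: ``ncols``, ``nrows``,
``xllcorner``, ``yllcorner``, ``cellsize``, ``nodata_value`` header lines
followed by a whitespace-separated integer matrix of raw level-1 codes,
rows running north to south.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Category",
    "CATEGORIES",
    "LandUseMap",
    "BufferComposition",
    "InvalidClassError",
    "OutOfBoundsError",
    "DegenerateBufferError",
    "reclassify",
    "reclassify_grid",
    "buffer_proportions",
    "landuse_at_point",
    "read_ascii_grid",
    "write_ascii_grid",
]


class Category(enum.IntEnum):
    """Studied land-use categories after level-1 reclassification."""

    URBAN = 0
    AGRICULTURAL = 1
    NATURAL = 2
    EXCLUDED = 3  # water bodies / nodata: outside the typology


#: The three analysed categories, in canonical order (EXCLUDED is not analysed).
CATEGORIES = (Category.URBAN, Category.AGRICULTURAL, Category.NATURAL)

#: Raw CLC level-1 code -> category.  1 artificial surfaces, 2 agricultural
#: areas, 3 forests & semi-natural areas, 4 wetlands (lumped into natural),
#: 5 water bodies (excluded).
_RECLASS = {
    1: Category.URBAN,
    2: Category.AGRICULTURAL,
    3: Category.NATURAL,
    4: Category.NATURAL,
    5: Category.EXCLUDED,
}


class InvalidClassError(ValueError):
    """A raw land-cover code outside the level-1 range {1..5}."""


class OutOfBoundsError(ValueError):
    """A query point falls outside the raster extent."""


class DegenerateBufferError(ValueError):
    """A buffer disc contains no cell centre (radius too small for the grid)."""


def reclassify(raw_code: int, position: tuple[int, int] | None = None) -> Category:
    """Map a raw CLC level-1 code to its studied category.

    Codes 1 and 2 map to urban and agricultural; 3 (forests and semi-natural
    areas) and 4 (wetlands) are lumped into natural; 5 (water bodies) is
    excluded from the typology.

    Parameters
    ----------
    raw_code
        Integer level-1 code, one of {1, 2, 3, 4, 5}.
    position
        Optional ``(row, col)`` grid position, used only to enrich the error
        message when the code is invalid.
    """
    try:
        return _RECLASS[int(raw_code)]
    except (KeyError, TypeError) as exc:
        where = f" at grid position {position}" if position is not None else ""
        raise InvalidClassError(
            f"invalid land-cover code {raw_code!r}{where}: expected a "
            f"CLC level-1 code in {{1, 2, 3, 4, 5}}"
        ) from exc


def reclassify_grid(raw: np.ndarray, nodata: int | None = None) -> np.ndarray:
    """Vectorised :func:`reclassify` over a raw-code matrix.

    ``nodata`` cells become :attr:`Category.EXCLUDED`.  Any other code
    outside {1..5} raises :class:`InvalidClassError` naming the first
    offending cell.
    """
    raw = np.asarray(raw)
    out = np.full(raw.shape, -1, dtype=np.int8)
    if nodata is not None:
        out[raw == nodata] = Category.EXCLUDED
    for code, cat in _RECLASS.items():
        out[(raw == code) & (out == -1)] = cat
    if (out == -1).any():
        i, j = np.argwhere(out == -1)[0]
        reclassify(raw[i, j], position=(int(i), int(j)))  # raises
    return out


@dataclass(frozen=True)
class LandUseMap:
    """A categorical land-use raster on a regular, axis-aligned grid.

    ``cells[i, j]`` holds the :class:`Category` of the cell whose x extent is
    ``[origin_x + j*cell_size, origin_x + (j+1)*cell_size)`` and whose y
    extent is ``[origin_y + i*cell_size, origin_y + (i+1)*cell_size)`` — i.e.
    row index increases *northward* from the lower-left corner (the ASCII
    grid reader flips the file's north-to-south row order on input).
    """

    origin_x: float
    origin_y: float
    cell_size: float
    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        cells = np.asarray(self.cells, dtype=np.int8)
        if cells.ndim != 2:
            raise ValueError("cells must be a 2-D matrix")
        if not np.isin(cells, [c.value for c in Category]).all():
            raise ValueError("cells must hold only Category codes")
        object.__setattr__(self, "cells", cells)

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` of the covered rectangle."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x < xmax and ymin <= y < ymax

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of column-centre x and row-centre y coordinates."""
        cx = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        cy = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return cx, cy

    def category_fractions(self) -> dict[Category, float]:
        """Realised fraction of each category over the whole grid."""
        n = self.cells.size
        return {c: float((self.cells == c).sum()) / n for c in Category}


@dataclass(frozen=True)
class BufferComposition:
    """Per-category area fractions of a fixed-radius buffer.

    The denominator is the *whole* buffer area (every cell centre in the
    disc, excluded water cells included), so the three proportions sum to 1
    only when the buffer contains no excluded cells and to less than 1 near
    water.
    """

    collection_id: str
    p_urban: float
    p_agri: float
    p_natural: float

    def __post_init__(self) -> None:
        for name in ("p_urban", "p_agri", "p_natural"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_urban + self.p_agri + self.p_natural > 1.0 + 1e-12:
            raise ValueError("buffer proportions sum to more than 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_urban, self.p_agri, self.p_natural])


def _require_inside(lmap: LandUseMap, x: float, y: float) -> None:
    if not lmap.contains(x, y):
        raise OutOfBoundsError(
            f"point ({x}, {y}) is outside the map extent {lmap.extent}"
        )


def buffer_proportions(
    lmap: LandUseMap,
    x: float,
    y: float,
    radius: float = 1000.0,
    collection_id: str = "",
) -> BufferComposition:
    """Land-use composition of the disc of ``radius`` metres around a point.

    A grid cell belongs to the buffer when its *centre* lies within Euclidean
    distance ``radius`` of ``(x, y)`` (inclusive); no area-weighted polygon
    clipping is attempted.  Each proportion is the fraction of buffer cells
    holding that category, over all buffer cells including excluded ones.

    Raises
    ------
    OutOfBoundsError
        If the point is outside the raster extent.
    DegenerateBufferError
        If no cell centre falls inside the disc.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    _require_inside(lmap, x, y)
    cs = lmap.cell_size
    # Bounding box of candidate cells, clipped to the grid.
    j0 = max(int(np.floor((x - radius - lmap.origin_x) / cs)), 0)
    j1 = min(int(np.ceil((x + radius - lmap.origin_x) / cs)), lmap.n_cols)
    i0 = max(int(np.floor((y - radius - lmap.origin_y) / cs)), 0)
    i1 = min(int(np.ceil((y + radius - lmap.origin_y) / cs)), lmap.n_rows)
    cx, cy = lmap.cell_centres()
    dx = cx[j0:j1] - x
    dy = cy[i0:i1] - y
    inside = (dy[:, None] ** 2 + dx[None, :] ** 2) <= radius**2
    total = int(inside.sum())
    if total == 0:
        raise DegenerateBufferError(
            f"buffer of radius {radius} m around ({x}, {y}) contains no cell "
            f"centre on a {cs}-m grid"
        )
    cats = lmap.cells[i0:i1, j0:j1][inside]
    return BufferComposition(
        collection_id=collection_id,
        p_urban=float((cats == Category.URBAN).sum()) / total,
        p_agri=float((cats == Category.AGRICULTURAL).sum()) / total,
        p_natural=float((cats == Category.NATURAL).sum()) / total,
    )


def landuse_at_point(lmap: LandUseMap, x: float, y: float) -> Category:
    """Category of the cell containing ``(x, y)``.

    Cell ownership is half-open on both axes: the cell with lower-left
    corner ``(x0, y0)`` owns ``[x0, x0 + cell_size) × [y0, y0 + cell_size)``,
    so a point on a shared edge belongs to the cell on its upper/right side.
    """
    _require_inside(lmap, x, y)
    j = int(np.floor((x - lmap.origin_x) / lmap.cell_size))
    i = int(np.floor((y - lmap.origin_y) / lmap.cell_size))
    return Category(int(lmap.cells[i, j]))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def read_ascii_grid(path: str | Path) -> LandUseMap:
    """Read an ESRI ASCII grid of raw CLC level-1 codes and reclassify it.

    nodata cells are treated as excluded (water-equivalent).
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required header line {key!r}")
    raw = np.loadtxt(lines[n_header:], dtype=np.int64, ndmin=2)
    if raw.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: matrix shape {raw.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = int(header["nodata_value"]) if "nodata_value" in header else None
    cells = reclassify_grid(np.flipud(raw), nodata=nodata)
    return LandUseMap(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        cells=cells,
    )


def write_ascii_grid(
    path: str | Path,
    raw: np.ndarray,
    origin_x: float,
    origin_y: float,
    cell_size: float,
    nodata: int = -9999,
) -> None:
    """Write a matrix of raw level-1 codes as an ESRI ASCII grid.

    ``raw[i, j]`` follows the in-memory convention (row index increases
    northward); the file stores rows north to south, as the dialect requires.
    """
    raw = np.asarray(raw, dtype=np.int64)
    nrows, ncols = raw.shape
    with Path(path).open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin_x:g}\n")
        fh.write(f"yllcorner {origin_y:g}\n")
        fh.write(f"cellsize {cell_size:g}\n")
        fh.write(f"nodata_value {nodata}\n")
        np.savetxt(fh, np.flipud(raw), fmt="%d")
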
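"""Core data types for grid stitching.

Coordinate conventions used throughout the package:

* pixel indices are 0-based; x grows rightward (columns), y grows downward (rows);
* grid indices are 0-based with tile (0, 0) at the top-left;
* a :class:`Translation` maps the FIRST tile's origin to the SECOND tile's origin,
  so a nominal 10 % horizontal overlap between W-wide tiles gives dx ≈ 0.9·W, dy ≈ 0.

A full acquisition is a dense R×C :class:`TileGrid` of same-sized tiles. Pairwise
displacements between adjacent tiles live in :class:`TranslationTables`: the H table
holds west→east pairs, the V table north→south pairs. The estimated mechanical
parameters of the stage are a :class:`StageModel`, and the final absolute placement of
every tile is a :class:`MosaicLayout`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import GridShapeError

__all__ = [
    "Tile",
    "TileGrid",
    "Translation",
    "TranslationTable",
    "TranslationTables",
    "StageModel",
    "MosaicLayout",
    "neighbor_pairs",
]


@dataclass(frozen=True)
class Tile:
    """One field of view in the acquisition grid.

    Parameters
    ----------
    row, col : int
        0-based grid indices (row 0 is the top row, col 0 the left column).
    image : ndarray
        2-D grayscale raster, shape (H, W); integer or float dtype.
    source_path : str
        Where the tile came from (filename or synthetic identifier).
    """

    row: int
    col: int
    image: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise GridShapeError(
                f"tile ({self.row},{self.col}): expected 2-D grayscale image, "
                f"got ndim={self.image.ndim}"
            )


class TileGrid:
    """A dense rectangular grid of same-sized tiles.

    Tiles are stored row-major. Missing tiles and mixed tile sizes are rejected:
    the stitching model assumes the stage visited every grid position with one
    camera configuration.
    """

    def __init__(self, tiles: list[Tile], rows: int, cols: int):
        if rows <= 0 or cols <= 0:
            raise GridShapeError(f"grid dimensions must be positive, got {rows}x{cols}")
        if len(tiles) != rows * cols:
            raise GridShapeError(
                f"expected {rows * cols} tiles for a {rows}x{cols} grid, got {len(tiles)}"
            )
        seen: dict[tuple[int, int], Tile] = {}
        for t in tiles:
            if not (0 <= t.row < rows and 0 <= t.col < cols):
                raise GridShapeError(f"tile index ({t.row},{t.col}) outside {rows}x{cols} grid")
            if (t.row, t.col) in seen:
                raise GridShapeError(f"duplicate tile at ({t.row},{t.col})")
            seen[(t.row, t.col)] = t
        shape = tiles[0].image.shape
        for t in tiles:
            if t.image.shape != shape:
                raise GridShapeError(
                    f"tile ({t.row},{t.col}) has shape {t.image.shape}, expected {shape}"
                )
        self.rows = rows
        self.cols = cols
        self._tiles = [seen[(r, c)] for r in range(rows) for c in range(cols)]
        self.tile_height, self.tile_width = shape

    @classmethod
    def from_images(cls, images: list[list[np.ndarray]], paths: list[list[str]] | None = None
                    ) -> "TileGrid":
        """Build a grid from a row-major nested list of rasters."""
        rows = len(images)
        cols = len(images[0]) if rows else 0
        tiles = []
        for r, rowimgs in enumerate(images):
            if len(rowimgs) != cols:
                raise GridShapeError("ragged image rows")
            for c, img in enumerate(rowimgs):
                path = paths[r][c] if paths is not None else ""
                tiles.append(Tile(r, c, img, path))
        return cls(tiles, rows, cols)

    def tile(self, row: int, col: int) -> Tile:
        return self._tiles[row * self.cols + col]

    def __iter__(self) -> Iterator[Tile]:
        return iter(self._tiles)

    def __len__(self) -> int:
        return self.rows * self.cols


def neighbor_pairs(grid: TileGrid) -> Iterator[tuple[Tile, Tile, str]]:
    """Yield every adjacent tile pair exactly once.

    West→east pairs come with direction ``"H"``, north→south with ``"V"``.
    The count is rows·(cols−1) + (rows−1)·cols; interior tiles take part in 4
    pairs, edge tiles in 3 and corner tiles in 2.
    """
    for r in range(grid.rows):
        for c in range(grid.cols - 1):
            yield grid.tile(r, c), grid.tile(r, c + 1), "H"
    for r in range(grid.rows - 1):
        for c in range(grid.cols):
            yield grid.tile(r, c), grid.tile(r + 1, c), "V"


@dataclass(frozen=True)
class Translation:
    """A pairwise displacement with its quality score.

    ``(dx, dy)`` is the position of the second tile's origin relative to the
    first tile's origin. ``ncc`` is the Pearson correlation of the two tiles'
    overlap regions under this displacement; NaN marks an invalid/unscorable
    translation. ``repaired`` flags entries replaced by the stage-model filter.
    """

    dx: int
    dy: int
    ncc: float
    repaired: bool = False

    @property
    def valid(self) -> bool:
        return math.isfinite(self.ncc)

    def __post_init__(self) -> None:
        if math.isfinite(self.ncc) and not (-1.0 - 1e-9 <= self.ncc <= 1.0 + 1e-9):
            raise ValueError(f"ncc out of [-1, 1]: {self.ncc}")


class TranslationTable:
    """Dense matrix of translations for one direction (H or V).

    Stored as parallel arrays so column/row statistics vectorize; ``entry`` and
    ``set_entry`` convert to/from :class:`Translation`.
    """

    def __init__(self, shape: tuple[int, int]):
        self.shape = shape
        self.dx = np.zeros(shape, dtype=np.int64)
        self.dy = np.zeros(shape, dtype=np.int64)
        self.ncc = np.full(shape, np.nan, dtype=np.float64)
        self.repaired = np.zeros(shape, dtype=bool)

    def entry(self, r: int, c: int) -> Translation:
        return Translation(int(self.dx[r, c]), int(self.dy[r, c]),
                           float(self.ncc[r, c]), bool(self.repaired[r, c]))

    def set_entry(self, r: int, c: int, t: Translation) -> None:
        self.dx[r, c] = t.dx
        self.dy[r, c] = t.dy
        self.ncc[r, c] = t.ncc
        self.repaired[r, c] = t.repaired

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.ncc)

    def copy(self) -> "TranslationTable":
        out = TranslationTable(self.shape)
        out.dx = self.dx.copy()
        out.dy = self.dy.copy()
        out.ncc = self.ncc.copy()
        out.repaired = self.repaired.copy()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranslationTable):
            return NotImplemented
        return (np.array_equal(self.dx, other.dx)
                and np.array_equal(self.dy, other.dy)
                and np.array_equal(self.ncc, other.ncc, equal_nan=True)
                and np.array_equal(self.repaired, other.repaired))


@dataclass
class TranslationTables:
    """The H (west→east) and V (north→south) translation matrices.

    H has shape rows×(cols−1): entry (r, c) relates tile (r, c) to (r, c+1).
    V has shape (rows−1)×cols: entry (r, c) relates tile (r, c) to (r+1, c).
    """

    h: TranslationTable
    v: TranslationTable

    @classmethod
    def empty(cls, rows: int, cols: int) -> "TranslationTables":
        return cls(TranslationTable((rows, max(cols - 1, 0))),
                   TranslationTable((max(rows - 1, 0), cols)))

    def copy(self) -> "TranslationTables":
        return TranslationTables(self.h.copy(), self.v.copy())


@dataclass
class StageModel:
    """Mechanical model of the microscope stage, per acquisition.

    Attributes
    ----------
    overlap_h, overlap_v : float
        Percent of the tile dimension shared between adjacent tiles, per
        direction, in (0, 100).
    alpha : float
        Camera angle in degrees: the small rotation between the stage's motion
        axes and the camera's pixel axes. Positive alpha gives horizontal stage
        motion a −sin(alpha) vertical component in camera coordinates.
    r : float
        Stage repeatability in pixels (max of the per-axis estimates). Bounds
        the error of any pairwise translation to ±2r per axis, hence the (4r)²
        optimization window.
    backlash_tol : float
        Tolerated deviation (percentage points of overlap) between estimated
        and nominal overlap before the estimate is deemed unreliable; stands in
        for actuator backlash. Default 3.
    h_valid, v_valid : bool
        Whether each direction's estimates are trusted.
    estimated : dict
        Per-field flag: True if the value was estimated from the translation
        tables, False if supplied by the user.
    diagnostics : dict
        Per-direction/axis repeatability spreads and selection counts.
    """

    overlap_h: float
    overlap_v: float
    alpha: float
    r: float
    backlash_tol: float = 3.0
    h_valid: bool = True
    v_valid: bool = True
    estimated: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError(f"repeatability must be >= 1 px, got {self.r}")
        for name in ("overlap_h", "overlap_v"):
            val = getattr(self, name)
            if not (0 < val < 100):
                raise ValueError(f"{name} must be in (0, 100), got {val}")
        if self.backlash_tol <= 0:
            raise ValueError("backlash_tol must be positive")

    def to_text(self) -> str:
        """Serialize to a flat key=value block (for run logs)."""
        lines = []
        for key in ("overlap_h", "overlap_v", "alpha", "r", "backlash_tol",
                    "h_valid", "v_valid"):
            lines.append(f"{key}={getattr(self, key)}")
        for key in ("overlap_h", "overlap_v", "alpha", "r"):
            est = self.estimated.get(key, True)
            lines.append(f"{key}.estimated={'yes' if est else 'no'}")
        return "\n".join(lines) + "\n"

    def nominal_displacement(self, direction: str, tile_w: int, tile_h: int
                             ) -> tuple[float, float]:
        """Expected (dx, dy) of an adjacent pair in camera coordinates.

        Projects the nominal stage step through the camera-angle rotation:
        a horizontal step H appears as (H·cosα, −H·sinα) and a vertical step V
        as (V·sinα, V·cosα).
        """
        a = math.radians(self.alpha)
        if direction == "H":
            step = tile_w * (1.0 - self.overlap_h / 100.0)
            return step * math.cos(a), -step * math.sin(a)
        elif direction == "V":
            step = tile_h * (1.0 - self.overlap_v / 100.0)
            return step * math.sin(a), step * math.cos(a)
        raise ValueError(f"direction must be 'H' or 'V', got {direction!r}")


@dataclass
class MosaicLayout:
    """Absolute pixel position of every tile plus its placement provenance.

    ``x``/``y`` are rows×cols integer arrays, min-normalized so the smallest
    coordinate on each axis is 0. ``placement_ncc[r, c]`` is the ncc of the
    spanning-tree edge that fixed tile (r, c) (−1.0 for the root).
    ``tree_edges`` lists ((row, col), (row2, col2), direction, ncc) for the
    rows·cols − 1 edges used.
    """

    x: np.ndarray
    y: np.ndarray
    placement_ncc: np.ndarray
    tree_edges: list[tuple[tuple[int, int], tuple[int, int], str, float]]
    mosaic_width: int
    mosaic_height: int

    @property
    def rows(self) -> int:
        return self.x.shape[0]

    @property
    def cols(self) -> int:
        return self.x.shape[1]

    def position(self, row: int, col: int) -> tuple[int, int]:
        return int(self.x[row, col]), int(self.y[row, col])

    def validate(self) -> None:
        if np.any(self.x < 0) or np.any(self.y < 0):
            raise ValueError("layout positions must be non-negative")
        if self.x.size > 0 and (self.x.min() != 0 or self.y.min() != 0):
            raise ValueError("layout must be min-normalized to (0, 0)")
        if len(self.tree_edges) != self.x.size - 1:
            raise ValueError("spanning tree must have rows*cols - 1 edges")
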
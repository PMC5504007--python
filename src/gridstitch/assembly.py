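"""Mosaic assembly: tile graph, maximum spanning tree, positions, blending.

The grid of pairwise translations over-constrains tile positions (every cycle
of the adjacency graph imposes a consistency equation the noisy translations
need not satisfy). Assembly resolves this by keeping only a spanning tree:
vertices are tiles, edges adjacent pairs weighted by their ncc, and the
maximum-weight spanning tree fixes each tile's position through exactly one
chain of translations. Edges whose displacement is consistent with the stage
model (within 4r of the nominal offset) get their weight boosted by +1 —
strictly above any unboosted ncc — so physically plausible links are always
preferred; invalid translations get a large negative weight and are used only
when connectivity demands it.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .errors import GridShapeError
from .grid import MosaicLayout, StageModel, TileGrid, TranslationTables

__all__ = ["build_tile_graph", "maximum_spanning_tree", "compose_positions",
           "render_mosaic", "apply_layout", "linear_blend_weights"]

#: weight assigned to edges with invalid ncc (never chosen unless needed)
INVALID_WEIGHT = -1.0e9
#: weight boost for edges consistent with the stage model
PLAUSIBLE_BOOST = 1.0


def build_tile_graph(tables: TranslationTables, model: StageModel,
                     tile_w: int, tile_h: int) -> nx.Graph:
    """Undirected tile-adjacency graph weighted by translation quality.

    Nodes are (row, col); each edge carries its direction, table indices,
    translation and weight. Plausible edges (|dx−dx_nom| < 4r and
    |dy−dy_nom| < 4r) get weight ncc + 1; invalid edges get a sentinel-low
    weight.
    """
    g = nx.Graph()
    r4 = 4.0 * model.r
    for table, direction in ((tables.h, "H"), (tables.v, "V")):
        nom = model.nominal_displacement(direction, tile_w, tile_h)
        rows, cols = table.shape
        for r in range(rows):
            for c in range(cols):
                u = (r, c)
                v = (r, c + 1) if direction == "H" else (r + 1, c)
                g.add_node(u)
                g.add_node(v)
                ncc_val = float(table.ncc[r, c])
                dx, dy = int(table.dx[r, c]), int(table.dy[r, c])
                if math.isnan(ncc_val):
                    weight = INVALID_WEIGHT
                else:
                    weight = ncc_val
                    if abs(dx - nom[0]) < r4 and abs(dy - nom[1]) < r4:
                        weight += PLAUSIBLE_BOOST
                g.add_edge(u, v, weight=weight, direction=direction,
                           dx=dx, dy=dy, ncc=ncc_val)
    return g


def _edge_sort_key(u: tuple[int, int], v: tuple[int, int], data: dict
                   ) -> tuple[float, int, int, int]:
    # Kruskal order: weight descending, ties by direction (H before V), row, col.
    return (-data["weight"], 0 if data["direction"] == "H" else 1, u[0], u[1])


def maximum_spanning_tree(graph: nx.Graph) -> list[tuple[tuple[int, int], tuple[int, int], dict]]:
    """Maximum-weight spanning tree via Kruskal with a deterministic tie-break.

    Edges are taken in order of decreasing weight; equal weights break by
    direction (H before V), then the first endpoint's (row, col). Raises on a
    disconnected graph (impossible for full grid topology).
    """
    edges = sorted(graph.edges(data=True), key=lambda e: _edge_sort_key(*e))
    parent: dict = {n: n for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = []
    for u, v, data in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v, data))
    if len(tree) != graph.number_of_nodes() - 1:
        raise GridShapeError("tile graph is disconnected; cannot span all tiles")
    return tree


def compose_positions(tree: list[tuple[tuple[int, int], tuple[int, int], dict]],
                      tables: TranslationTables, grid: TileGrid) -> MosaicLayout:
    """Absolute tile positions by accumulating translations along the tree.

    Tile (0, 0) anchors the traversal at (0, 0); each tree edge adds (dx, dy)
    in its west→east / north→south direction (subtracting when traversed
    backwards). Positions are then min-normalized so the smallest x and y are 0.
    """
    adj: dict[tuple[int, int], list] = {}
    for u, v, data in tree:
        adj.setdefault(u, []).append((v, data, +1))
        adj.setdefault(v, []).append((u, data, -1))

    rows, cols = grid.rows, grid.cols
    x = np.zeros((rows, cols), dtype=np.int64)
    y = np.zeros((rows, cols), dtype=np.int64)
    placement_ncc = np.full((rows, cols), -1.0)
    visited = {(0, 0)}
    stack = [(0, 0)]
    while stack:
        node = stack.pop()
        for other, data, sign in adj.get(node, []):
            if other in visited:
                continue
            visited.add(other)
            x[other] = x[node] + sign * data["dx"]
            y[other] = y[node] + sign * data["dy"]
            placement_ncc[other] = data["ncc"] if math.isfinite(data["ncc"]) else -1.0
            stack.append(other)
    if len(visited) != rows * cols:
        raise GridShapeError("spanning tree does not reach every tile")

    x -= x.min()
    y -= y.min()
    tree_edges = [(u, v, d["direction"], float(d["ncc"])) for u, v, d in tree]
    return MosaicLayout(
        x=x, y=y, placement_ncc=placement_ncc, tree_edges=tree_edges,
        mosaic_width=int(x.max() + grid.tile_width),
        mosaic_height=int(y.max() + grid.tile_height),
    )


def linear_blend_weights(tile_h: int, tile_w: int) -> np.ndarray:
    """Pyramid blending weights: peak at the tile center, →0 at the borders.

    w(u, v) = (min(u+1, W−u)/⌈W/2⌉) · (min(v+1, H−v)/⌈H/2⌉) for pixel column u
    and row v; strictly positive everywhere inside the tile and symmetric under
    horizontal/vertical flips.
    """
    u = np.arange(tile_w)
    v = np.arange(tile_h)
    wu = np.minimum(u + 1, tile_w - u) / math.ceil(tile_w / 2)
    wv = np.minimum(v + 1, tile_h - v) / math.ceil(tile_h / 2)
    return np.outer(wv, wu)


def _clip_to_dtype(canvas: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return np.clip(np.rint(canvas), info.min, info.max).astype(dtype)
    return canvas.astype(dtype)


def render_mosaic(layout: MosaicLayout, grid: TileGrid, mode: str = "overlay"
                  ) -> np.ndarray:
    """Render the stitched mosaic.

    Modes: ``overlay`` (last-written tile wins, row-major order), ``average``
    (per-pixel mean of contributing tiles), ``linear`` (per-pixel weighted mean
    with pyramid weights). Accumulation is in float; output is clipped and cast
    back to the input dtype. Uncovered canvas stays 0 (blank).
    """
    if (layout.rows, layout.cols) != (grid.rows, grid.cols):
        raise GridShapeError(
            f"layout is {layout.rows}x{layout.cols} but grid is {grid.rows}x{grid.cols}")
    h, w = grid.tile_height, grid.tile_width
    dtype = grid.tile(0, 0).image.dtype
    ch = max(layout.mosaic_height, int(layout.y.max()) + h)
    cw = max(layout.mosaic_width, int(layout.x.max()) + w)

    if mode == "overlay":
        canvas = np.zeros((ch, cw), dtype=dtype)
        for tile in grid:
            px, py = layout.position(tile.row, tile.col)
            canvas[py:py + h, px:px + w] = tile.image
        return canvas

    acc = np.zeros((ch, cw), dtype=np.float64)
    wacc = np.zeros((ch, cw), dtype=np.float64)
    if mode == "average":
        weights = np.ones((h, w))
    elif mode == "linear":
        weights = linear_blend_weights(h, w)
    else:
        raise ValueError(f"unknown blend mode {mode!r}")
    for tile in grid:
        px, py = layout.position(tile.row, tile.col)
        acc[py:py + h, px:px + w] += weights * np.asarray(tile.image, dtype=np.float64)
        wacc[py:py + h, px:px + w] += weights
    covered = wacc > 0
    canvas = np.zeros((ch, cw), dtype=np.float64)
    canvas[covered] = acc[covered] / wacc[covered]
    return _clip_to_dtype(canvas, dtype)


def apply_layout(layout: MosaicLayout, other_grid: TileGrid, mode: str = "overlay"
                 ) -> np.ndarray:
    """Render another channel/time point at previously computed positions."""
    return render_mosaic(layout, other_grid, mode)
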
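"""End-to-end stitching pipeline.

Four stages, mirroring how the method is defined:

1. pairwise translations for every adjacent tile pair (phase correlation +
   multi-peak ncc disambiguation);
2. stage-model estimation from the translation tables (skipped for any
   parameter the user supplies);
3. translation repair (median filter beyond 4r) and refinement (constrained
   hill climbing within the (4r)² window);
4. maximum-spanning-tree assembly into absolute positions and a blended
   mosaic.

Pairwise translations are mutually independent, so stage 1 may run on a
thread pool; results are reduced in a fixed order, keeping the output
bit-identical to sequential execution.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from . import assembly, optimization, pcm, stage_model
from .grid import MosaicLayout, StageModel, TileGrid, TranslationTables, neighbor_pairs

__all__ = ["StitchResult", "stitch"]


@dataclass
class StitchResult:
    """Everything a stitching run produces, stage by stage."""

    raw_tables: TranslationTables
    filtered_tables: TranslationTables
    optimized_tables: TranslationTables
    model: StageModel
    layout: MosaicLayout

    def render(self, grid: TileGrid, mode: str = "overlay") -> np.ndarray:
        return assembly.render_mosaic(self.layout, grid, mode)


def _compute_tables_parallel(grid: TileGrid, n_peaks: int,
                             min_overlap_px: int | None, workers: int
                             ) -> TranslationTables:
    pairs = list(neighbor_pairs(grid))
    with ThreadPoolExecutor(max_workers=workers) as pool:
        results = list(pool.map(
            lambda p: pcm.pairwise_translation(p[0].image, p[1].image,
                                               n_peaks, min_overlap_px),
            pairs))
    tables = TranslationTables.empty(grid.rows, grid.cols)
    for (ta, _, direction), t in zip(pairs, results):
        if direction == "H":
            tables.h.set_entry(ta.row, ta.col, t)
        else:
            tables.v.set_entry(ta.row, ta.col, t)
    return tables


def stitch(grid: TileGrid,
           user: stage_model.StageParams | None = None,
           nominal_overlap: float | None = None,
           n_peaks: int = 2,
           ncc_min: float = stage_model.DEFAULT_NCC_MIN,
           min_overlap_px: int | None = None,
           workers: int = 1) -> StitchResult:
    """Run the full pipeline on a tile grid.

    ``user`` supplies stage parameters that bypass estimation;
    ``nominal_overlap`` is the commanded overlap used for the backlash
    plausibility check. ``workers`` > 1 computes pairwise translations on a
    thread pool (bit-identical to sequential execution).
    """
    if workers > 1:
        raw = _compute_tables_parallel(grid, n_peaks, min_overlap_px, workers)
    else:
        raw = pcm.compute_translation_tables(grid, n_peaks, min_overlap_px)
    model = stage_model.build_stage_model(raw, grid, user=user,
                                          nominal_overlap=nominal_overlap,
                                          ncc_min=ncc_min)
    filtered = optimization.filter_translations(raw, model,
                                                tile_w=grid.tile_width,
                                                tile_h=grid.tile_height)
    optimized = optimization.optimize_all(filtered, model, grid)
    graph = assembly.build_tile_graph(optimized, model,
                                      grid.tile_width, grid.tile_height)
    tree = assembly.maximum_spanning_tree(graph)
    layout = assembly.compose_positions(tree, optimized, grid)
    return StitchResult(raw_tables=raw, filtered_tables=filtered,
                        optimized_tables=optimized, model=model, layout=layout)
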
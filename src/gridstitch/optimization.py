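"""Translation repair and refinement constrained by the stage model.

Two passes:

1. **Median filtering** — within a column of H (or a row of V) every pair shares
   one commanded stage step, so trusted displacements cluster within ±2r of a
   common value. Entries deviating from the column/row median by more than 4r
   on either axis are replaced by the median and flagged ``repaired``.
2. **Constrained hill climbing** — each translation is refined by steepest
   ascent on the ncc surface over the integer displacement lattice, confined to
   the square window of side 4r centered on the start (±2r per axis), the
   maximum error the stage model allows.
"""

from __future__ import annotations

import math

import numpy as np

from .grid import StageModel, TileGrid, Translation, TranslationTables
from .pcm import default_min_overlap, ncc
from .stage_model import select_valid

__all__ = ["filter_translations", "hill_climb", "optimize_all"]

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _lower_median(values: np.ndarray) -> int:
    s = np.sort(np.asarray(values).ravel())
    return int(s[(s.size - 1) // 2])


def _filter_lines(dx: np.ndarray, dy: np.ndarray, ncc_vals: np.ndarray,
                  repaired: np.ndarray, r4: float, axis: int,
                  nominal: tuple[float, float], valid: np.ndarray) -> None:
    """Median-replace outliers line-by-line, in place.

    ``axis`` = 0 filters column-wise (H tables), 1 row-wise (V tables).
    ``valid`` marks the entries trusted to contribute to medians. A line median
    needs at least 2 trusted entries (a single entry may itself be a
    high-scoring false registration); lines below that fall back to the
    table-wide median, and a table with no valid entries anywhere falls back to
    the model's nominal displacement.
    """
    if valid.any():
        table_med = (_lower_median(dx[valid]), _lower_median(dy[valid]))
    else:
        table_med = (int(round(nominal[0])), int(round(nominal[1])))
    n_lines = dx.shape[1] if axis == 0 else dx.shape[0]
    for i in range(n_lines):
        sel = (slice(None), i) if axis == 0 else (i, slice(None))
        line_valid = valid[sel]
        if line_valid.sum() >= 2:
            med = (_lower_median(dx[sel][line_valid]), _lower_median(dy[sel][line_valid]))
        else:
            med = table_med
        dev = (np.abs(dx[sel] - med[0]) > r4) | (np.abs(dy[sel] - med[1]) > r4)
        bad = dev | (~np.isfinite(ncc_vals[sel]) & ~repaired[sel])
        if bad.any():
            dxl, dyl, nccl, repl = dx[sel], dy[sel], ncc_vals[sel], repaired[sel]
            dxl[bad] = med[0]
            dyl[bad] = med[1]
            nccl[bad] = np.nan
            repl[bad] = True
            dx[sel], dy[sel], ncc_vals[sel], repaired[sel] = dxl, dyl, nccl, repl


def filter_translations(tables: TranslationTables, model: StageModel,
                        tile_w: int | None = None, tile_h: int | None = None,
                        ncc_min: float = 0.5) -> TranslationTables:
    """Replace implausible translations by their column/row medians.

    H is filtered column-wise and V row-wise: entries whose dx or dy deviates
    from the line median by more than 4r are set to (median dx, median dy) with
    ncc = NaN and ``repaired`` = True. Medians are computed over trusted,
    unrepaired entries only — ncc ≥ ``ncc_min`` and primary displacement in the
    physically plausible band [0.5·extent, extent) — so that the gross
    registration failures the filter exists to repair cannot drag the median
    itself. The operation is idempotent: repaired entries sit exactly on the
    medians and are excluded from them.
    """
    out = tables.copy()
    r4 = 4.0 * model.r
    if out.h.ncc.size:
        if tile_w is None:
            raise ValueError("tile_w required to derive the nominal H displacement")
        nom_h = model.nominal_displacement("H", tile_w, tile_h or tile_w)
        valid = select_valid(out.h, "H", tile_w, ncc_min) & ~out.h.repaired
        _filter_lines(out.h.dx, out.h.dy, out.h.ncc, out.h.repaired, r4, 0,
                      nom_h, valid)
    if out.v.ncc.size:
        if tile_h is None:
            raise ValueError("tile_h required to derive the nominal V displacement")
        nom_v = model.nominal_displacement("V", tile_w or tile_h, tile_h)
        valid = select_valid(out.v, "V", tile_h, ncc_min) & ~out.v.repaired
        _filter_lines(out.v.dx, out.v.dy, out.v.ncc, out.v.repaired, r4, 1,
                      nom_v, valid)
    return out


def _ascend(score, start: tuple[int, int], half: int
            ) -> tuple[tuple[int, int], float]:
    """Steepest ascent over the 8-connected integer lattice.

    ``score(dx, dy) -> float`` may return NaN for unscorable points. Moves
    never leave the square |dx − dx₀| ≤ half, |dy − dy₀| ≤ half; evaluations
    are memoized. Returns the local maximum reached and its score (NaN when
    the start and all reachable neighbors are unscorable).
    """
    dx0, dy0 = int(start[0]), int(start[1])
    memo: dict[tuple[int, int], float] = {}

    def cached(dx: int, dy: int) -> float:
        key = (dx, dy)
        if key not in memo:
            memo[key] = float(score(dx, dy))
        return memo[key]

    cur = (dx0, dy0)
    cur_val = cached(*cur)
    while True:
        best_n = None
        best_val = -math.inf
        for sx, sy in _NEIGHBORS8:
            nx, ny = cur[0] + sx, cur[1] + sy
            if abs(nx - dx0) > half or abs(ny - dy0) > half:
                continue
            val = cached(nx, ny)
            if math.isnan(val):
                continue
            if val > best_val:
                best_val = val
                best_n = (nx, ny)
        cur_ok = not math.isnan(cur_val)
        if best_n is None:
            break
        if cur_ok and best_val <= cur_val:
            break
        cur, cur_val = best_n, best_val
    return cur, cur_val


def hill_climb(a: np.ndarray, b: np.ndarray, start: tuple[int, int],
               bound_r: float, min_overlap_px: int | None = None) -> Translation:
    """Steepest-ascent refinement of a displacement on the ncc surface.

    8-connected unit steps on the integer (dx, dy) lattice, never leaving the
    window |dx − dx₀| ≤ 2r, |dy − dy₀| ≤ 2r (the (4r)² uncertainty square of
    the stage model); ncc evaluations are memoized. Terminates at a local
    maximum. If the start and all reachable neighbors are invalid, returns the
    start with invalid ncc.
    """
    if bound_r < 1:
        raise ValueError("bound_r must be >= 1")
    if min_overlap_px is None:
        min_overlap_px = default_min_overlap(a.shape)
    half = int(math.floor(2.0 * bound_r))
    (fx, fy), val = _ascend(lambda dx, dy: ncc(a, b, dx, dy, min_overlap_px),
                            start, half)
    return Translation(fx, fy, val if not math.isnan(val) else math.nan)


def optimize_all(tables: TranslationTables, model: StageModel, grid: TileGrid
                 ) -> TranslationTables:
    """Hill-climb every (possibly repaired) translation within the 4r window.

    Repaired entries get their ncc recomputed at the median displacement before
    the climb, so the ascent invariant (final ncc ≥ starting ncc) holds for
    every entry with a scorable start.
    """
    out = tables.copy()
    min_ov = default_min_overlap((grid.tile_height, grid.tile_width))
    for table, direction in ((out.h, "H"), (out.v, "V")):
        rows, cols = table.shape
        for r in range(rows):
            for c in range(cols):
                if direction == "H":
                    a = grid.tile(r, c).image
                    b = grid.tile(r, c + 1).image
                else:
                    a = grid.tile(r, c).image
                    b = grid.tile(r + 1, c).image
                start = (int(table.dx[r, c]), int(table.dy[r, c]))
                result = hill_climb(a, b, start, model.r, min_ov)
                table.dx[r, c] = result.dx
                table.dy[r, c] = result.dy
                table.ncc[r, c] = result.ncc
    return out
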
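"""Estimation of the mechanical stage model from raw translation tables.

An automated microscope's stage visits an R×C lattice of positions. Four
quantities characterize the mechanics well enough to bound translation errors:

* the actual **overlap** between adjacent tiles per direction (the commanded
  overlap fluctuates — a commanded 10 % may come out anywhere in roughly 8–12 %);
* the **camera angle** α between the stage's motion axes and the camera's pixel
  axes (horizontal stage motion H appears as (H·cosα, −H·sinα) to the camera,
  vertical motion V as (V·sinα, V·cosα));
* the stage **repeatability** r — the positional uncertainty when revisiting a
  commanded position, which bounds any pairwise translation error to ±2r;
* an actuator **backlash** tolerance, used here as a plausibility band on the
  overlap estimate rather than an additive correction.

All estimators are robust (median / percentile) because feature-poor overlap
regions produce grossly wrong pairwise translations that must not drag the
estimates. Any parameter the user supplies is taken verbatim and not estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import StageModelError
from .grid import StageModel, TileGrid, TranslationTable, TranslationTables

__all__ = ["StageParams", "select_valid", "estimate_overlap",
           "estimate_camera_angle", "estimate_repeatability", "build_stage_model"]

DEFAULT_NCC_MIN = 0.5
DEFAULT_BACKLASH_TOL = 3.0


@dataclass
class StageParams:
    """User-supplied stage parameters; any field left None is estimated."""

    overlap: float | None = None
    alpha: float | None = None
    r: float | None = None
    backlash_tol: float | None = None


def select_valid(table: TranslationTable, direction: str, tile_extent: int,
                 ncc_min: float = DEFAULT_NCC_MIN) -> np.ndarray:
    """Boolean mask of entries trusted for parameter estimation.

    An entry qualifies when its ncc is valid and ≥ ``ncc_min`` and its primary
    displacement (dx for H, dy for V) lies in the physically plausible band
    [0.45·extent, extent): adjacent tiles overlap by roughly half a tile at
    most and cannot be disjoint. The lower edge sits slightly below half a
    tile so that an acquisition commanded at exactly 50 % overlap does not
    have half of its jittered displacements truncated (which would bias the
    median overlap estimate). An all-False mask means the direction is
    untrusted.
    """
    if direction == "H":
        primary = table.dx
    elif direction == "V":
        primary = table.dy
    else:
        raise ValueError(f"direction must be 'H' or 'V', got {direction!r}")
    with np.errstate(invalid="ignore"):
        mask = (np.isfinite(table.ncc) & (table.ncc >= ncc_min)
                & (primary >= 0.45 * tile_extent) & (primary < tile_extent))
    return mask


def _lower_median(values: np.ndarray) -> float:
    """Median with even-count ties broken toward the lower value."""
    s = np.sort(np.asarray(values).ravel())
    if s.size == 0:
        raise ValueError("median of empty selection")
    return float(s[(s.size - 1) // 2])


def estimate_overlap(table: TranslationTable, mask: np.ndarray, tile_extent: int,
                     direction: str) -> float:
    """Overlap percent from the median primary displacement of trusted entries."""
    if not mask.any():
        raise StageModelError("no trusted entries for overlap estimation")
    primary = table.dx if direction == "H" else table.dy
    med = _lower_median(primary[mask])
    overlap = 100.0 * (1.0 - med / tile_extent)
    return float(np.clip(overlap, 1e-6, 100.0 - 1e-6))


def estimate_camera_angle(h_table: TranslationTable, v_table: TranslationTable,
                          h_mask: np.ndarray, v_mask: np.ndarray) -> float:
    """Camera angle (degrees) as the pooled median of per-pair angles.

    Each H entry contributes atan2(−dy, dx) and each V entry atan2(dx, dy):
    both invert the camera projection of a pure stage step, so a positive α
    gives horizontal motion a −sinα vertical component.
    """
    angles: list[float] = []
    if h_mask.any():
        angles.extend(np.degrees(np.arctan2(-h_table.dy[h_mask], h_table.dx[h_mask])))
    if v_mask.any():
        angles.extend(np.degrees(np.arctan2(v_table.dx[v_mask], v_table.dy[v_mask])))
    if not angles:
        raise StageModelError("no trusted entries for camera-angle estimation")
    return _lower_median(np.array(angles))


def _half_range(values: np.ndarray) -> float:
    """Half the 2.5–97.5 percentile span: a robust half-range about the median."""
    lo, hi = np.percentile(values, [2.5, 97.5])
    return 0.5 * float(hi - lo)


def estimate_repeatability(h_table: TranslationTable, v_table: TranslationTable,
                           h_mask: np.ndarray, v_mask: np.ndarray
                           ) -> tuple[float, dict]:
    """Stage repeatability r (px) from the spread of trusted displacements.

    For each direction and axis the spread is half the 2.5–97.5 percentile
    span; r is the ceiling of the maximum spread, floored at 1 px. Per-axis
    spreads are returned for diagnostics.
    """
    spreads: dict[str, float] = {}
    if h_mask.any():
        spreads["h_dx"] = _half_range(h_table.dx[h_mask])
        spreads["h_dy"] = _half_range(h_table.dy[h_mask])
    if v_mask.any():
        spreads["v_dx"] = _half_range(v_table.dx[v_mask])
        spreads["v_dy"] = _half_range(v_table.dy[v_mask])
    if not spreads:
        raise StageModelError("no trusted entries for repeatability estimation")
    r = max(1.0, math.ceil(max(spreads.values())))
    return r, spreads


def build_stage_model(tables: TranslationTables, grid: TileGrid,
                      user: StageParams | None = None,
                      nominal_overlap: float | None = None,
                      ncc_min: float = DEFAULT_NCC_MIN) -> StageModel:
    """Assemble a :class:`StageModel`, estimating only what the user left open.

    ``nominal_overlap`` is the overlap the acquisition was commanded with
    (distinct from a hard ``user.overlap`` override): when the estimated
    overlap deviates from it by more than the backlash tolerance the estimate
    is deemed unreliable — the nominal value is used instead and r is widened
    to backlash_tol·extent/100 so the optimizer can absorb the discrepancy.

    Raises :class:`StageModelError` when neither direction yields a trusted
    estimate and the user supplied nothing to fall back on.
    """
    user = user or StageParams()
    backlash_tol = user.backlash_tol if user.backlash_tol is not None else DEFAULT_BACKLASH_TOL
    w, h = grid.tile_width, grid.tile_height

    h_mask = select_valid(tables.h, "H", w, ncc_min) if tables.h.ncc.size else \
        np.zeros((0, 0), dtype=bool)
    v_mask = select_valid(tables.v, "V", h, ncc_min) if tables.v.ncc.size else \
        np.zeros((0, 0), dtype=bool)
    h_valid = bool(h_mask.any())
    v_valid = bool(v_mask.any())

    estimated = {"overlap_h": False, "overlap_v": False, "alpha": False, "r": False}
    diagnostics: dict = {"n_selected_h": int(h_mask.sum()), "n_selected_v": int(v_mask.sum())}

    fallback_overlap = user.overlap if user.overlap is not None else nominal_overlap
    if not (h_valid or v_valid) and fallback_overlap is None:
        raise StageModelError(
            "cannot model stage: no translation direction is trusted and no "
            "user parameters were provided")

    # -- overlap per direction -------------------------------------------------
    if user.overlap is not None:
        overlap_h = overlap_v = float(user.overlap)
    else:
        overlap_h = estimate_overlap(tables.h, h_mask, w, "H") if h_valid else None
        overlap_v = estimate_overlap(tables.v, v_mask, h, "V") if v_valid else None
        estimated["overlap_h"] = overlap_h is not None
        estimated["overlap_v"] = overlap_v is not None
        if overlap_h is None and overlap_v is None:
            overlap_h = overlap_v = float(nominal_overlap)  # guarded above
        else:
            if overlap_h is None:
                overlap_h = overlap_v
            if overlap_v is None:
                overlap_v = overlap_h

    # -- camera angle ----------------------------------------------------------
    if user.alpha is not None:
        alpha = float(user.alpha)
    elif h_valid or v_valid:
        alpha = estimate_camera_angle(tables.h, tables.v, h_mask, v_mask)
        estimated["alpha"] = True
    else:
        alpha = 0.0

    # -- repeatability ---------------------------------------------------------
    if user.r is not None:
        r = float(user.r)
        if r < 1:
            raise ValueError("user repeatability must be >= 1 px")
    elif h_valid or v_valid:
        r, spreads = estimate_repeatability(tables.h, tables.v, h_mask, v_mask)
        estimated["r"] = True
        diagnostics["spreads"] = spreads
    else:
        r = max(1.0, math.ceil(backlash_tol * max(w, h) / 100.0))

    # -- backlash plausibility check on estimated overlaps ---------------------
    if nominal_overlap is not None and user.overlap is None:
        widened = False
        if estimated["overlap_h"] and abs(overlap_h - nominal_overlap) > backlash_tol:
            overlap_h = float(nominal_overlap)
            h_valid = False
            estimated["overlap_h"] = False
            widened = True
        if estimated["overlap_v"] and abs(overlap_v - nominal_overlap) > backlash_tol:
            overlap_v = float(nominal_overlap)
            v_valid = False
            estimated["overlap_v"] = False
            widened = True
        if widened and user.r is None:
            r = max(r, backlash_tol * max(w, h) / 100.0)
            diagnostics["backlash_widened_r"] = True

    return StageModel(overlap_h=overlap_h, overlap_v=overlap_v, alpha=alpha, r=r,
                      backlash_tol=backlash_tol, h_valid=h_valid, v_valid=v_valid,
                      estimated=estimated, diagnostics=diagnostics)
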
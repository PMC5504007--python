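"""Reference-based accuracy scoring of stitched mosaics.

A stitched result is scored against reference regions of interest (ROIs, e.g.
cell colonies whose true centroid was measured on the microscope stage):

* **centroid distance error** D_err = √((x_m−x_c)² + (y_m−y_c)²) per matched
  pair (reference centroid (x_m, y_m) vs computed (x_c, y_c));
* **signed percent area error** S_err = (A_c − A_m)/A_m × 100;
* **FP + FN** — computed ROIs with no reference partner (added by duplication)
  plus reference ROIs with no computed partner (deleted by misalignment).
  Matching is by the Hungarian algorithm on a similarity matrix; any matched
  pair farther apart than ``max_dist`` (default: half the smaller field-of-view
  dimension) is unmatched again and counted as one FN plus one FP.

Before computing D_err the computed set is rigidly aligned onto the reference
frame with Kabsch's algorithm, removing the global rotation/translation offset
the camera angle introduces between stage and mosaic coordinates.

Blank-pixel counting flags stitching gaps: zero-valued pixels inside the union
of the placed tile rectangles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .grid import MosaicLayout
from .pcm import ncc as _patch_ncc

__all__ = ["Roi", "AccuracyReport", "centroid_distance_error", "area_error",
           "kabsch_align", "match_rois", "blank_pixel_count", "coverage_mask",
           "evaluate"]


@dataclass(frozen=True)
class Roi:
    """A region of interest: centroid (x, y), area in px², and a label."""

    x: float
    y: float
    area: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"ROI area must be positive, got {self.area}")


@dataclass
class AccuracyReport:
    """Matched pairs with their errors, plus unmatched counts and summaries."""

    matches: list[tuple[Roi, Roi, float, float]]  # (ref, comp, D_err, S_err)
    fp: int
    fn: int
    d_err_mean: float = math.nan
    d_err_sd: float = math.nan
    s_err_mean: float = math.nan
    s_err_sd: float = math.nan
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"matched ROIs : {len(self.matches)}",
            f"FP + FN      : {self.fp + self.fn} (FP={self.fp}, FN={self.fn})",
            f"D_err (px)   : {self.d_err_mean:.2f} +/- {self.d_err_sd:.2f}",
            f"S_err (%)    : {self.s_err_mean:.2f} +/- {self.s_err_sd:.2f}",
            f"frame fix    : rotation {self.rotation_deg:.4f} deg, "
            f"translation ({self.translation[0]:.2f}, {self.translation[1]:.2f})",
        ]
        return "\n".join(lines) + "\n"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"ref_label": r.label, "comp_label": c.label,
                 "ref_x": r.x, "ref_y": r.y, "comp_x": c.x, "comp_y": c.y,
                 "d_err_px": d, "s_err_pct": s}
                for r, c, d, s in self.matches]
        return pd.DataFrame(rows, columns=["ref_label", "comp_label", "ref_x",
                                           "ref_y", "comp_x", "comp_y",
                                           "d_err_px", "s_err_pct"])


def centroid_distance_error(ref: Roi, comp: Roi) -> float:
    """Euclidean distance between the reference and computed centroids (px)."""
    return math.hypot(ref.x - comp.x, ref.y - comp.y)


def area_error(ref: Roi, comp: Roi) -> float:
    """Signed percent area error (A_c − A_m)/A_m × 100."""
    if ref.area <= 0:
        raise ValueError("reference area must be positive")
    return (comp.area - ref.area) / ref.area * 100.0


def kabsch_align(ref_points: np.ndarray, comp_points: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid alignment of ``comp_points`` onto ``ref_points``.

    Returns (R, t) with R a proper 2×2 rotation (det = +1) and t a 2-vector
    minimizing the RMSD of R·comp + t against ref over the paired points.
    """
    ref = np.asarray(ref_points, dtype=np.float64)
    comp = np.asarray(comp_points, dtype=np.float64)
    if ref.shape != comp.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("point sets must be matching (n, 2) arrays")
    if ref.shape[0] < 2:
        raise ValueError("need at least 2 paired points")
    ref_c = ref - ref.mean(axis=0)
    comp_c = comp - comp.mean(axis=0)
    cov = comp_c.T @ ref_c
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, d]) @ u.T
    t = ref.mean(axis=0) - rot @ comp.mean(axis=0)
    return rot, t


def match_rois(ref: list[Roi], comp: list[Roi], similarity: str = "neg_distance",
               max_dist: float | None = None,
               ref_image: np.ndarray | None = None,
               comp_image: np.ndarray | None = None,
               patch_size: int = 32
               ) -> tuple[list[tuple[Roi, Roi]], int, int]:
    """Optimal one-to-one ROI matching via the Hungarian algorithm.

    ``similarity`` is ``"neg_distance"`` (negative centroid distance; default)
    or ``"ncc_patch"`` (ncc of square patches cropped around each centroid from
    the supplied images). The rectangular assignment maximizes total
    similarity; matched pairs farther apart than ``max_dist`` are broken — the
    reference counts as missed (FN) and the computed as added (FP). Returns
    (matched pairs, fp, fn).
    """
    if not ref or not comp:
        return [], len(comp), len(ref)
    sim = np.empty((len(ref), len(comp)))
    if similarity == "neg_distance":
        for i, rr in enumerate(ref):
            for j, cc in enumerate(comp):
                sim[i, j] = -centroid_distance_error(rr, cc)
    elif similarity == "ncc_patch":
        if ref_image is None or comp_image is None:
            raise ValueError("ncc_patch similarity requires ref_image and comp_image")
        half = patch_size // 2

        def patch(img: np.ndarray, roi: Roi) -> np.ndarray:
            cy, cx = int(round(roi.y)), int(round(roi.x))
            y0, x0 = max(0, cy - half), max(0, cx - half)
            return np.asarray(img[y0:y0 + patch_size, x0:x0 + patch_size], dtype=np.float64)

        for i, rr in enumerate(ref):
            for j, cc in enumerate(comp):
                pr, pc = patch(ref_image, rr), patch(comp_image, cc)
                if pr.shape != pc.shape or pr.size == 0:
                    sim[i, j] = -np.inf
                    continue
                score = _patch_ncc(pr, pc, 0, 0, min_overlap_px=1)
                sim[i, j] = score if math.isfinite(score) else -np.inf
    else:
        raise ValueError(f"unknown similarity {similarity!r}")

    rows, cols = linear_sum_assignment(sim, maximize=True)
    matches: list[tuple[Roi, Roi]] = []
    fp_extra = 0
    fn_extra = 0
    for i, j in zip(rows, cols):
        dist = centroid_distance_error(ref[i], comp[j])
        if max_dist is not None and dist > max_dist:
            fn_extra += 1
            fp_extra += 1
            continue
        matches.append((ref[i], comp[j]))
    fp = len(comp) - len(matches)
    fn = len(ref) - len(matches)
    assert fp >= fp_extra and fn >= fn_extra
    return matches, fp, fn


def coverage_mask(layout: MosaicLayout, tile_w: int, tile_h: int,
                  shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the union of placed tile rectangles on a canvas."""
    mask = np.zeros(shape, dtype=bool)
    for r in range(layout.rows):
        for c in range(layout.cols):
            px, py = layout.position(r, c)
            mask[py:py + tile_h, px:px + tile_w] = True
    return mask


def blank_pixel_count(mosaic: np.ndarray, coverage_hull: np.ndarray) -> int:
    """Number of zero-intensity pixels inside the covered region.

    A blank pixel is neither background nor foreground — it simply was never
    written (intensity 0), indicating a stitching gap. ``coverage_hull`` is a
    boolean mask of the region the placed tiles should cover.
    """
    if coverage_hull.shape != mosaic.shape:
        raise ValueError("coverage hull must match the mosaic shape")
    return int(np.count_nonzero((mosaic == 0) & coverage_hull))


def evaluate(ref_rois: list[Roi], comp_rois: list[Roi],
             fov: tuple[int, int] | None = None,
             max_dist: float | None = None,
             align: bool = True,
             similarity: str = "neg_distance") -> AccuracyReport:
    """Full accuracy report: align, match, per-pair errors, aggregates.

    ``fov`` is the (height, width) of one field of view; when ``max_dist`` is
    not given it defaults to half the smaller FOV dimension (the miss rule).
    When ``align`` is true the computed set is Kabsch-aligned onto the
    reference frame (using a provisional distance matching) before the final
    matching and error computation, making the report invariant to a global
    rigid transform of the computed set.
    """
    if not ref_rois or not comp_rois:
        raise ValueError("evaluate requires non-empty ROI sets")
    if max_dist is None and fov is not None:
        max_dist = 0.5 * min(fov)

    rotation_deg = 0.0
    translation = (0.0, 0.0)
    comp_work = list(comp_rois)
    if align and len(ref_rois) >= 2 and len(comp_rois) >= 2:
        provisional, _, _ = match_rois(ref_rois, comp_work, "neg_distance", None)
        if len(provisional) >= 2:
            ref_pts = np.array([[r.x, r.y] for r, _ in provisional])
            comp_pts = np.array([[c.x, c.y] for _, c in provisional])
            rot, t = kabsch_align(ref_pts, comp_pts)
            rotation_deg = math.degrees(math.atan2(rot[1, 0], rot[0, 0]))
            translation = (float(t[0]), float(t[1]))
            comp_work = []
            for c in comp_rois:
                xy = rot @ np.array([c.x, c.y]) + t
                comp_work.append(Roi(float(xy[0]), float(xy[1]), c.area, c.label))

    pairs, fp, fn = match_rois(ref_rois, comp_work, similarity, max_dist)
    matches = [(r, c, centroid_distance_error(r, c), area_error(r, c))
               for r, c in pairs]
    d_errs = np.array([m[2] for m in matches]) if matches else np.array([])
    s_errs = np.array([m[3] for m in matches]) if matches else np.array([])
    return AccuracyReport(
        matches=matches, fp=fp, fn=fn,
        d_err_mean=float(d_errs.mean()) if d_errs.size else math.nan,
        d_err_sd=float(d_errs.std(ddof=1)) if d_errs.size > 1 else 0.0,
        s_err_mean=float(s_errs.mean()) if s_errs.size else math.nan,
        s_err_sd=float(s_errs.std(ddof=1)) if s_errs.size > 1 else 0.0,
        rotation_deg=rotation_deg, translation=translation,
    )
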
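"""Synthetic acquisitions with known ground truth.

Emulates what an automated microscope stage does to a specimen: a large source
image (the "plate") is sampled into an R×C grid of overlapping tiles. Each
commanded stage position is perturbed by the stage repeatability r (uniform or
Gaussian jitter), odd rows can receive a constant x offset (actuator backlash
under serpentine motion), and the whole position lattice is rotated by the
camera angle α before sampling — tiles are integer-pixel crops, so α acts on
positions, not as an image rotation (valid in the small-α regime the stage
model addresses). Optional per-tile Gaussian noise and a multiplicative
intensity decay on re-imaged overlap strips (a photobleaching stand-in) stress
the correlation scoring.

Defaults mirror a typical low-density stem-cell plate acquisition: 10 %
commanded overlap, repeatability 2 px, camera angle 1°, no added noise.

Everything is deterministic per seed, and the exact tile positions, stage
parameters and source ROIs are returned as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DataError
from .grid import MosaicLayout, StageModel, Tile, TileGrid, TranslationTables
from .metrics import Roi

__all__ = ["SyntheticAcquisition", "generate_source", "simulate_acquisition",
           "corrupt_translations"]

_SOURCE_MAX = 60000  # uint16 headroom; minimum intensity is kept >= 1


@dataclass
class SyntheticAcquisition:
    """A generated tile grid plus everything needed to verify a stitch."""

    grid: TileGrid
    truth_layout: MosaicLayout
    truth_model: StageModel
    source: np.ndarray
    rois: list[Roi]
    seed: int
    params: dict = field(default_factory=dict)


def generate_source(seed: int, width: int, height: int, content: str = "blobs",
                    blob_density: float = 3e-4) -> tuple[np.ndarray, list[Roi]]:
    """Deterministic source raster plus the ROIs it contains.

    ``content``:

    * ``"blobs"`` — Poisson-placed Gaussian blobs on a low-noise background,
      mimicking sparse colonies; each blob's centroid and nominal area
      (a 2σ disc) are recorded as an ROI;
    * ``"texture"`` — band-passed noise, feature-rich everywhere (no ROIs);
    * ``"flat"`` — constant (degenerate-case testing).

    Minimum intensity is ≥ 1 so the value 0 stays reserved for blank pixels.
    """
    rng = np.random.default_rng(seed)
    if content == "flat":
        return np.full((height, width), 1000, dtype=np.uint16), []
    if content == "texture":
        # broadband: smooth structure plus fine grain, like stained tissue
        # under shot noise; a pure low-pass field would leave the whitened
        # cross-power spectrum dominated by noise at high frequencies
        raw = rng.standard_normal((height, width))
        smooth = ndimage.gaussian_filter(raw, sigma=1.5)
        smooth /= smooth.std()
        grain = rng.standard_normal((height, width)) * 0.15
        field = smooth + grain
        lo, hi = field.min(), field.max()
        img = 1 + (field - lo) / (hi - lo) * (_SOURCE_MAX - 1)
        return img.astype(np.uint16), []
    if content == "blobs":
        img = 1000.0 + rng.normal(0.0, 20.0, size=(height, width))
        n = rng.poisson(blob_density * width * height)
        rois: list[Roi] = []
        margin = 12
        for k in range(int(n)):
            cx = rng.uniform(margin, width - margin)
            cy = rng.uniform(margin, height - margin)
            sigma = rng.uniform(3.0, 8.0)
            amp = rng.uniform(10000.0, 40000.0)
            rad = int(math.ceil(4 * sigma))
            x0, x1 = max(0, int(cx) - rad), min(width, int(cx) + rad + 1)
            y0, y1 = max(0, int(cy) - rad), min(height, int(cy) + rad + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += amp * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
            rois.append(Roi(cx, cy, math.pi * (2 * sigma) ** 2, label=f"blob{k:03d}"))
        return np.clip(img, 1, _SOURCE_MAX).astype(np.uint16), rois
    raise ValueError(f"unknown content {content!r}")


def _trivial_tree(rows: int, cols: int
                  ) -> tuple[list[tuple[tuple[int, int], tuple[int, int], str, float]],
                             np.ndarray]:
    """Row-0-then-columns spanning tree used for ground-truth layouts."""
    edges = []
    ncc = np.full((rows, cols), 1.0)
    ncc[0, 0] = -1.0
    for c in range(1, cols):
        edges.append(((0, c - 1), (0, c), "H", 1.0))
    for c in range(cols):
        for r in range(1, rows):
            edges.append(((r - 1, c), (r, c), "V", 1.0))
    return edges, ncc


def simulate_acquisition(source: np.ndarray, rows: int, cols: int,
                         tile_w: int, tile_h: int,
                         overlap_pct: float = 10.0, alpha_deg: float = 1.0,
                         r_px: float = 2.0, backlash_px: float = 0.0,
                         noise_sigma: float = 0.0, bleach_factor: float = 1.0,
                         seed: int = 0, jitter: str = "uniform",
                         rois: list[Roi] | None = None) -> SyntheticAcquisition:
    """Cut ``source`` into a jittered, rotated, overlapping tile grid.

    Nominal steps are tile_w·(1−overlap/100) horizontally and the analogue
    vertically. Per tile, the commanded stage position gets per-axis jitter of
    magnitude ``r_px`` (uniform in [−r, r], or Gaussian with σ = r/2 when
    ``jitter="gaussian"``) plus ``backlash_px`` on the x axis of odd rows
    (serpentine actuator reversal). Camera-frame positions follow from rotating
    the stage lattice by ``alpha_deg`` and are rounded to integers. Tiles are
    crops of the source at those positions; Gaussian pixel noise of
    ``noise_sigma`` is then added (clipped so intensities stay ≥ 1) and overlap
    strips re-imaged after a neighbor are multiplied by ``bleach_factor``.
    """
    rng = np.random.default_rng(seed)
    step_x = tile_w * (1.0 - overlap_pct / 100.0)
    step_y = tile_h * (1.0 - overlap_pct / 100.0)
    a = math.radians(alpha_deg)
    cos_a, sin_a = math.cos(a), math.sin(a)

    px = np.zeros((rows, cols), dtype=np.int64)
    py = np.zeros((rows, cols), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            if jitter == "uniform":
                jx, jy = rng.uniform(-r_px, r_px, size=2)
            elif jitter == "gaussian":
                jx, jy = rng.normal(0.0, r_px / 2.0, size=2)
            else:
                raise ValueError(f"unknown jitter {jitter!r}")
            sx = c * step_x + jx + (backlash_px if r % 2 == 1 else 0.0)
            sy = r * step_y + jy
            # camera observes stage steps through the camera-angle rotation
            px[r, c] = int(round(sx * cos_a + sy * sin_a))
            py[r, c] = int(round(-sx * sin_a + sy * cos_a))
    px -= px.min()
    py -= py.min()
    if px.max() + tile_w > source.shape[1] or py.max() + tile_h > source.shape[0]:
        raise DataError(
            f"grid footprint {py.max() + tile_h}x{px.max() + tile_w} exceeds "
            f"source {source.shape[0]}x{source.shape[1]}")

    dtype = source.dtype
    maxval = np.iinfo(dtype).max if np.issubdtype(dtype, np.integer) else None
    tiles = []
    for r in range(rows):
        for c in range(cols):
            x0, y0 = int(px[r, c]), int(py[r, c])
            img = np.asarray(source[y0:y0 + tile_h, x0:x0 + tile_w], dtype=np.float64).copy()
            if bleach_factor != 1.0:
                # strips already imaged by the west / north neighbor fade
                for (nr, nc) in ((r, c - 1), (r - 1, c)):
                    if nr < 0 or nc < 0:
                        continue
                    ox0 = max(x0, int(px[nr, nc]))
                    ox1 = min(x0 + tile_w, int(px[nr, nc]) + tile_w)
                    oy0 = max(y0, int(py[nr, nc]))
                    oy1 = min(y0 + tile_h, int(py[nr, nc]) + tile_h)
                    if ox1 > ox0 and oy1 > oy0:
                        img[oy0 - y0:oy1 - y0, ox0 - x0:ox1 - x0] *= bleach_factor
            if noise_sigma > 0:
                img += rng.normal(0.0, noise_sigma, size=img.shape)
            img = np.clip(img, 1, maxval) if maxval is not None else np.maximum(img, 1)
            tiles.append(Tile(r, c, img.astype(dtype), f"synthetic_r{r:03d}_c{c:03d}"))

    grid = TileGrid(tiles, rows, cols)
    edges, placement_ncc = _trivial_tree(rows, cols)
    layout = MosaicLayout(x=px, y=py, placement_ncc=placement_ncc, tree_edges=edges,
                          mosaic_width=int(px.max() + tile_w),
                          mosaic_height=int(py.max() + tile_h))
    model = StageModel(overlap_h=overlap_pct, overlap_v=overlap_pct,
                       alpha=alpha_deg, r=max(1.0, float(r_px)))
    return SyntheticAcquisition(
        grid=grid, truth_layout=layout, truth_model=model, source=source,
        rois=list(rois) if rois is not None else [], seed=seed,
        params=dict(rows=rows, cols=cols, tile_w=tile_w, tile_h=tile_h,
                    overlap_pct=overlap_pct, alpha_deg=alpha_deg, r_px=r_px,
                    backlash_px=backlash_px, noise_sigma=noise_sigma,
                    bleach_factor=bleach_factor, jitter=jitter, seed=seed))


def corrupt_translations(tables: TranslationTables, fraction: float,
                         magnitude: int, seed: int
                         ) -> tuple[TranslationTables, dict[str, np.ndarray]]:
    """Replace a random subset of entries with junk displacements.

    Emulates the gross registration failures that feature-poor overlap regions
    produce: each corrupted entry gets uniform dx, dy in [−magnitude, magnitude]
    and a low ncc in [0, 0.2]. Returns the corrupted tables and a per-direction
    boolean mask of which entries were hit.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = tables.copy()
    masks: dict[str, np.ndarray] = {}
    for name, table in (("H", out.h), ("V", out.v)):
        mask = rng.random(table.shape) < fraction if fraction > 0 else \
            np.zeros(table.shape, dtype=bool)
        if fraction >= 1.0:
            mask = np.ones(table.shape, dtype=bool)
        n = int(mask.sum())
        if n:
            table.dx[mask] = rng.integers(-magnitude, magnitude + 1, size=n)
            table.dy[mask] = rng.integers(-magnitude, magnitude + 1, size=n)
            table.ncc[mask] = rng.uniform(0.0, 0.2, size=n)
        masks[name] = mask
    return out, masks
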
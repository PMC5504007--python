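"""Pairwise translation by the Phase Correlation Method (PCM).

The displacement between two overlapping tiles appears, via the Fourier shift
theorem, as a peak in the inverse transform of the normalized cross-power
spectrum. Real microscope tiles produce several peaks (the overlap is partial,
not a cyclic shift), so the top peaks are kept and each peak index is expanded
into its four periodic interpretations; every candidate displacement is scored
by the normalized cross-correlation (ncc) of the implied overlap regions and
the best-scoring candidate wins.

Conventions: a peak at matrix index (row, col) corresponds to candidate origin
offsets (dx, dy) ∈ {col, col−W} × {row, row−H} of the second tile relative to
the first (x rightward, y downward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import TileGrid, Translation, TranslationTables, neighbor_pairs

__all__ = [
    "PhaseCorrelationSurface",
    "phase_correlation",
    "find_peaks",
    "candidate_translations",
    "overlap_regions",
    "ncc",
    "default_min_overlap",
    "pairwise_translation",
    "compute_translation_tables",
]

#: relative guard for zero-magnitude frequencies in the spectrum normalization
EPS_REL = 1e-12


@dataclass
class PhaseCorrelationSurface:
    """Real-valued phase-correlation surface, same shape as the input tiles.

    ``degenerate`` is set when the cross-power spectrum carries no usable
    phase information (e.g. both images constant) and the surface is flat.
    """

    values: np.ndarray
    degenerate: bool = False


def phase_correlation(a: np.ndarray, b: np.ndarray) -> PhaseCorrelationSurface:
    """Inverse transform of the normalized cross-power spectrum of ``a`` and ``b``.

    For ``b`` whose content equals ``a`` sampled at origin offset (dx, dy)
    (cyclically), the surface attains its maximum at index (dy mod H, dx mod W).

    The cross-power spectrum F(a)·conj(F(b)) is normalized by
    max(|·|, ε·max|·|) with ε = 1e−12, guarding zero-magnitude frequencies.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    fa = np.fft.fft2(np.asarray(a, dtype=np.float64))
    fb = np.fft.fft2(np.asarray(b, dtype=np.float64))
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    peak = float(mag.max())
    if peak == 0.0:
        return PhaseCorrelationSurface(np.zeros(a.shape), degenerate=True)
    surface = np.real(np.fft.ifft2(cross / np.maximum(mag, EPS_REL * peak)))
    # flat surface (single non-zero frequency, e.g. constant images) carries no shift
    degenerate = bool(np.ptp(surface) < 1e-9)
    return PhaseCorrelationSurface(surface, degenerate=degenerate)


def find_peaks(surface: PhaseCorrelationSurface, n: int = 2) -> list[tuple[int, int]]:
    """Indices of the ``n`` highest peaks, in decreasing surface value.

    After each selection the peak's 3×3 wrap-around neighborhood is masked so
    successive peaks are distinct features rather than adjacent samples of one
    correlation lobe.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    vals = surface.values.copy()
    h, w = vals.shape
    if n > vals.size:
        raise ValueError(f"requested {n} peaks from a {h}x{w} surface")
    peaks: list[tuple[int, int]] = []
    for _ in range(n):
        flat = np.argmax(vals)
        if not np.isfinite(vals.flat[flat]):
            raise ValueError("surface exhausted: fewer unmasked cells than requested peaks")
        r, c = np.unravel_index(flat, vals.shape)
        peaks.append((int(r), int(c)))
        rr = [(r - 1) % h, r, (r + 1) % h]
        cc = [(c - 1) % w, c, (c + 1) % w]
        vals[np.ix_(rr, cc)] = -np.inf
    return peaks


def candidate_translations(peak: tuple[int, int], shape: tuple[int, int]
                           ) -> list[tuple[int, int]]:
    """The four periodic (dx, dy) interpretations of a Fourier-domain peak index.

    Order is fixed (used as the deterministic tie-break):
    (col, row), (col, row−H), (col−W, row), (col−W, row−H).
    """
    r, c = peak
    h, w = shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"peak {peak} outside surface {shape}")
    return [(c, r), (c, r - h), (c - w, r), (c - w, r - h)]


def overlap_regions(shape: tuple[int, int], dx: int, dy: int
                    ) -> tuple[tuple[slice, slice], tuple[slice, slice]] | None:
    """Slices of the two same-shape rasters that coincide under (dx, dy).

    Returns (slices_into_first, slices_into_second), or None if the rectangles
    do not intersect.
    """
    h, w = shape
    xa0, xa1 = max(0, dx), min(w, w + dx)
    ya0, ya1 = max(0, dy), min(h, h + dy)
    if xa1 <= xa0 or ya1 <= ya0:
        return None
    return ((slice(ya0, ya1), slice(xa0, xa1)),
            (slice(ya0 - dy, ya1 - dy), slice(xa0 - dx, xa1 - dx)))


def ncc(a: np.ndarray, b: np.ndarray, dx: int, dy: int, min_overlap_px: int = 25
        ) -> float:
    """Pearson correlation of the overlap regions of ``a`` and ``b`` under (dx, dy).

    Returns NaN (invalid) when the overlap has fewer than ``min_overlap_px``
    pixels or either region has zero variance.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    regions = overlap_regions(a.shape, dx, dy)
    if regions is None:
        return math.nan
    sa, sb = regions
    ra = np.asarray(a[sa], dtype=np.float64).ravel()
    rb = np.asarray(b[sb], dtype=np.float64).ravel()
    if ra.size < min_overlap_px:
        return math.nan
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    va = float(ra @ ra)
    vb = float(rb @ rb)
    if va <= 0.0 or vb <= 0.0:
        return math.nan
    return float(np.clip((ra @ rb) / math.sqrt(va * vb), -1.0, 1.0))


def default_min_overlap(shape: tuple[int, int]) -> int:
    """Minimum overlap area (px) for a statistically meaningful ncc.

    At least 25 px and at least 1 % of the tile area.
    """
    h, w = shape
    return max(25, int(math.ceil(0.01 * h * w)))


def pairwise_translation(a: np.ndarray, b: np.ndarray, n_peaks: int = 2,
                         min_overlap_px: int | None = None) -> Translation:
    """Best translation of tile ``b`` relative to tile ``a``.

    Evaluates the ncc of all ``n_peaks`` × 4 candidate displacements and
    returns the one with the highest valid ncc. Ties break toward the lower
    peak rank, then the candidate order of :func:`candidate_translations`.
    Returns an invalid Translation (ncc = NaN, dx = dy = 0) when no candidate
    can be scored (e.g. flat tiles); the caller substitutes a nominal value.
    """
    if min_overlap_px is None:
        min_overlap_px = default_min_overlap(a.shape)
    surface = phase_correlation(a, b)
    if surface.degenerate:
        return Translation(0, 0, math.nan)
    best: Translation | None = None
    for peak in find_peaks(surface, n_peaks):
        for dx, dy in candidate_translations(peak, a.shape):
            score = ncc(a, b, dx, dy, min_overlap_px)
            if math.isnan(score):
                continue
            if best is None or score > best.ncc:
                best = Translation(dx, dy, score)
    if best is None:
        return Translation(0, 0, math.nan)
    return best


def compute_translation_tables(grid: TileGrid, n_peaks: int = 2,
                               min_overlap_px: int | None = None
                               ) -> TranslationTables:
    """Pairwise translations for every adjacent pair of the grid.

    Deterministic for fixed inputs; invalid pairs are recorded as-is.
    """
    tables = TranslationTables.empty(grid.rows, grid.cols)
    for ta, tb, direction in neighbor_pairs(grid):
        t = pairwise_translation(ta.image, tb.image, n_peaks, min_overlap_px)
        if direction == "H":
            tables.h.set_entry(ta.row, ta.col, t)
        else:
            tables.v.set_entry(ta.row, ta.col, t)
    return tables
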
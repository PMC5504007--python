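# Methods

## The stitching model

An automated microscope images a specimen larger than one field of view (FOV)
by commanding its mechanical stage to visit an R×C lattice of positions with a
nominal overlap (e.g. 10 %) between adjacent tiles. Three mechanical
imperfections separate the commanded lattice from what the camera records:

* **stage repeatability** r — each visited position deviates from the
  commanded one by up to ±r px per axis, so any *pairwise* translation
  (a difference of two positions) carries up to ±2r of error per axis;
* **actuator backlash** — a systematic offset when an actuator reverses
  direction (serpentine acquisition), shifting whole rows;
* **camera angle** α — a small rotation between the stage's motion axes and
  the camera's pixel axes. A horizontal stage step H is observed as
  (H·cos α, −H·sin α), a vertical step V as (V·sin α, V·cos α).

The pipeline has four stages.

**1. Pairwise translations (phase correlation).** For every adjacent pair the
normalized cross-power spectrum F(a)·conj(F(b)) / |·| is inverted; the true
displacement appears as a peak. Because the overlap is partial and the Fourier
domain periodic, the top two peaks are kept (adjustable), each expanded into
its four periodic interpretations {j, j−W} × {i, i−H}, and every candidate is
scored by the Pearson correlation (ncc) of the two overlap regions it implies.
The best valid candidate wins. Guards: the spectrum denominator is floored at
1e−12 of its maximum; ncc is invalid below a minimum overlap area
(max(25 px, 1 % of the tile)) or at zero variance; each selected peak's 3×3
wrap-around neighborhood is masked so the second peak is a distinct feature.
No windowing function and no subpixel interpolation are applied.

**2. Stage-model estimation.** Unless supplied by the user, four quantities
are estimated from the raw translation tables H (west→east) and V
(north→south), using only *trusted* entries — valid ncc ≥ 0.5 and primary
displacement within [0.45·extent, extent):

* overlap per direction: 100·(1 − median(primary displacement)/extent);
* camera angle: pooled median of per-pair angles, atan2(−dy, dx) for H
  entries and atan2(dx, dy) for V entries;
* repeatability: per direction and axis, half the 2.5–97.5 percentile span of
  trusted displacements; r = ceil(max of the four spreads), floored at 1 px;
* backlash: treated as a tolerance band (default ±3 percentage points of
  overlap). When a commanded (nominal) overlap is known and the estimate
  deviates by more than the band, the estimate is deemed unreliable: the
  nominal value is used and r is widened to backlash_tol·extent/100.

All estimators are medians/percentiles because feature-poor overlap regions
produce grossly wrong translations that must not drag the estimates. The
trust band's lower edge is 0.45 (not 0.50) of the tile extent so that an
acquisition commanded at exactly 50 % overlap does not have half of its
jittered displacements truncated, which would bias the median estimate by
about r/2 px.

**3. Constrained optimization.** H is filtered column-wise and V row-wise
(one commanded step per column/row): entries deviating from the line median
by more than 4r on either axis are replaced by the line median and flagged
repaired. Line medians are computed over trusted, unrepaired entries and
require at least two of them — a single trusted entry may itself be a
high-scoring false registration — otherwise the table-wide trusted median is
used, and with no trusted entries anywhere, the model's nominal displacement.
The filter is idempotent. Every entry is then refined by steepest-ascent hill
climbing on the ncc surface over the integer displacement lattice
(8-connected unit steps, memoized evaluations), confined to the square window
of side 4r centered on its start — the maximum error the stage model allows.
The final ncc never drops below a scorable start (ascent invariant) and the
displacement never moves more than 2r per axis (confinement invariant).

**4. Assembly.** Tiles are vertices of an undirected graph; each adjacent
pair contributes an edge weighted by its optimized ncc. Edges whose
displacement lies within 4r of the model's nominal displacement get +1 weight
— strictly above any unboosted ncc — and invalid edges get a large negative
sentinel, used only if connectivity demands. Kruskal's algorithm with a
deterministic tie-break (weight desc, H before V, then row, col) extracts the
maximum spanning tree; positions accumulate along tree edges from tile (0,0)
and are min-normalized. Rendering modes: overlay (last tile wins), average,
and linear blending with pyramid weights
w(u,v) = (min(u+1, W−u)/⌈W/2⌉)·(min(v+1, H−v)/⌈H/2⌉); accumulation in float,
output clipped to the input dtype. Positions are integers throughout; there
is no subpixel resampling.

## Accuracy metrics

Given reference ROIs (e.g. colony centroids measured on the stage) and ROIs
from a stitched mosaic: the computed set is rigidly aligned onto the
reference frame (Kabsch via SVD, proper rotation enforced) using a
provisional nearest-centroid matching, then matched by the Hungarian
algorithm on a similarity matrix (negative centroid distance by default, ncc
of image patches optionally). Matched pairs farther apart than half the
smaller FOV dimension (configurable) are broken and counted as one FN plus
one FP. Per-pair errors are the centroid distance
D_err = √((x_m−x_c)²+(y_m−y_c)²) and the signed percent area error
S_err = (A_c−A_m)/A_m·100. Blank pixels — zero-valued pixels inside the union
of placed tile rectangles — flag stitching gaps.

## Synthetic acquisitions

The generator cuts a large source raster into a tile grid exactly the way the
stage model says a microscope would: nominal steps tile·(1−overlap/100),
per-position jitter uniform in [−r, r] (repeatability is a bound, not a
variance; a Gaussian option with σ = r/2 exists), a constant x offset on odd
rows (backlash under serpentine motion), and the whole position lattice
rotated by α before integer rounding — α acts on positions, not as image
rotation, because the stitcher is integer-resolution (valid for the small-α
regime the model addresses). Optional Gaussian pixel noise and a
multiplicative intensity decay on strips re-imaged after a neighbor (a
photobleaching stand-in that stresses ncc scoring, not a fluorophore model)
complete the picture. Source contents: ``blobs`` (Poisson-placed Gaussian
blobs on a noisy background — sparse colonies; blob centroids/areas are
recorded as ROIs with area defined as a 2σ disc), ``texture`` (band-passed
noise plus fine grain — confluent, feature-rich specimens), ``flat``
(degenerate). Textures are deliberately broadband: a purely low-pass field
would leave the whitened cross-power spectrum dominated by numerical noise at
high frequencies, which no real detector produces. Minimum intensity is 1 so
the value 0 stays reserved for blank pixels.

Defaults (10 % overlap, r = 2 px, α = 1°, no added noise) mirror a typical
low-density stem-cell plate acquisition on a good motorized stage (1–2 µm
repeatability at ~0.65 µm/px).

What the generator does **not** emulate: optics (PSF, vignetting,
flat-field), stage drift over time, specimen growth, and non-integer tile
offsets. Passing tests therefore demonstrate correctness of the registration,
modeling, optimization and assembly machinery under the stage model's own
assumptions — not robustness to optical artifacts.

## Problem sizes and numerical choices

Tests and the acceptance script run 5×5 grids of 64–256 px tiles (256 px for
stage-parameter recovery, where angle resolution scales with the step
length); these sizes exercise every code path while keeping the suite fast.
Key tolerances and tie-breaks: ncc trust threshold 0.5 (configurable);
equal-ncc candidates resolve by peak rank then candidate order; median ties
break toward the lower value; MST ties break by direction then grid index;
hill climbing moves only on strict improvement, so equal-score plateaus are
fixed points. Degenerate inputs (flat tiles, zero spectra, empty overlaps)
produce flagged invalid values that downstream stages replace by
model-nominal displacements; a grid with no trusted direction and no
user-supplied parameters fails with "cannot model stage".

## Known limitations

* Integer-pixel positions only; subpixel accuracy is out of scope.
* One global overlap per direction: acquisitions with deliberately varying
  overlap violate the stage model and are flagged by the backlash check at
  best.
* The two-peak default can miss the true peak when the genuine overlap extent
  drops below ~25 px on an axis; raising ``n_peaks`` trades time for
  robustness.
* Greedy hill climbing finds the window's global maximum only on unimodal ncc
  surfaces; on multimodal surfaces it stops at a local maximum (never below
  its start).
* The camera-angle model is a pure rotation; lens distortion, scale and shear
  are not estimated.
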
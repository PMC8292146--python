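# Methods

## Linear mixing model and unmixing

A multispectral tile stores, per pixel, intensities across B acquisition
bands. We assume each pixel is a non-negative linear combination of the
emission spectra of the panel fluorophores (DAPI, the Opal series, plus a
constant autofluorescence spectrum), recorded in a spectral library. Spectra
are max-normalized to 1 (not unit-sum), so abundance units follow pixel
intensity units. Unmixing solves per-pixel non-negative least squares
against the library matrix. Implementation detail: the unconstrained
least-squares solution is computed for all pixels in a single solve; only
pixels whose solution violates non-negativity beyond a small tolerance
(10⁻⁸ relative to the pixel magnitude) are re-solved with the active-set
NNLS routine. This is exact, deterministic, and fast on noise-free data
where the unconstrained solution is already feasible.

The library must have full column rank and at least as many bands as
fluorophores; both are enforced at construction. Autofluorescence is kept as
a channel during unmixing and simply discarded downstream rather than
subtracted — this keeps the least-squares problem well posed without
assuming a background model.

Abundance planes are stored as 32-bit floats; quantization to 8 bits happens
only in brightfield synthesis. The float32 storage bounds abundance
round-trip accuracy at ~6·10⁻⁸ relative, well inside the 10⁻⁶ tolerance the
tests assert.

## Stitching

Tiles carry their global origin; stitching pastes each unmixed plane at its
origin on a zero canvas. The acquisition produces non-overlapping tiles, so
no blending rule is needed; should tiles overlap, the mosaic is
last-written-wins with a logged warning. For non-overlapping tilings the
result is order-invariant and exact.

## Artificial brightfield synthesis

With I_DAPI and I_IHC normalized to [0, 1], each RGB channel is
`255·exp(−(I_DAPI·c_ch,Hem + I_IHC·c_ch,DAB))` — the Beer–Lambert
transmission of a virtual hematoxylin/DAB double stain. Defaults are the
Ruifrok–Johnston optical-density triplets, hematoxylin (0.650, 0.704, 0.286)
and DAB (0.269, 0.568, 0.777); both vectors are configurable. Intensity
normalization uses the per-plane 99.9th percentile by default (robust to hot
pixels) and accepts a fixed constant for cross-slide comparability; which
scaling the original acquisition software applied is not documented, so this
choice is ours. All arithmetic is floating point; rounding
(half-away-from-zero) to 8 bits happens once at the end. Because the two
stain vectors are linearly independent, the 3×2 optical-density system can
be inverted by least squares; on the pre-quantization float image this
recovers (I_DAPI, I_IHC) to machine precision, which both the tests and the
end-to-end pipeline exploit (the reference detector runs on the
deconvolved DAB plane, so the brightfield stage is genuinely in the loop).

## Detection decoding

Probability maps are thresholded (0.7 for the strongly stained CD3 channel,
0.4 for other lymphocyte channels), connected components are taken with
8-connectivity, and components whose centroids lie closer than a minimum
separation (default: one cell diameter — 4 µm lymphocytes, 21 µm
macrophages) are merged transitively; each group yields one detection at the
pixel-weighted centroid with confidence equal to the group's maximum
probability. Component centroids were chosen over local maxima because the
original postprocessing is unspecified; centroids are parameter-free and
stable under plateaus. Raising the threshold never increases the detection
count for isolated unimodal objects; the property can fail when a ridge
connecting two peaks is cut by a higher threshold (one component splitting
into two distant ones), which the tests document by asserting monotonicity
on separated-blob fields only.

Box candidates go through greedy non-maximum suppression: drop candidates
below the objectness threshold (0.45 for macrophage boxes), then keep boxes
in descending objectness (ties broken by (y, x)), suppressing remaining
candidates whose intersection-over-union with a kept box exceeds the overlap
threshold. The published suppression parameter 0.05 is interpreted as an IoU
threshold; the original overlap measure is not stated.

The reference blob detector is a negated Laplacian-of-Gaussian filter at
σ = r/√2 for target radius r, returning local maxima at least a relative
threshold (default 0.1) times the global maximum response, with a minimum
peak distance of one radius. It is the deterministic stand-in for trained
detectors on synthetic scenes; it is not a macrophage/lymphocyte CNN and no
claim is made about its performance on real tissue.

Lymphocyte decoding operates at 0.49 µm/px and macrophage decoding at
0.98 µm/px; radii and separations are configured in micrometres and
converted through the pixel size.

## Matching and scoring

A detection is true positive if it lies within one average cell diameter of
an unclaimed annotation. The "closest detection wins" rule is realized as a
global one-to-one greedy assignment over all (detection, annotation) pairs
with distance ≤ radius, in ascending distance order, ties broken by
(annotation index, detection index). This is deterministic, reproduces the
two-detections-one-annotation case exactly, and is a maximal matching —
within a factor two of the maximum-cardinality assignment and equal to it
except in alternating-chain configurations, which the tests flag explicitly.
The boundary convention is ≤ radius for detection matching (a strict flag is
available) and strictly < radius for double positivity. Scores over a slide
set pool summed TP/FP/FN rather than averaging per-slide scores.

Precision, recall and F1 follow the standard definitions with 0/0 defined as
0. Of the six published precision/recall/F1 triplets, five reproduce as
rounded harmonic means; the legacy cytoplasmic-detector row on conventional
IHC (0.76, 0.79 → printed 0.78) rounds to 0.77 instead, indicating it was
computed from unrounded inputs — noted, not corrected.

## Spatial quantification

ROIs are shapely geometries: inclusion polygons minus exclusion polygons,
areas reported in mm². The subcapsular band is the part of the ROI within
400 µm *Euclidean* distance of the capsule polyline (capsules curve, so a
buffer is used rather than a vertical offset); band and remainder partition
the ROI. Boundary points count as inside. Double positivity and population
subtraction (CD3⁺CD8⁻ = CD3 detections with no pairable CD8 within 4 µm)
share the greedy one-to-one pairing engine, so one B-cell can never validate
two A-cells and the two outputs partition A exactly. Mean shortest distance
is the average over source cells of the Euclidean distance to the nearest
target cell (k-d tree), reported in µm and px; it is asymmetric by
construction and flagged undefined for empty populations. Positive-pixel
percentage thresholds the plane inside the rasterized ROI with Otsu's method
by default (the original work used an unnamed automatic threshold in an
image-analysis GUI) or a fixed threshold for reproducibility.

## Cohort statistics

Mann–Whitney U: for combined n ≤ 20 the two-sided p-value is computed from
exhaustive enumeration of all group assignments of the pooled average ranks
(exact under ties), p = 2·min(P(U≤u), P(U≥u)) capped at 1; larger samples
use the tie-corrected normal approximation with continuity correction. The
exact path is validated against an independent implementation on tie-free
data. Spearman correlation uses average ranks with the t-approximation for
p; constant input is flagged undefined. The Wilcoxon signed-rank test drops
zero differences and flags the all-zero case as no-test. Fisher's exact test
is two-sided by summing tables with probability ≤ the observed one.
Group summaries report median (min–max) for densities and percentages and
mean (SD) for ratios; missing values (e.g. undefined ratios from a zero
denominator) are excluded per column with an explicit count, never silently.
No multiple-testing correction is applied by default; Benjamini–Hochberg is
available as an option.

## Synthetic scenes: what they emulate and what they do not

The generator plants cells uniformly inside a rectangular ROI (default
pixel size 0.49 µm/px) with a minimum center separation of one cell radius —
enough to avoid pathological merges while still exercising clustered
neighbourhoods. Cells render as isotropic Gaussian bumps with σ = radius/2
(radius 4 µm for lymphocytes, 21 µm for macrophages); every cell carries
DAPI. Double positives are planted exactly as round(fraction · population
size). The capillary mask is a smoothed Gaussian random field thresholded at
the quantile that makes the positive fraction of ROI pixels exactly the
requested value. Optional additive band-wise Gaussian noise (clipped at 0)
exercises the non-negativity of unmixing, and a fluorophore×fluorophore
bleed matrix (unit diagonal, off-diagonal in [0, 1)) emulates cross-talk
such as a strong CD68 signal bleeding into the CD4 channel. Everything is
deterministic under the scene seed, byte-for-byte.

These scenes deliberately lack tissue texture, autofluorescence structure
beyond a constant spectrum, staining gradients, artifacts, and the
cell-shape and annotation ambiguity of real biopsies. Passing end-to-end
tests therefore demonstrates that the computational chain is faithful
(rendering inverts exactly through unmixing, conversion, detection and
quantification), not that any detector achieves the published F1 on real
tissue.

## Problem sizes and defaults

End-to-end validation runs two 550×550 µm scenes (≈1122² px at 0.49 µm/px,
30 acquisition bands, 256-px tiles): a panel-I scene with 130 planted cells
plus an 8% capillary fraction, and a panel-II scene with 98 cells, sizes
chosen to give every population enough members for stable densities while a
full run stays in the tens of seconds. Null-distribution checks use 2000
replicates at group sizes 11 and 13. Tile size defaults to 256 px,
non-overlapping (the acquisition system's tile geometry is not published).

## Known limitations

- The trained detection networks themselves are out of scope; only their
  decoding contracts (thresholds, NMS, resolutions) are implemented, with
  the LoG detector as the test stand-in.
- Cohort-level biological findings (group density differences, correlations)
  are not reproducible computationally because the biopsy images and
  annotations are not public; the statistics layer is validated on
  simulated cohorts instead.
- Overlapping-tile blending, flat-field correction and spectral-library
  estimation from single-stain slides are not implemented.
- Greedy one-to-one matching can undercount TP by one per alternating chain
  relative to an optimal assignment; this mirrors the published rule rather
  than optimizing the score.
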
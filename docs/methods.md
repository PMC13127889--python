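# Methods

`ki67quant` quantifies the Ki-67 labeling index (LI) — the percentage of
immunopositive nuclei among all nuclei — on brightfield H-DAB whole-slide
images. This note describes the model behind each stage, the parameters
that matter, what the synthetic phantom does and does not emulate, and the
numerical choices a maintainer would want spelled out.

## Optics and stain model

Brightfield H-DAB slides transmit light through two absorbers:
hematoxylin (blue, binds all nuclei) and the DAB chromogen (brown, marks
Ki-67). In optical density, OD_c = −log10((I_c+1)/(bg_c+1)) per channel
(the +1 avoids log 0; OD is clipped at zero because pixels brighter than
the background white point carry no stain signal), absorbances add
linearly (Beer–Lambert), so each pixel is a non-negative combination of
two unit "stain vectors". We start from the published generic H-DAB
matrix, H = (0.651, 0.701, 0.290) and DAB = (0.269, 0.568, 0.778)
(normalized), and re-estimate both per slide:

1. **Background**: Gaussian-smooth each channel (σ 2 px), take the
   per-channel mode over pixels above the 75th luminance percentile
   (glass), falling back to the global mode on constant images.
2. **Vector estimation**: tissue pixels are OD-transformed and gated to
   total OD ∈ [0.05, 1.0] (drops glass and opaque pigment). Each pixel's
   angle in the plane spanned by the default H and DAB directions assigns
   it to the blue or brown cluster (split at the midpoint angle); each
   cluster is then restricted to its extreme-angle decile and summarized
   by the geometric median (Weiszfeld), normalized. The decile refinement
   matters: pixels near the split are physical mixtures — positive-nucleus
   edges, DAB haze over counterstain — and including them drags both
   estimates toward each other by 5–15°. Clusters under 50 pixels keep the
   default vector.
3. **Weak-hematoxylin flag**: true iff the red component of the unit H
   vector is ≥ 0.7. A red-heavy estimate means the blue dye signal is so
   faint that the vector has drifted toward the red/residual axis; the
   component index and cutoff are config keys (`stain.weak_h_component`,
   `stain.weak_h_cutoff`). The flag raises the tissue threshold and
   switches nucleus normalization to image level.

Deconvolution inverts the 3×3 basis (H, DAB, residual = normalized cross
product) exactly; negative coefficients are clipped to zero. A basis with
determinant below 1e-6 is rejected as singular.

## Tissue segmentation

Two pixel classifiers run at a 4.0016 μm/px working grid after Gaussian
smoothing of the red channel with σ = 8 px (≈ 32 μm):

- **Preliminary**: keep smoothed red strictly > 80. Dark artifacts — pen
  ink, debris — fall below; glass stays in. Components < 20,000 μm² are
  removed and holes < 8,000 μm² filled (8-connectivity, ≥ keeps).
- **Refined**: keep smoothed red strictly below a stain-adaptive custom
  threshold, intersected with the preliminary mask; components
  < 10,000 μm², holes < 8,000 μm². The custom threshold is
  `background_red − margin`, margin 40 for normally stained slides and 15
  for weak-hematoxylin slides (a weakly stained slide barely darkens the
  red channel, so the threshold must sit closer to the background),
  clamped to [10, 250]. After hole filling the mask is re-intersected
  with the preliminary mask so refined ⊆ preliminary holds even when a
  filled hole coincides with a preliminarily removed island.

With a 32 μm smoothing kernel, the mask boundary sits where the blurred
edge profile crosses the threshold — for the default margin that is
roughly 30 μm inside the true tissue edge. On centimeter-scale slides
this rim is negligible; on sub-millimeter phantoms it biases the
annotation area low by up to ~20%, which is why the phantom keeps its
ground-truth nuclei 40 μm inside the tissue boundary.

The smoothed raster is rounded to 1e-6 before comparison so that the
strict inequalities of the thresholds cannot flip on floating-point
filter jitter.

## Nucleus segmentation

Detection runs at 0.5 μm/px on the combined H+DAB OD channel (every
nucleus carries at least one of the dyes) in 1024 px tiles with 64 px
overlap. Intensities are normalized linearly between the 1st and 99th
percentile of the tile's tissue pixels — or of the whole image's tissue
pixels when the slide is flagged weak-hematoxylin, because local
normalization on weak slides amplifies glass into phantom signal. Values
outside the percentile band are not clipped.

The backend is pluggable (`nuclei.backend`). The bundled reference
segmenter is deterministic and classical:

- foreground cut = median + max(3·1.4826·MAD, 0.02·range) over the
  tile's tissue pixels. The median/MAD measure the unstained background
  (nuclei cover well under half of any tissue); a mode-seeking threshold
  such as Otsu's was tried and rejected because it bisects the background
  texture on tiles containing few or no nuclei.
- distance-transform watershed with seeds ≥ 6 μm apart (one typical
  nucleus diameter) splits touching nuclei.
- each instance's boundary is refined to the half-contrast level between
  its interior and the local ring background, removing the dim halo the
  low global cut admits (the halo would otherwise dilute the instance's
  mean DAB).
- area filter 10–400 μm² (debris and clumps); saturated-pigment gate:
  instances with interior OD > 1.2 are discarded — pen ink and
  hemosiderin-like debris deconvolve to combined OD 1.4–2, while the
  darkest plausible nucleus stays below ~1.
- pseudo-probability = min(1, (median interior OD of the 2-px-eroded
  core − median ring OD) / 0.3), clipped at 0. On an empty background
  this reduces to interior/0.3 (a disk of OD 0.06 scores 0.2); on
  counterstained tissue it measures stained-ness *above* the local
  background, so texture blobs score near zero. Detections under the
  0.25 probability threshold are dropped.

Tile overlaps are deduplicated by core ownership: a detection is kept by
the tile whose interior (overlap-free) rectangle contains its centroid.
Detections whose centroid falls outside the tissue mask are discarded,
and output is sorted by (y, x) so runs are reproducible. An adapter for a
pretrained star-convex polygon model is included and selected with
`backend="stardist"`; it raises a clear error naming the packages to
install when they are absent.

## Classification and labeling index

The DAB raster (at detection resolution, area-average downsampled 4×) is
histogrammed over OD [0, 2] in 256 bins within the tissue mask, and
thresholded with the triangle (Zack) rule: a line joins the histogram
peak to the far end of the longer tail, and the threshold is the bin
whose point lies farthest from that line (histogram flipped and the
result mirrored when the long tail is on the left; ties break toward the
tail). The selected bin's lower edge, in OD units, becomes the slide's
threshold, so a nucleus whose mean DAB lands exactly in the threshold bin
classifies positive — consistent with the equal-or-above rule: positive
iff mean DAB OD ≥ threshold. LI = 100·n_pos/(n_pos+n_neg), NA (NaN) when
no cells were detected. The triangle rule suits DAB histograms because
they are extremely skewed — a dominant near-zero background mode with a
long positive tail — and it lands at the "corner" where the background
mass ends. Its known failure mode is preserved, not patched: on a slide
with no positive tail the corner sits low in the background distribution,
so truly negative slides are best generated/validated with trace-level
negative DAB.

## Density maps

Density at a map cell = count of classified nuclei within a 50 μm radius
of the cell center (Euclidean, boundary-inclusive, flat kernel — the
literal search-radius semantics; a Gaussian kernel is available in
config), divided by the disk area, in cells/mm². The map grid is 8 μm/px.
One isolated cell yields a plateau of 1/(π·0.05²) ≈ 127.32 cells/mm².
The LI map is pos/(pos+neg) per cell, NA where no cell is in reach. Raw
maps are written as 16-bit grayscale TIFF with a JSON scale sidecar;
renders are min-max normalized over non-NA cells through a matplotlib
colormap with NA as background.

## Cohort statistics

Per-slide summaries aggregate into group tables (median, mean, sample sd,
min, max for LI and the two class densities; sd is NA for single-slide
groups; groups ordered by descending median LI with the group name as a
deterministic tie-break). Group differences use the tie-corrected
Kruskal–Wallis H with a chi-square (k−1 df) p-value; a family of tests is
Bonferroni-adjusted (p_adj = min(1, m·p), m recorded in the report).
Method agreement uses Spearman's ρ (average ranks for ties), ICC(2,1) —
two-way random effects, absolute agreement, single measurement, computed
from the two-way ANOVA mean squares; negative estimates are reported as
computed, not clamped — and an OLS regression of the second method on the
first. The absolute-agreement form was chosen because method comparison
asks whether two tools produce the *same numbers*, not merely correlated
ones; `agreement_stats(x, x+c)` correctly returns ρ = 1 with ICC < 1.
These statistics are implemented from the rank/ANOVA definitions; the
test suite cross-checks them against scipy and pingouin to 1e-10/1e-8.

## Synthetic phantom

The generator inverts the exact forward model the pipeline assumes —
deliberately, so end-to-end error isolates pipeline decisions rather than
model mismatch. A slide is an elliptical tissue region on a glass
background (default RGB 243) carrying:

- a diffuse hematoxylin counterstain, OD 0.15 — enough red-channel
  absorption for the tissue classifiers to see the tissue even where
  cellularity is low;
- a nonspecific DAB haze: |Gaussian field|, σ 0.04 OD, correlated at
  50 μm. Real slides always show faint brown background; a phantom
  without it makes the triangle histogram degenerate (the corner collapses
  onto the zero spike) and would break *any* histogram-corner threshold;
- elliptical nuclei (radius U(3, 6) μm, aspect 0.75–1, anti-aliased, with
  ≥ 1 μm boundary separation under uniform placement) that replace the
  underlying tissue OD. Negative nuclei: hematoxylin N(0.5, 0.1)
  truncated > 0.2, DAB N(0.03, 0.02) truncated to [0, 0.06] — an
  immunonegative nucleus with strong DAB would be a contradiction in
  terms. Positive nuclei: DAB N(0.6, 0.1) truncated > 0.3 with
  hematoxylin suppressed to 5%, as the brown chromogen optically masks
  the counterstain;
- nuclei are placed ≥ 40 μm inside the tissue edge, because the coarse
  classifier cannot localize the boundary more finely and the phantom is
  meant to measure detection and classification, not boundary effects;
- optional artifacts: a pen-mark stroke (opaque blue ink), dark debris,
  a bright hole, and a left-side control-tissue block (a second,
  positive-heavy tissue ellipse whose nuclei are *not* part of the
  ground-truth counts). `tissue_side="right"` reproduces the
  control-block tissue geometry without the block, giving an exact
  comparator for crop experiments.

RGB = (bg+1)·10^(−OD) − 1, rounded to uint8 — the exact inverse of the
OD transform, so noiseless round trips agree within one gray level. All
randomness flows through one seeded generator; synthesis is a
deterministic function of (spec, seed).

What the phantom does **not** emulate: tissue texture and cytoplasm,
chromatin substructure, out-of-focus and illumination gradients, scanner
noise beyond optional Gaussian pixel noise, stain-vector drift within a
slide, overlapping nuclei beyond the clustered-placement mode, and
non-tumor cell types. Passing the synthetic suite therefore demonstrates
the pipeline's internal consistency and its behavior under the modeled
physics; it does not certify accuracy on scanned tissue, where the
pretrained star-convex backend rather than the classical reference
segmenter would be the appropriate choice.

## Problem sizes and runtime

The test-suite and acceptance-script fixtures range from 40 to 2,000
nuclei per slide (slides 0.5–1.3 mm across, chosen so the
minimum-separation packing stays below ~30% exclusion coverage) and
cohorts of 4–8 slides; these sizes keep a full run in minutes on one CPU
while covering the labeling-index range (0.5–50%) reported for pediatric
brain-tumor types. Measured recovery on artifact-free phantoms:
positive- and negative-count errors ≤ ~2%, LI error ≤ ~0.5 points,
stain-vector errors ≤ ~1.6°.

## Known limitations

- The triangle threshold degrades on slides with (near-)zero positive
  fraction; the threshold can sit inside the negative/background DAB
  distribution (see above).
- The tissue-mask boundary is biased inward by the working-resolution
  smoothing; annotation areas (and hence densities) on very small tissue
  fragments are underestimated.
- The reference segmenter assumes roughly convex, size-bounded nuclei and
  a background-dominated OD histogram; it is a validation backend, not a
  replacement for a learned model on real tissue.
- Pixels shared by overlapping nuclei count toward both means; with the
  default separation constraint this is rare, but the clustered placement
  mode deliberately produces merges and undercounts.
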
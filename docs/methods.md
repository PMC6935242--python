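# Methods

This note documents the models, conventions and numerical choices behind
the package, the reasoning where the design was genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## The detection model

The pipeline treats ki67-index estimation as staged binary-mask refinement
rather than end-to-end learning. Two small, interpretable classifier
families carry all the learning:

* a **3-class pixel color tree** over (red, blue, hue) that splits
  candidate pixels into positive-nucleus / negative-nucleus / background;
* two **binary shape trees** (one per stain polarity) over a 20-feature
  morphological descriptor that decide whether a binary region is
  nucleus-shaped.

Both are CART decision trees with class posteriors at the leaves
(`max_depth` 8; `min_samples_leaf` 5 for the pixel tree, 1 for the shape
trees, whose training sets hold only tens of regions). Trees serialize to
JSON (split feature, threshold, leaf posteriors) and prediction runs on
those arrays directly, so saved models are portable and human-readable.

The color tree is trained on, and applied to, the colors of the
*preprocessed* image — the image an annotator actually sees. The
STRESS-enhanced image serves only the candidate threshold. This division
of labor matters: envelope stretching is rank-based, so it maximizes local
contrast but discards the absolute color that separates DAB brown from
hematoxylin blue. In sparse fields, where a pixel's sampling disk usually
holds only its own nucleus and background, both stains stretch to
near-black and hue becomes noise; classifying original colors avoids this
while the enhanced image still decides *where* nuclei are.

## STRESS enhancement

Each pixel becomes the mean over `n_iter` iterations of its value
stretched between the per-channel min/max of `n_samples` pixels drawn
uniformly (with replacement) from the disk of radius `radius` around it.
Conventions, fixed so that a naive reference loop reproduces the
implementation bit for bit:

* candidates are integer offsets in the Euclidean disk, centre excluded,
  clipped to the image (and to the mask, in the masked variant),
  enumerated in row-major offset order;
* pixels are visited row-major; every in-mask pixel consumes an
  `n_iter × n_samples` block of float64 uniforms (iteration-major); a
  uniform `u` selects candidate `min(floor(u·ncand), ncand−1)`; a pixel
  with no candidates passes through unchanged;
* degenerate envelopes (min = max) keep the original value, so constant
  areas are preserved exactly;
* output is float64 clamped to [0, 255].

Defaults are `n_iter=128`, `n_samples=8` at 20x (doubled at 40x). The
sampling radius defaults to the *extent* (≈ diameter) of the largest
annotated nucleus: the radius statistics harvested from annotations
measure the half-extent (mean skeleton-to-border distance), while the
envelope must reach past a whole nucleus to see background. The same
extent scaling puts the LoG scale ladder (σ = r/3 for integer r over the
annotated scale range) into its blob-matched regime; with σ tied to the
half-extent instead, the filters behave as edge detectors and the vote
image degenerates into boundary rings (verified empirically on synthetic
pairs).

The hot loop is a numba kernel fed by pre-generated uniform blocks
(~128 MB per chunk), which keeps the documented RNG stream while running
a 512×512 field in ~10 s on one CPU.

## Shape descriptors

Per region (one 8-connected component, ≥5 px): isoperimetric compactness
4πA/P² (perimeter via the weighted 4-neighborhood boundary-walk
estimator, which is within ~3% on disks), eccentricity and axis lengths
of the second-central-moments ellipse, convex-hull area, perimeter, area,
P/A, min and max Euclidean distance from the topological skeleton to the
border, their ratio, bounding-box area, A/BB, and seven ratios relating
area and axes to the annotated per-polarity size statistics
(min/med/max of area and radius). A region's scalar "radius" is the mean
of its min and max skeleton-to-border distances. Positive and negative
codings share the first 13 entries and differ only in the last seven.

## Multiscale separation

**LoG voting.** At every integer scale r in the annotated range, the gray
image (BT.601 luma of the preprocessed tile) is filtered with a
Laplacian-of-Gaussian (σ = r/3, support truncated at r; positive response
= dark blob). The top 65% of in-mask pixels per scale each gain one vote.
The vote image is thresholded per connected region at
{75, 60, 45, 30, 15}% (count semantics, ceil), and components the shape
tree accepts are recorded and removed immediately. Integer votes tie in
large blocks, and resolving ties in scan order systematically biased
every accepted core toward the top of its region; ties are therefore
broken by the summed z-scored filter response, which is deterministic and
spatially unbiased (scan order remains the last resort).

**Masked-STRESS separation.** Each surviving region is re-enhanced with
masked STRESS at every radius from its minimum to its median thickness,
then thresholded at {85, 70, 55, 40, 25}% of the *lowest* values — here
by value, ties included, so a perfectly flat region stays one component.
Components pass if their area lies strictly inside
(min annotated area / 2, max annotated area) and their moments-ellipse
axis ratio exceeds 0.6. Regions at or below the area floor are skipped
outright (no subset of them can ever qualify — a pure optimization).

**Leftovers.** Remaining components are admitted as detections, subject
to a minimum-area floor that defaults to half the smallest annotated
nucleus area — the same floor the eligibility rules use. Setting it to 0
admits everything; on noisy fields that floods the result with color-leak
specks, which is why the floor is the default. Thin leftover fragments
(median thickness < 0.8 × the polarity's smallest annotated radius) that
touch an accepted detection are arcs stranded when that nucleus's core
was removed; their pixels are attributed to the touching detection
instead of becoming new nuclei.

**Recomposition.** Duplicates (tile overlap, core/fragment pairs) are
merged by centroid proximity within the polarity's median annotated
radius; the earlier-stage detection wins (isolated > LoG > stress >
leftover), then the larger area.

## Estimators

With per-polarity counts n and segmented areas A, and annotated median
areas medA:

* indexEst = 100·n⁺/(n⁺+n⁻)
* AreaEst = 100·A⁺/(A⁺+A⁻)
* NoEst   = 100·(A⁺/medA⁺) / (A⁺/medA⁺ + A⁻/medA⁻), counts kept
  fractional.

All are `None` (undefined, not zero) when nothing is detected.

## The synthetic generator

Fields emulate the relevant structure of Ki-67 IHC material: rotated
ellipse nuclei (axis ratio 0.7–1.0), positive nuclei larger than negative
(default radius ranges 6–10 px and 5–7 px give median areas near real
training material, ~190 and ~115 px), a light near-neutral background,
per-nucleus color jitter, radial shading (darkest centre), smooth
channel-independent chromatin-like texture, touching clusters rendered as
one low-contrast clump whose internal seams are thin, slightly lighter
interstices of per-contact visibility (uniform in 0.3–1.7 × a 10% base
contrast — some contacts are nearly invisible), "weakly positive" nuclei
mixing both stains, faint nuclei at 3% opacity (raw mean just *above* the
225 candidate threshold, so only enhancement makes them segmentable —
the defining property of "barely visible"), small saturated deposits,
Gaussian and salt-and-pepper noise. Defaults describe a 512×512 field
with 150 nuclei, 30% positive, 30% clustered.

Not modelled: real tissue texture and stroma, staining chemistry,
vignetting/color cast, scanner optics, out-of-focus planes. Passing tests
therefore demonstrate the pipeline's mechanics — enhancement, color
separation, cluster splitting, index arithmetic — under controlled
conditions, not clinical performance.

Training annotations are auto-generated: exact pixel-edge boundary
polygons of sampled nuclei (vertices on pixel corners, so rasterization
reproduces the pixel set bit for bit) plus background regions shaped as
elongated bars, oversized round blobs and tiny specks — spanning what the
shape trees must reject. Merged-pair (dumbbell) negatives were tried and
rejected: at realistic training-set sizes (~20–30 regions per class) they
starved the other negative kinds and degraded the trees.

## Numerical conventions

0-based (row, col) coordinates; 8-connectivity for all mask operations;
percentile counts via ceil; seeds derived per tile/region/stage from a
`SeedSequence` so runs are exactly reproducible; hue in [0, 1) without
circular treatment (brown and blue sit far from the wrap point).

## Known limitations

* Detected regions for clustered nuclei are threshold *cores*, not whole
  nuclei; their centroids carry a 2–7 px bias away from cluster seams and
  their areas undercount, which feeds through to AreaEst/NoEst on heavily
  clustered material. Whole-field index recovery is nonetheless within a
  few points (the biases largely cancel between polarities).
* Clusters whose seams have no intensity expression at all separate only
  by scale information and often survive as single detections.
* The color tree assumes the two stains keep distinct hue families; heavy
  color cast would require retraining (the trees are cheap to retrain by
  design).
* Tumor-region identification is an input, not a result.
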
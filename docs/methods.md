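# Methods

This note documents the models, parameters and numerical choices behind
`netquant`, and what its synthetic validation does and does not
demonstrate.

## Segmentation

ROIs are maximal connected components of pixels whose intensity is
*strictly greater than* a per-channel threshold.  The strict comparison
makes a threshold of 0 exclude an exactly-zero background.  Connectivity
defaults to 8-neighbour (the usual choice for blob detection) and is
configurable to 4-neighbour.  Components below `min_roi_area` (default
4 px) are discarded as shot noise.  Optional Gaussian or median
pre-filters are off by default; when enabled they are applied before
thresholding and before the LoG response is computed.  Intensities stay
in native camera units end to end — every threshold and class range is
expressed in the units of the instrument that produced the image, and
no bit-depth normalisation is applied.  Merged structures (e.g. two
NETs released by adjacent cells) are deliberately kept as single
objects; no watershed splitting is attempted, which is why total NET
*area* is a more reliable readout than NET *count*.

## Features

All statistics are taken over an ROI's own pixel set, never its
bounding box.  For ROIs segmented on either channel, `mean_total` and
`mean_log` read the total-DNA raster under the footprint and
`mean_extra`/`std_extra` the extracellular raster.  Standard deviations
use the population (n-denominator) form: the feature describes the ROI
itself, not a sample drawn from it.

The LoG response is the discrete 5-point Laplacian of the
Gaussian-smoothed image (default sigma 2 px, configurable).  This
formulation — rather than convolution with a sampled LoG kernel — has
an exactly zero response to constant and affine-ramp images, so flat
backgrounds contribute nothing.  With this sign convention a focused
bright blob has a strongly negative mean response over its footprint,
while a diffuse clump with blurred borders (a bacterial aggregate) has
a response of small magnitude; class ranges on `mean_log` are therefore
signed intervals, and margin widths use magnitudes so they stay
non-negative for negative bounds.

Two circularity measures (area/perimeter², with the perimeter counted
as pixel edges bordering background, and area/diameter², with the
diameter the maximal pixel-centre distance, computed via the convex
hull for large ROIs) are available but excluded from all preset class
definitions: elongated but regular nuclei score as circular as discs,
so neither measure separates the stages.  A single-pixel ROI has an
undefined diameter ratio, reported as NaN.

## Scoring and the decision rule

The partial score is

    S(x; l, u, s) = 1                                   if x ∈ [l, u]
                    ½ + ½ sin(π (x−l+Δl)/Δl − π/2)      if x ∈ [l−Δl, l]
                    ½ + ½ sin(π (x−u+Δu)/Δu − π/2)      if x ∈ [u, u+Δu]
                    0                                   otherwise

with Δl = s·l·(u−l)/(u+l) and Δu = s·u·(u−l)/(u+l).  Degenerate cases:
an infinite bound removes its branch entirely and the finite side's
margin falls back to s·|bound| (the interval-length ratio is undefined);
l = u or a zero bound gives a hard edge.  A class score is the product
of its partial scores; features a class does not constrain contribute
factor 1.

An ROI receives a label only when exactly one candidate class scores at
or above the assignment threshold (default 0.8) and all others score at
or below the rejection threshold (default 0.4).  Both comparisons are
closed, so a competitor sitting exactly at 0.4 does not block
assignment.  Everything else is flagged unknown with a reason
(`no_high_score` or `multiple_high_scores`).  This asymmetry is
intentional: with misspecified parameters it is safer to abstain than
to mislabel, which trades recall for precision.

Stage 1 (NET vs artifact) uses hard interval tests by default, as the
workflow's wording implies; a soft mode that reuses the partial score
with the global `s` is available but off by default.  A total-DNA ROI
is excluded from stage 2 when more than half of its pixels (default;
configurable down to any-overlap) lie under the NET/artifact mask —
inside such regions the permeabilization state of a cell cannot be
judged.  Masked-out ROIs and the small extracellular components skipped
in stage 1 are excluded from both counts and the quality score; the
small extracellular footprints of PER cells are never counted
independently, preventing double counting.

The quality score Q = 100·(1 − U/S) counts the extracellular-artifact
area in U by default (artifacts require manual inspection just as
intracellular unknowns do); a flag restricts U to intracellular
unknowns.  Q is defined as 100 for an image with no retained ROIs.
The NET-area percentage uses the full image pixel count as its
denominator.

## Evaluation

Predicted and ground-truth bounding boxes are matched one-to-one by
repeatedly taking the globally highest-IoU remaining pair with IoU ≥
0.10 (ties broken by smaller prediction index, then truth index, for
deterministic reports).  The greedy procedure is verified in the test
suite against exhaustive enumeration of all one-to-one matchings.
Pascal-VOC coordinates are 1-based inclusive; ingestion converts them
to 0-based half-open boxes via (min−1, max) so box areas equal pixel
counts.  In the report, unmatched predictions occupy the Unmatched
column of their label's row and unmatched truths the Unmatched row of
their class's column; precision excludes the Unknown and Unmatched
rows, recall excludes the Unmatched column, and averages are unweighted
means over the named classes.

## Synthetic scenes

The generator renders 256×256 (configurable) 16-bit two-channel scenes
on a background of 100 a.u. with Gaussian camera noise of SD 5 a.u.
Class morphologies: PMN/PER as unions of 2–4 overlapping ellipses
(lobulated), RND as discs, RUP and NETs as boundary-perturbed clouds,
artifacts as smooth ellipses, bacterial clumps as closed unions of
scattered small discs blurred with sigma 3 px.  Intensity targets are
drawn per object from the class preset's range and the amplitude map is
rescaled so the measured mean over the 1-px-eroded mask hits the drawn
value exactly; anti-aliased edges are the only systematic deviation.
NET heterogeneity is a low-frequency multiplicative field (Gaussian
noise smoothed with sigma 6 px, clipped to keep every NET pixel above
half the base brightness so NETs never fragment at segmentation time),
giving a guaranteed brightness-SD floor of roughly 0.38× the base
amplitude; artifacts are smooth by construction, so the SD threshold of
150 a.u. in the emitted stage-1 configuration separates the two with a
wide margin.  NETs carry only a faint sub-threshold haze in the
total-DNA channel.  Objects are placed largest-first with
non-overlapping padded bounding boxes; a scene that cannot be placed
within 300 attempts per object raises a placement error rather than
silently overlapping.

The preset intensity ranges reproduce the ordinal relations between
classes (RND brightest; RUP larger and dimmer than PMN; PER the only
cell with extracellular signal; bacteria dimmest and most diffuse) at
separations a well-tuned experiment would show, and the emitted
configuration's [l, u] intervals bracket the generating ranges with
allowance for the dimmer edge pixels that segmentation includes.  Every
pair of cell classes is separated by at least one feature whose
intervals (margins included, at s = 0.2) do not overlap in the region
the generator populates.

**What passing tests show — and do not.**  Perfect recovery on these
scenes demonstrates that the workflow's plumbing is correct: features
are measured where they should be, the decision rule assigns the
intended class when features fall in the configured ranges, masking and
bookkeeping conserve counts.  It does not demonstrate performance on
real micrographs, where classes overlap in feature space, illumination
varies, cells touch, and NET boundaries fade into background; on real
data the unknown fraction is substantially nonzero and parameters must
be tuned per laboratory.

## Problem sizes and numerical choices

The test suite and the acceptance script use 256×256 scenes (192×256
for the 121-image batch), 10–20 scenes per property, 100 random rasters
(≤ 32×32) for the flood-fill equivalence and 200 instances of ≤ 6 boxes
for the matching oracle — sizes chosen so the whole validation runs in
well under a minute while exercising every code path.  All randomness
in tests, fixtures and the acceptance script flows from explicit seeds;
scene seeds derived from a base seed are reduced modulo 2³¹−1.

## Known limitations

No adaptive thresholding (Otsu etc.), no watershed splitting of merged
NETs, no 3-D stacks or time-lapse tracking, no interactive viewer, and
no co-culture with non-neutrophil host cells.  The optics model of the
generator is deliberately simple (no PSF, vignetting or out-of-focus
light).  NET identification from DNA staining alone is presumptive;
confirming the identity of NET structures requires immunostaining of
NET-associated proteins, which is outside the scope of image analysis.
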
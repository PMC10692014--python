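# Methods

This note documents the models, numerical choices and limitations of
`ivcflow`, in the spirit of a statistical-software methods appendix. It
states how quantities are defined and computed; all empirical numbers
quoted are produced by the package's own tests and scripts.

## Problem setting

From a subcostal B-mode echocardiography clip the pipeline estimates the
inferior vena cava diameter over time, dIVC(t), its respiratory
collapsibility

    cIVC = (dIVC_max − dIVC_min) / dIVC_max × 100%,

and a categorical right-atrial-pressure estimate. Clips arrive as DICOM
cine loops or `.npz` arrays with a mm-per-pixel calibration. The pipeline
stages are view retrieval with quality gating, lumen segmentation and
contouring, diameter tracking, and rule-based RAP categorisation.

## Calibration and coordinates

DICOM ultrasound regions carry `PhysicalDeltaX/Y` in cm per pixel; these
are converted to mm. `PixelSpacing`, when that is all a file has, is
taken as mm directly. If the two axes differ by more than 1% the frames
are resampled to square pixels at the finer spacing, because diameter
chords are cast in arbitrary directions. A clip with no calibration
source is a hard error — silently defaulting would corrupt every
millimetre downstream. Coordinates are 0-based row-major with
pixel-centre geometry; a pixel (r, c) covers [r−0.5, r+0.5) ×
[c−0.5, c+0.5) for sub-pixel chord arithmetic.

## View retrieval and open-set rejection

A shared-encoder network (32×32 downsampled input, one 64-unit tanh
layer, ~66k parameters) feeds a K-class view head and a 2-class quality
head; training minimises the sum of both cross-entropies (quality weight
λ = 1 by default) with full-batch Adam, 300 epochs, learning rate 3e-3.
Determinism is by construction: seeded initialisation, fixed data order,
no stochastic layers. The compact size follows the design goal of a
model cheap enough for point-of-care hardware; the capacity is ample for
the phantom view classes, which are linearly separable by construction.

Open-set recognition follows the OpenMax recipe. The activation vector
of a frame is its pre-softmax view score vector. For each class k the
mean activation vector (MAV) is taken over correctly classified training
frames, and a Weibull distribution is fitted by maximum likelihood
(scipy `weibull_min`, location fixed at 0, optional shift) to the
η largest Euclidean distances from the MAV (η = 20 by default, clipped
to the class sample count). At inference the α top-ranked activations
(α = min(3, K)) are discounted by

    w_k = WeibullCDF_k(‖v − MAV_k‖) · (α − i) / α,   i = 0 … α−1,

the removed mass Σ v_k w_k becomes an "unknown" pseudo-activation, and a
softmax over K+1 entries yields the output. α = 0 reduces exactly to the
closed-set softmax with zero unknown probability. A clip is labelled
unknown when the aggregated unknown probability is the argmax or exceeds
a threshold (0.5 by default); clip aggregation is the mean of per-frame
probability vectors, and quality is a per-frame majority vote with ties
resolved to "bad" (the conservative direction for a screening gate).

## Segmentation and contouring

Two segmentation paths produce the per-frame binary lumen mask. The
trainable path is a per-pixel logistic regression over multiscale
intensity features (raw intensity plus Gaussian means and local standard
deviations at σ = 1, 2, 4, 8 px), fitted on foreground-balanced pixel
subsamples with a seeded RNG and a deterministic solver. The
training-free fallback applies an inverted Otsu threshold and keeps the
darkest sufficiently elongated connected component (axis ratio ≥ 2,
scored by darkness × log area). The fallback is bit-reproducible with no
fitted state, so all geometry-sensitive validation runs through it;
the learned segmenter is exercised separately against held-out Dice.

Mask cleanup keeps the largest 8-connected component, fills 4-connected
interior holes, and opens with a 3×3 structuring element, iterated to a
fixed point so the operation is idempotent. Foreground is 8-connected
and background 4-connected — the standard digital-topology pairing that
avoids connectivity paradoxes.

The ordered outer boundary is traced with the Moore-Neighbor algorithm:
from the first foreground pixel in raster order, the 8-neighbourhood is
scanned clockwise starting just past the backtrack pixel. Termination
uses Jacob's criterion — the walk stops when a pixel is re-entered from
the same direction as before (implemented as a repeat of the
(pixel, backtrack) walk state), which prevents both premature stops on
pinched shapes and infinite loops. One refinement: when the walk steps
diagonally, the inside elbow pixel of the turn is also recorded (the
outside elbow was just scanned and is background), so the visited set
equals exactly the set of foreground pixels 8-adjacent to the exterior
background. This set equality is enforced in tests against an
independent brute-force oracle (flood-fill the exterior, collect
8-adjacent foreground) on hundreds of random masks.

## Diameter tracking

The cleaned mask's morphological skeleton is reduced to its longest
geodesic path (double Dijkstra sweep over the 8-adjacency graph with
Euclidean edge weights) and extended along its end tangents to the mask
boundary, since skeletons stop about half a width short of each end.
Masks with axis ratio < 2 are rejected as non-vessel-like. The
measurement site sits at a configurable arc length from the junction end
of the centerline — default 20 mm, matching the clinical "within 1–2 cm
of the cavo-atrial junction" convention; alternative caudal sites (10,
30, 40, 50 mm) support site-variation analyses. The junction end is the
centerline endpoint nearest the configured image edge. The diameter is
the maximal contiguous in-mask chord through the site perpendicular to
the local tangent (central differences over ±3 path points); each chord
end is located by 24 bisection steps of the in/out indicator, giving
sub-pixel edges and, e.g., exactly 10.0 mm for a 20-px slab at
0.5 mm/px.

Frames where segmentation, centerline extraction or the site fail
contribute *missing* diameters, not zeros — out-of-plane artifacts must
not masquerade as collapse. Interior gaps are linearly interpolated and
edge gaps held before smoothing with a Savitzky–Golay filter (window 11,
order 3 by default; the window is a compromise that suppresses
frame-level segmentation jitter while preserving respiratory-scale peaks
at typical 10–30 Hz frame rates — the filter reproduces cubic series
exactly, which the tests assert). Negative smoothed values are clamped
to zero. dIVC_max and dIVC_min are the global extrema of the smoothed
curve.

## RAP categorisation

The rule table is split at dIVC 21 mm and cIVC 50%:

| dIVC | cIVC | ASE | NIH |
|---|---|---|---|
| ≤ 21 mm | > 50% | 3 mmHg | 5 mmHg |
| ≤ 21 mm | otherwise | 8 mmHg | 10 mmHg |
| > 21 mm | > 50% | 15 mmHg | 15 mmHg |
| > 21 mm | otherwise | 15 mmHg | 20 mmHg |

Boundary ties follow the printed predicates: exactly 21 mm counts as
small (≤ 21), and exactly 50% falls to the low-collapsibility row
because "> 50%" is strict. The diameter entering the table is dIVC_max —
the maximal (end-expiration) diameter, as in guideline practice; the
table's source does not name which extremum it uses, so this choice is
explicit and tested. The mapping is total on [0, ∞) × [0, 100] for both
criteria.

## Agreement statistics

Bland–Altman uses differences auto − manual, bias = mean, limits of
agreement = bias ± 1.96·SD with ddof = 1. The paired location test is
gated by Shapiro–Wilk on the differences at α = 0.05: normal → paired
t-test, otherwise the Wilcoxon signed-rank test. (A Mann-Whitney U form
is available behind a flag for unpaired designs, but the signed-rank
test is the coherent paired counterpart and is the default non-normal
branch.) Chi-square association is Pearson's without continuity
correction, with all-zero margins dropped under a warning. Macro
accuracy is defined as the unweighted mean of per-class recall
(balanced accuracy), the natural reading of "treats all classes
equally"; per-class precision/recall/F1 define 0/0 as 0. IoU and Dice
treat two empty masks as perfect agreement; Dice = 2·IoU/(1+IoU) is
asserted as an identity on random masks.

## Phantom generator

A phantom IVC clip is a dark tube on multiplicative Rayleigh-like
speckle (scale 0.3, lightly smoothed, mean-normalised). The centerline
is a mild quadratic arc entering from the junction edge (bowing ~8% of
the image height) so centerline extraction is exercised on genuine
curvature; the lumen is every pixel within d(t)/2 of the continuous
centerline, with

    d(t) = d_min + (d_max − d_min)(1 + cos(2π t / T_resp)) / 2.

The width is spatially constant at each instant, so the truth diameter
is exact at every site. Defaults emulate a realistic acquisition:
800×600 px frames, 0.25 mm/px, 30 Hz, a 4 s respiratory period and five
cycles (a 20 s loop), 18/9 mm diameters; tests use smaller frames and
lower frame rates, stated per test. When the frame rate times the
respiratory period is even, sampled frames hit both extrema exactly and
the truth cIVC equals the nominal one. The lumen edge is a ~0.7 px
sigmoid before a 0.8 px blur (good quality); bad quality is
operationalised as heavy blur (σ ≥ 3 px) or lumen contrast ≤ 0.15.
Dropout frames replace the tube with plain background, emulating
out-of-plane respiration artifacts. Decoy views (parasternal-long-axis-,
four-chamber- and Doppler-like) are deterministic geometric overlays
with distinct pixel statistics — sufficient for separability and
open-set tests, deliberately not anatomy.

What passing phantom tests do show: the geometry, smoothing, rule logic
and statistics are internally correct to sub-pixel accuracy, and the
open-set machinery rejects a distribution it never saw. What they do not
show: performance on clinical speckle, probe-dependent artifacts,
anatomically confusable views, or real inter-observer variability — the
phantom's decoys are far easier than neighbouring cardiac views, so
classifier accuracies on phantoms say nothing quantitative about
clinical accuracy.

## Problem sizes and numerical choices

The recovery validation runs 12 phantoms (cIVC ∈ {20, 40, 60, 80}% ×
dIVC_max ∈ {12, 18, 24} mm) at 240×340 px, 0.25 mm/px, 10 Hz, two
respiratory cycles, through the fallback segmenter; recovered cIVC is
required within ±5 percentage points and dIVC_max within ±0.5 mm. The
open-set check trains on a ~200-frame corpus (96×128 px clips, 8 frames
each) with the Doppler-like class withheld. Contour-oracle equivalence
runs on 100 random single-component masks up to 64×64. These sizes were
chosen as desk-scale study conditions; all randomness is seeded and every
run is reproducible bit-for-bit.

Numerical details worth knowing: chord sampling steps are 0.25 px with
24-step bisection at the edges; Weibull fits reject degenerate
(all-equal) tails; the two-head trainer adds 1e-12 inside logs and 1e-8
to feature standard deviations; `clean_mask` iterates at most 8 rounds
to its fixed point (in practice ≤ 2); the contour walk is bounded by
16·(number of foreground pixels) steps as a safety net.

## Known limitations

- The learned segmenter is a per-pixel classifier with no shape prior;
  on clinical data a dedicated encoder–decoder would be needed.
- RAP output is categorical only and has not been compared against
  invasive reference pressures.
- The fallback segmenter assumes the IVC is the darkest elongated
  structure in view, which can fail with shadowing or nearby hepatic
  vessels on real images.
- Collapsibility uses absolute extrema of the whole clip, not
  per-respiratory-cycle averages; long clips with irregular breathing
  will report the single deepest collapse.
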
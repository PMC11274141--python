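# Methods

## Scope and model

The toolkit implements the deterministic, learned-model-free half of a
tooth-level calculus screening pipeline: locating single teeth in a
bitewing radiograph by projection profiles, enhancing proximal edge
structure, preparing balanced train/test/validation pools, and scoring
detections. Neural detection and classification stages are deliberately
out of scope; the interfaces stop at crops, overlays, splits and metrics.

## Projection-profile segmentation

A bitewing is modeled as two rows of bright crowns on a dark background
separated by a dark occlusal band. The chain is:

1. 3×3 mean filter (noise suppression before thresholding);
2. global binarization at 170, *strictly greater* → white — the asymmetry
   matters at the threshold value itself and is part of the contract;
3. jaw split at the row minimizing the horizontal (per-row) profile of the
   binary image. The search is restricted to the central 50% of rows
   because dark frame borders otherwise win; ties resolve to the midmost
   tied row, which centers the split on a flat occlusal band;
4. per-jaw vertical (per-column) profiles; every maximal run of columns
   below the valley threshold 400 collapses to its center column. On a
   binary image, 400 accumulated intensity means "fewer than two white
   pixels in the column", so the threshold reads as an almost-empty-column
   test; it is configurable, and the profile is deliberately computed on
   the binary (not grayscale) raster so the number keeps that meaning.
   Runs touching the frame border are discarded — radiograph margins are
   not interdental gaps;
5. consecutive cuts (plus frame edges) bound teeth; boxes are expanded by
   ±50 px in x, clipped, and filled with pixels from the **unfiltered**
   original. Filtering only ever influences *where* to cut;
6. each crop is halved at ⌊w/2⌋ into left/right proximal views. Halving
   happens before enhancement: proximal surfaces are the diagnostic
   region, and enhancing the halves keeps adaptive statistics local.

A jaw that produces no interdental cut aborts with a stage-named
diagnostic (`gap_cuts`): a blank image, or a single-tooth jaw, is outside
the method's operating range and silently returning one full-width "tooth"
would be worse.

## Filters

All three filters use edge replication at the borders (a zero border would
fabricate dark halos that corrupt the profiles) and round-half-up to uint8
after floating-point accumulation.

* **Mean**: plain windowed average, default 3×3 — the smallest standard
  denoising window; it exists to stabilize binarization, not to beautify.
* **Median**: exact middle order statistic (windows have odd counts),
  default 3×3.
* **Bilateral**: weight `exp(−Δd²/2σs²)·exp(−ΔI²/2σr²)` over a square
  window of radius 4, σ_spatial = 2 px, σ_range = 25 levels. The range
  kernel argument is the neighbor-minus-center intensity difference — the
  canonical form. σ_range → ∞ degenerates to a spatial Gaussian mean;
  σ_range → 0 approaches the identity on piecewise-constant images. Both
  limits are asserted in tests.

## Binarization and morphology

Adaptive binarization compares each pixel to the mean of its block_size
(default 15) neighborhood minus an offset C. The block *mean* (not a
Gaussian-weighted mean) is the simplest faithful local statistic. The
standalone default is C = 0; the enhancement chain overrides it to C = +5
because with C = 0 a flat noisy region binarizes to ~50% salt-and-pepper
(every pixel is compared to a mean it is equally likely to exceed), which
floods the morphology stage.

Binary dilation and erosion follow the set-theoretic definitions on the
white set with an explicit structuring-element origin; everything outside
the frame is background. Opening is erosion-then-dilation, closing the
reverse — the standard convention, which matches the intended behaviors
("remove small specks" / "fill small holes") even though one sometimes
sees the compositions printed the other way around. Default element: 3×3
cross; shape (cross/square), size and the opening/closing order are
configurable, defaulting to closing-then-opening (fill pinholes first,
then drop speckle). Because the outside-is-background convention truncates
at the frame, the enhancement chain edge-pads the binary raster before
morphology and crops back afterwards; otherwise an all-white crop would
acquire an artificial eroded ring that Canny would then trace. Algebraic
identities that presume infinite support (closing extensivity, idempotence,
duality) are exercised in tests on masks with a background margin for the
same reason.

## Canny and overlay

Gradient: 3×3 Sobel (edge-replicated), no Gaussian pre-smoothing — the
median and bilateral stages have already denoised, and extra blur would
round off the small crescent contours of interest. Non-maximum suppression
quantizes the gradient direction into four 45° bins and keeps a pixel iff
its magnitude strictly exceeds the forward neighbor and is at least the
backward neighbor along the signed gradient — the asymmetric tie-break
thins a two-pixel step-edge plateau to the single pixel on the bright
side. Hysteresis: thresholds 50/150 (the common 1:3 ratio) on the 8-bit
Sobel magnitude, where a straight full-contrast step reaches 1020;
8-connected weak-edge components survive iff they contain a strong pixel.
Canny consumes the morphology output by default (configurable to the
bilateral output instead). The overlay replicates the grayscale crop to
RGB and replaces exactly the edge-mask pixels with pure green.

## Phantom generator

The generator emulates the features the algorithms actually key on, not
radiographic realism: two rows of bright superellipse "teeth" (exponent 4
≈ rounded rectangles) at intensity 200 on a background of 60, separated by
a dark band of height 40 that arises simply from drawing no teeth there;
dark interdental gaps of 8–16 px; optional bright crescents (intensity
245) on a uniformly chosen proximal side of a tooth, emulating calculus;
additive Gaussian noise (default σ = 6) clipped to [0, 255]. Default
frame 640×480, 8 teeth per jaw of width 42–58 px and height 120–160 px;
all randomness flows from one seeded generator, so a spec maps to exactly
one raster. Ground truth records the band center row, per-jaw gap-center
columns, tight tooth boxes and per-tooth calculus flags.

What the phantom does **not** model: overlapping or tilted teeth,
restorations, caries, bone texture, gum shadows, exposure gradients, and
the continuous gray ramps of real enamel. Passing the recovery tests
therefore shows the algorithms are implemented correctly and are robust to
additive noise — not that they would reach the same recovery on clinical
images, where tooth contact and exposure variation dominate the failure
modes. Calculus crescents protrude into the interdental space (as real
deposits do), so a large crescent can lift its gap's valley above the
threshold; with the default calculus probability this costs a few percent
of gap recovery, which is a property of the scene, not a detector bug.

## Dataset preparation

Balancing equalizes the two classes at a target (default ⌊total/2⌋): the
minority is topped up with flip/mirror copies of re-sampled sources, the
majority subsampled without replacement. A target below the minority's
natural count is rejected rather than silently subsampling the minority.

The two-stage split floors the holdout remainder and the train share and
cascades remainders to test then validation:
`rest = ⌊N(1−h)⌋, train = ⌊rest·t⌋, test = rest − train, val = N − rest`
(1340 → 750/322/268 at h = 0.2, t = 0.7; t = 1 is the degenerate two-way
path, 200 → 130/0/70 at h = 0.35). Augmented copies are confined to the
same subset as their source to prevent leakage; items sharing a root id
move as one shuffled group, greedily first-fit into the three quota bins.
With singleton groups the counts are exact; with groups of size g a
boundary can shift by at most g−1.

## Evaluation

Greedy confidence-ordered matching at IoU ≥ 0.5 (the conventional default;
configurable). A detector has no natural true negatives, so Tn = 0 and
specificity is reported only when a caller supplies classification counts;
zero-denominator metrics raise instead of returning 0. AP integrates the
all-point interpolated precision envelope over recall; an 11-point mode
exists for comparability with older conventions. mAP averages classes
that have ground truth; empty-truth classes are excluded with a warning.

## Problem sizes and numerical choices

The test suite and the acceptance script use 50 phantoms (6–10 teeth per
jaw, noise σ = 8, 760×480 px so the widest 10-tooth layout always fits),
100 random 16×16 images for the mean/median oracles, 25 random 8×8 images
for the per-pixel bilateral oracle, and 50 random 12×12 masks for the
morphology algebra — sizes chosen to make brute-force oracles exact and
fast while still exercising every code path. Floor arithmetic in the
splitter adds 1e-9 before flooring to absorb binary representation error
in products like 1340 × 0.8. Checksummed rasters pin byte-level
determinism of the generator under a fixed seed.

## Known limitations

* The segmentation assumes near-horizontal jaws; rotated or oblique
  bitewings are out of scope.
* Touching teeth produce no interdental valley and cannot be separated.
* The 400 valley threshold is calibrated to binary profiles; running the
  gap detector on grayscale profiles requires rescaling it.
* DICOM input is not supported; convert to PNG/TIFF/BMP first.
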
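# bitewing

A toolkit for the classical image-processing side of dental calculus
screening on bitewing radiographs: projection-profile single-tooth
segmentation, an interdental edge-enhancement chain, dataset
balancing/splitting, and object-detection evaluation metrics — plus a
seeded synthetic bitewing *phantom* generator with exhaustive ground truth,
since clinical bitewing databases are IRB-restricted and cannot be shipped.

It is aimed at researchers building or validating tooth-level analysis
pipelines who need a reproducible, learned-model-free baseline for
localization and a deterministic test bed for every preprocessing operator.

## What it computes

**Segmentation.** A bitewing shows two rows of bright crowns separated by a
dark occlusal band. After a mean filter and a global binarization at
threshold 170 (strictly `> 170 → 255`), the horizontal projection profile
`H(y) = Σ_x I(x, y)` attains its minimum inside the occlusal band — that row
splits the jaws. Within each jaw the vertical profile `V(x) = Σ_y I(x, y)`
drops below a valley threshold (default 400) in the dark interdental gaps;
each sub-threshold run collapses to one cut column. Consecutive cuts bound
a tooth; boxes are padded by ±50 px in x (so proximal surfaces — where
calculus sits — survive), pixels are cropped from the *original* grayscale,
and each crop is halved vertically into left/right proximal views.

**Enhancement.** Each crop runs through
`median → bilateral → adaptive binarization → morphology (closing, opening)
→ Canny → green overlay`. The bilateral weight of neighbor *q* around
center *p* is `Fr(I(q) − I(p)) · GS(‖q − p‖)` with Gaussian kernels
`exp(−d²/2σ²)`; Canny uses a 3×3 Sobel gradient, non-maximum suppression
and double-threshold hysteresis (defaults 50/150). Edge pixels are painted
pure green onto the original crop; every other pixel is bit-identical.

**Dataset arithmetic.** A two-class pool is balanced by augmenting the
minority with flip/mirror copies and subsampling the majority
(428/912 → 670/670 at the default target), then split with floors and
cascading remainders: `rest = ⌊N(1−h)⌋`, `train = ⌊rest·t⌋`,
`test = rest − train`, `validation = N − rest` — so 1340 at h = 0.2,
t = 0.7 gives 750/322/268, and 200 at h = 0.35, t = 1 gives 130/70.

**Metrics.** Precision `Tp/(Tp+Fp)`, recall/sensitivity `Tp/(Tp+Fn)`,
specificity `Tn/(Fp+Tn)` (percentages; zero denominators raise instead of
returning 0), IoU-thresholded greedy matching of detections to truths, and
mAP as the area under the all-point interpolated precision–recall curve.

## Worked example

```python
import bitewing as bw

spec = bw.PhantomSpec(teeth_per_jaw=8, noise_sigma=6.0, seed=0)
image, truth = bw.generate_bitewing(spec)
crops = bw.segment_bitewing(image)
print(len(truth.tooth_boxes), truth.jaw_split_row, len(crops))
enhanced = bw.enhance_tooth(crops[0])
print(enhanced.rgb.shape, int((enhanced.edge_mask == 255).sum()))
```

prints

```
16 240 32
(240, 95, 3) 327
```

— the phantom carries 16 ground-truth tooth boxes (8 per jaw) with the
occlusal band centered on row 240; segmentation recovers all 16 teeth and
halves them into 32 proximal crops; enhancing the first 240×95 crop paints
327 green edge pixels onto its RGB overlay.

The same pipeline runs from the shell:

```sh
bitewing phantom --seed 0 --out-image bw.png --out-truth truth.json
bitewing segment --in bw.png --out-dir crops --save-boxes yolo
bitewing enhance --in crops --out-dir enhanced
bitewing split --manifest manifest.csv --holdout 0.2 --train-frac 0.7 --seed 1 --out splits
bitewing evaluate --pred pred/ --truth gt/ --iou 0.5 --report report.json
bitewing --show-config   # all defaults as YAML
```

Every subcommand reads one YAML config (sections `phantom`, `filters`,
`adaptive`, `morphology`, `segmentation`, `enhancement`, `dataset`,
`metrics`), logs each stage with its parameters, seed and input checksums,
and is bit-reproducible under a fixed seed.

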
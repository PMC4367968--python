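# eyereg

Quantification of *Drosophila* compound-eye surface regularity from
reflected-light photographs.

Each ommatidial lens of the insect compound eye reflects incident light
as a bright spot, so a healthy eye photographed face-on shows a
near-hexagonal lattice of reflections. Retinal degeneration — the
rough-eye phenotype used as a readout in countless neurodegeneration
and modifier screens — scrambles and thins that lattice. `eyereg` turns
a folder of eye-surface images into a single regularity index per eye,
so phenotypic rescue or enhancement can be scored quantitatively
instead of by visual inspection.

## Method

For each image (8-bit grayscale, with a polygon ROI marking the
in-focus eye region):

1. **Normalize** — rolling-ball background subtraction followed by a
   surface-like filter (average of the image with a horizontally
   displaced, inverted copy of itself), which removes uneven
   illumination and sharpens spot contrast.
2. **Detect** — ommatidial reflections as local intensity maxima whose
   prominence exceeds a noise tolerance; a calibration routine tunes
   tolerance and ball radius against a manual count.
3. **Summarize** — 18 spatial-regularity variables from the maxima: a
   grid of squares fully inside the ROI yields occupancy percentages,
   maxima-per-cell moments, and moments of the distance between each
   cell's centroid and its maxima center of mass (DISTM, DISTVAR,
   DISTSKEW); the whole ROI yields the log nearest-neighbor-distance
   variance (LOGNNVAR) and the total count (TOTMAX).
4. **Classify** — a built-in five-class multinomial logit on
   (DISTM, DISTSKEW, LOGNNVAR), class 4 (fully degenerate) as
   reference:

       a_i = independent_i + distm_i·DISTM + distskew_i·DISTSKEW + lognnvar_i·LOGNNVAR
       PP_i = exp(a_i) / (Σ_j exp(a_j) + 1),  PP_4 = 1 / (Σ_j exp(a_j) + 1)

   collapsed into the regularity index

       IREG = (4·PP_0 + 3·PP_1 + 2·PP_2 + PP_3) / 4  ∈ [0, 1]

   with IREG = 1 a fully regular (wild-type) surface and IREG = 0
   complete degeneration.

The package also contains the model-(re)building pipeline that produced
the shipped coefficients (correlation pruning, ANOVA screening, PC1
clustering into five ordered classes, stepwise selection, multinomial
fitting with split-robustness checks), Kruskal–Wallis + Dunn group
statistics, and a synthetic eye-image generator with ground truth for
testing. See `docs/methods.md` for conventions and numerical details.

## Worked example

```python
import numpy as np
from eyereg import (SyntheticEyeSpec, generate_eye_image, preprocess,
                    PreprocessParams, find_maxima, make_grid,
                    extract_features, model_features, builtin_results)
from eyereg.synthetic import eye_footprint_roi

spec = SyntheticEyeSpec(jitter_sd=3.0, seed=42)      # moderately disordered eye
image, truth = generate_eye_image(spec)
roi = eye_footprint_roi(spec)

processed = preprocess(image, PreprocessParams(rolling_radius=25))
maxima = find_maxima(processed, roi, tolerance=12.0)
grid = make_grid(roi, cell_size=50)
fv = extract_features(maxima, grid, image.pixel_size)
mf = model_features(fv)

res = builtin_results()
print(f"true spots: {truth.n_spots}, detected maxima: {len(maxima)}")
print(f"DISTM={mf.distm:.3f}  DISTSKEW={mf.distskew:.3f}  LOGNNVAR={mf.lognnvar:.3f}")
print("class probabilities:", np.round(res.predict_proba(mf.as_array())[0], 4))
print(f"IREG = {res.predict_ireg(mf.as_array())[0]:.4f}")
```

prints

```
true spots: 87, detected maxima: 87
DISTM=3.870  DISTSKEW=0.194  LOGNNVAR=1.894
class probabilities: [6.300e-03 4.175e-01 5.755e-01 1.000e-04 5.000e-04]
IREG = 0.6073
```

All 87 lattice spots are recovered; 3 px of positional jitter lands the
eye between degeneration classes 1 and 2, an intermediate IREG of 0.61
— more disordered than a wild-type surface (IREG ≈ 1), far from full
degeneration (IREG ≈ 0).

## Command line

```sh
eyereg generate  --out-dir demo --n-per-class 3 --seed 1   # synthetic test batch
eyereg calibrate --counts counts.csv --out params.csv      # tune detection to manual counts
eyereg analyze   --image-dir demo/images --roi-dir demo/rois \
                 --out-dir demo/out --groups demo/groups.csv
eyereg compare   --per-image demo/out/per_image.csv
eyereg refit     --features features.csv --out coefficients.json
```

`analyze` writes per-image and per-group CSV tables, the group
comparison report, a config echo for provenance, and IREG box/histogram
plots. ROIs are matched to images by base filename (JSON polygons or
ImageJ `.roi` files).

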
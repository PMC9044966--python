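# tomatophen

Quantitative tomato fruit phenotyping from images, for breeders and
plant-phenomics pipelines that need morphometric traits at scale instead of
calipers and manual counting.

From three standardized photographs per sample — intact fruits, vertical
cuts, and horizontal cuts on a uniform light background, with one
black-white ruler card (1 cm × 1 cm squares) per camera setup — the package
measures:

* **fruit colour** — mean (R, G, B) per fruit after HSV filtering removes
  background, sepal and calyx: a pixel is fruit iff H ∈ [h_low, h_high]
  (0–360°), S > s_min and V > v_min, with per-cultivar-class presets
  (`pure_color`, `black`, `mottled`);
* **horizontal and vertical diameter** (cm) — sides of the rotated
  minimum-area rectangle enclosing the fruit contour, assigned to axes by
  the navel→top direction, plus the **fruit shape index**
  *SI = vertical / horizontal*;
* **top and navel angle** (degrees) — the contour is simplified with the
  Douglas–Peucker algorithm; the navel is the concave vertex with the
  largest distance to the chord through its adjacent convex vertices (ties
  broken by the low saturation of calyx-side tissue), the top is the
  contour point farthest from the navel, and each angle is the vertex angle
  toward the adjacent convex landmarks; plus the **top/navel ratio**;
* **locule number, locule area proportion and pericarp thickness** — scored
  locule instances from a pluggable segmenter (a classical value-channel
  backend ships by default; any external instance-segmentation model can be
  adapted through the same contract), then per section:
  count, Σ locule area / section area, and the mean radial gap between the
  locule boundary and the section boundary along rays from the section
  centroid through each locule centroid, in cm.

Around the measurements the package provides the matching dataset
machinery: annotation-consistent augmentation (rotations 90/180/270°,
vertical/horizontal mirroring, bilinear rescaling to 0.1–4×, and a 5×5
Gaussian-blurred copy of every geometric variant — 24 variants per source),
seeded 70/20/10 dataset splits, instance-segmentation evaluation
(IoU > 0.5 greedy matching, P/R/F1, precision-envelope AP, auditable
practical re-scoring), and verification statistics against manual
measurements (relative RMSE = √(1/n Σ((Rᵢ−Mᵢ)/Mᵢ)²), Pearson R²,
Brown–Forsythe variance test, Welch location test).

Everything is testable without photographs: `tomatophen.synthetic` renders
all four scene types with analytic ground truth for every trait above.

## Worked example

Render a synthetic ruler card and a three-fruit horizontal-cut scene,
calibrate, and measure:

```sh
tomatophen synth --kind ruler --pitch-px 50 --out demo
tomatophen synth --kind horizontal --seed 7 --n-fruits 3 --out demo
tomatophen calibrate --image demo/ruler.png
# -> 50.000 px/cm (25 squares)
tomatophen horizontal --image demo/horizontal.png --scale-px-per-cm 50 --out demo/horiz.csv
```

`demo/horiz.csv` (measured, classical segmenter):

```
image_id,fruit_id,locule_count,locule_area_proportion,pericarp_thickness_cm,low_confidence,n_warnings
horizontal.png,0,6,0.1117,1.0656,False,0
horizontal.png,1,5,0.1068,1.1012,False,0
horizontal.png,2,4,0.1556,0.7452,False,0
```

against `demo/ground_truth.csv` (analytic):

```
image_id,fruit_id,scene_kind,locule_count,locule_area_proportion,pericarp_thickness_cm
horizontal.png,0,horizontal,6,0.1116,1.0605
horizontal.png,1,horizontal,5,0.1068,1.1031
horizontal.png,2,horizontal,4,0.1555,0.7447
```

All three locule counts are exact; area proportions agree to the third
decimal and pericarp thickness to within half a millimetre. The same CLI
offers `color`, `vertical` (with landmark overlays), `augment`, `split`,
`evaluate`, `verify` and a manifest-driven `run`; every command is a thin
wrapper over the library API (`tomatophen.isolation`, `.vertical`,
`.locules`, `.augment`, `.evaluation`, `.pipeline`).

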
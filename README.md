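# octamorph

Quantitative vascular morphometry of **macular neovascularization (MNV)** on
en-face **OCT angiography** images, with the group statistics used to compare
MNV types 1, 2 and 3 in neovascular age-related macular degeneration (nAMD).

The package is aimed at retinal-imaging researchers who have an exported
en-face OCTA slab (typically the outer-retina-to-choriocapillaris projection
of a 6 × 6 mm scan, 500 × 500 px → 12 µm/px) and a delineated lesion mask,
and want reproducible numbers instead of subjective pattern labels.

## What it computes

From one image + lesion mask, six per-lesion parameters:

| parameter | unit | definition |
|---|---|---|
| `area`  | mm²   | lesion-mask pixel count × pitch² |
| `flow`  | %     | perfused pixels / lesion pixels × 100 |
| `FD`    | —     | box-counting fractal dimension of the centerline skeleton |
| `numN`  | 1/mm² | vessel-fork (junction node) count per lesion area |
| `sumL`  | mm    | total centerline length |
| `avgW`  | µm    | length-weighted mean vessel caliber (2 × EDT at the centerline) |

Pipeline: multiscale Hessian (Frangi-type) tubularity filter → Otsu threshold
restricted to the lesion → topology-preserving thinning with spur pruning →
Euclidean distance transform for calibers → centerline graph (junctions =
skeleton pixels with ≥ 3 neighbors, merged per anatomical fork).

Across a cohort labeled by MNV type, `compare_types` runs the
precondition-gated analysis: Levene (variance homogeneity) and Shapiro–Wilk
(normality of groupwise-centered residuals); if either fails at α = 0.05,
Kruskal–Wallis (tie-corrected,

&nbsp;&nbsp;H = [12/(N(N+1))] Σ nᵢ R̄ᵢ² − 3(N+1), corrected by 1 − Σ(t³−t)/(N³−N))

followed by Dunn's post hoc z tests with Bonferroni (×3) adjustment;
otherwise one-way ANOVA with pairwise t tests.

Because the cohort images behind the published study are not deposited, a
`synth` module provides (a) per-type metric generators moment-matched to the
published summary table (log-normal for the right-skewed area/sumL/avgW,
truncated normal for FD/numN/flow) and (b) an image-level phantom generator
(stochastic branching trees rasterized over speckle) with exact ground truth
for recovery testing.

## Worked example

```python
import numpy as np
from octamorph import SyntheticLesionSpec, generate_lesion_image, compute_all

image, mask, truth = generate_lesion_image(SyntheticLesionSpec(seed=1))
m = compute_all(image, mask)
print(f"area  {m.area_mm2:.3f} mm2   (truth {truth.area_mm2:.3f})")
print(f"sumL  {m.sumL_mm:.2f} mm     (truth {truth.sumL_mm:.2f})")
print(f"numN  {m.numN_per_mm2 * m.area_mm2:.0f} forks (truth {truth.numN})")
print(f"avgW  {m.avgW_um:.1f} um     (truth {truth.avgW_um:.1f})")
print(f"flow  {m.flow_pct:.1f} %   FD {m.fd:.2f}")
```

prints

```
area  2.400 mm2   (truth 2.400)
sumL  17.09 mm     (truth 16.85)
numN  21 forks (truth 20)
avgW  29.9 um     (truth 24.0)
flow  18.6 %   FD 1.29
```

— the mask area is recovered exactly (both sides count the same pixels), the
total centerline length to ~1.6 %, the fork count to ±1, and the mean
caliber within one pixel pitch (the distance-transform estimator reads a
discrete tube about half a pixel wide of its continuous diameter; 12 µm/px
is the resolution floor).

The same pipeline is scriptable from a shell:

```bash
octamorph phantom --seed 1 --n 1 --out-dir ph/
octamorph measure --image ph/phantom_0001.png --mask ph/phantom_0001_mask.png --out-csv one.csv
octamorph simulate --seed 11 --out-csv cohort.csv
octamorph compare --cohort-csv cohort.csv --out-json comparisons.json
octamorph run-study --cohort simulate --out-dir study/
```

`run-study` writes the per-type summary table (min/Q1/median/Q3/max/mean/SD),
boxplot statistics (1.5 × IQR whiskers) and the full comparison JSON; every
output embeds the config hash and seed, and reruns with the same config are
byte-identical.

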
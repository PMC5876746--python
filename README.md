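# bunch3d

Automated extraction of grape bunch architecture traits from dense 3D
point clouds.

Grapevine breeders select for loose bunch architecture because densely
packed bunches favor *Botrytis* bunch rot. Scoring architecture by eye
(OIV descriptor 204, five classes from very loose to very dense) is slow
and subjective; `bunch3d` instead takes a surface scan of a hanging bunch —
a PLY point cloud in millimetres, vertical axis y — and recovers every
visible berry, from which it computes seven phenotypes: berry number *n*,
mean berry diameter, mean and total berry volume, convex hull volume,
bunch width and bunch length.

The core method:

1. **Reduction** — voxel-grid downsampling to a 0.4 mm working resolution.
2. **Segmentation** — region growing over the k-NN graph; growth crosses an
   edge when neighboring PCA normals agree within 15° and stops at the
   high-curvature creases between touching berries.
3. **Berry detection** — per region, RANSAC sphere fitting (minimal
   4-point algebraic solver, 1000 hypotheses, inlier band 0.4 mm) with
   least-squares refinement; a sphere is a berry only if its radius r
   satisfies 1 mm ≤ r ≤ 9 mm and it has ≥ 100 supporting points. Accepted
   inliers are removed and fitting repeats, so one region can yield several
   berries. Duplicates from split berries are suppressed: of two spheres
   whose lens-intersection volume exceeds 25% of the smaller sphere's
   volume, only the one with more inliers survives.
4. **Traits** — per-berry volume 4/3 π r³; length and width from berry
   extents (center ± r) along y and x/z respectively; convex hull over all
   berry inlier points (SciPy Qhull). Volumes are reported in mL.

Candidate compactness factors (e.g. total volume per length × width) are
evaluated from the traits and rank-correlated with OIV 204 classes by
Spearman's ρ with average-rank ties.

A fully ground-truthed synthetic bunch generator (`bunch3d.synth`)
produces 360° and single-side ("partial") scans of bunches of 10–500
spherical berries with realistic packing, skeleton structure, sensor noise
and close-range structured-light occlusion, so the entire pipeline is
testable without scanner data.

## Worked example

```python
import numpy as np
from bunch3d import (SyntheticBunchSpec, generate_bunch, analyze_cloud,
                     match_detections)

spec = SyntheticBunchSpec(n_berries=30, seed=1)      # radii 4.6-8.45 mm
cloud, truth = generate_bunch(spec)                  # 36 171 points
result = analyze_cloud(cloud, rng=np.random.default_rng(1))
report = match_detections(truth, result.models)

print(len(result.models), report.precision, report.recall)
print(result.traits)
```

prints

```
30 1.0 1.0
BunchTraits(n_berries=30, mean_diameter=13.158..., mean_volume=1.292...,
            total_volume=38.779..., convex_hull_volume=141.359...,
            width=57.860..., length=72.658...)
```

All 30 synthetic berries are recovered with no false positives; the mean
berry diameter (13.16 mm) and total berry volume (38.8 mL) match the
generator's ground truth (38.8 mL total, within a fraction of a percent),
while the convex hull (141 mL) is larger than the berry volume because it
includes the space between berries.

From a shell, the same pipeline runs in batch over a folder of scans:

```sh
bunch3d simulate --out scans --name bunch01 --n-berries 100 --seed 7
bunch3d detect scans --out results --seed 7
bunch3d factors results/combined_traits.csv ratings.csv
```

`detect` writes one tab-separated trait file and one per-berry CSV per
scan, a combined CSV across scans, and a metadata JSON with every
parameter and the seed; corrupt files are logged and skipped. `factors`
reports Spearman's ρ of each configured compactness factor against OIV 204
ratings.

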
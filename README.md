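# gastruquant

Quantitative analysis of gastruloid experiments: image morphometry,
anterior–posterior (A-P) expression profiling, and rule-based single-cell
categorization — built as a tested, reusable pipeline with a synthetic-data
module that supplies ground truth for every stage.

Gastruloids are 3D aggregates of embryonic stem cells that break symmetry,
polarize T (brachyury) expression at a posterior pole, and elongate. The
analyses such experiments rely on are usually one-off image-software
pipelines and R snippets; `gastruquant` packages them as a library plus a
CLI:

* **Morphometry** — structure segmentation (Otsu or local-variance
  thresholding after Gaussian smoothing, watershed splitting of touching
  objects), area, Feret diameters by rotating calipers on the convex
  hull, and the elongation index `EI = Feret_max / Feret_min`; nucleus
  quantification with area-normalized intensity and the standard filters
  (area 100–1000 µm², circularity `√(4A/(π·Feret_max²))` in 0.6–1).
* **A-P profiling** — reporter intensity along the structure midline,
  relative positions `p = x / L`, per-sample DAPI normalization, mean
  intensity in 100 bins of width 0.01, optional 0–1 scaling, Euclidean
  k-means over binned profiles, and the per-condition rate of structures
  carrying a reporter-positive (polarized) pole.
* **Cell rules** — single-cell QC (200–2500 features, ≤ 5% mitochondrial
  counts), bulk CPM filtering (> 0.4 CPM in ≥ 2 samples), the sequential
  Hox-positive → brain-like → spinal-cord-like categorization (≥ 1 of 28
  Hox genes; else ≥ 5 of 30 fore/midbrain markers and no Fgfbp3; else
  spinal), mutually exclusive dorsal/midline/ventral module assignment,
  per-state log2 abundance ratios versus a reference condition, and
  pseudo-bulk group means.
* **Synthetic data** — seeded generators for elliptical two-channel
  gastruloid images with a logistic posterior reporter gradient (analytic
  area and Feret ground truth) and for count matrices with planted
  marker-defined populations and dropout.

See `docs/methods.md` for the models, defaults, and design decisions.

## Worked example

Simulate 40 structures (12 with a polarized reporter), segment and
measure each, bin the DAPI-normalized A-P profiles, and cluster:

```python
import numpy as np
from gastruquant import (ImageSimParams, simulate_gastruloid_image,
                         segment_structures, measure_structure,
                         extract_profile, bin_profile, cluster_profiles)

binned = []
rng = np.random.default_rng(7)
for i in range(40):
    params = ImageSimParams(reporter_polarized=(i < 12),
                            seed=int(rng.integers(0, 2**31 - 1)))
    image, truth = simulate_gastruloid_image(params)
    labels = segment_structures(image, "dapi")
    m = measure_structure(labels, 1, image.pixel_size)
    if i == 0:
        print(f"structure 0: area {m.area:.0f} um^2 (truth {truth.true_area:.0f}), "
              f"elongation index {m.elongation_index:.2f}")
    profile = extract_profile(image, labels == 1)
    binned.append(bin_profile(profile, normalize_to_dapi=True))

result = cluster_profiles(np.asarray(binned), k=2, seed=7)
frac = (result.labels == result.polarized_cluster_id).mean()
print(f"polarized cluster: {result.polarized_cluster_id}, "
      f"fraction of structures with a reporter-positive pole: {frac:.2f}")
```

Output:

```
structure 0: area 23600 um^2 (truth 23562), elongation index 3.00
polarized cluster: 1, fraction of structures with a reporter-positive pole: 0.30
```

The default simulated body is a 150 × 50 µm semi-axis ellipse, so the
true area is `π·150·50 ≈ 23 562 µm²` and the true elongation index is 3;
segmentation recovers both to ≈ 0.2%. The k = 2 clustering separates
polarized from flat profiles and recovers exactly the planted 30%
polarized fraction.

The same chain is available from the shell:

```bash
gastruquant simulate-image --seed 4 --out img.tif
gastruquant morphometry --image img.tif --channel dapi --out morpho
gastruquant profile --image img.tif --out profiles.csv
gastruquant cluster-profiles --profiles profiles.csv --k 2 --seed 7 --out clus
gastruquant simulate-cells --seed 1 --out cells --fmt csv
gastruquant classify-cells --csv cells/counts.csv --out classes.csv
```

plus `qc-filter`, `dv-classify`, `abundance` and `run` (full pipeline
from a YAML config, writing a hash-stamped manifest).

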
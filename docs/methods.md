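# Methods

`gastruquant` re-implements, as a reusable and tested pipeline, the
quantification steps applied to gastruloid experiments: morphometric image
analysis, anterior–posterior (A-P) reporter profiling with k-means profile
clustering, and rule-based single-cell categorization with differential
cell-type abundance. Because the raw images and sequencing data such
pipelines were originally run on are not redistributable at desk scale,
every stage is validated against synthetic data with analytic or planted
ground truth. This note records the models, the defaults, and the design
choices made where the procedures underdetermine an implementation.

## Synthetic gastruloid images

The generator renders a two-channel (DAPI, reporter) 2D image of a single
elongated structure. The body is an axis-aligned ellipse with semi-axes
`(a, b)` in µm (default 150 × 50, matching a well-elongated 120 h
gastruloid at the scale of a few hundred µm). An ellipse was chosen over a
more organic outline because its area (`πab`) and Feret diameters
(`2a`, `2b`) are closed forms, so segmentation and morphometry can be
scored against exact oracles rather than against another segmentation.

* **DAPI channel** — a uniform in-body baseline (default 120 intensity
  units) plus Gaussian blobs (amplitude 100, radius ≈ 4 µm) at nucleus
  centers drawn uniformly inside a 0.92-shrunk ellipse. The baseline
  models cytoplasmic and out-of-focus signal in a maximum-intensity
  projection; it is what makes the whole body a single Otsu foreground
  class and keeps per-sample DAPI normalization of reporter profiles well
  conditioned. Without it the image histogram is dominated by the
  nucleus/inter-nucleus contrast and global thresholding segments nuclei,
  not the structure.
* **Reporter channel** — when polarized, a logistic gradient in relative
  axial position `p ∈ [0, 1]`:
  `I(p) = baseline + amplitude · σ(steepness · (p − midpoint))`, default
  midpoint 0.6, steepness 15, amplitude 200, baseline 10. The published
  images show sigmoid-like posterior confinement of the T reporter but no
  functional form; the logistic is the minimal monotone model with a
  controllable half-max position for half-max-recovery tests. A
  non-polarized structure carries a flat reporter at half amplitude.
* **Noise** — additive Gaussian, default sd 2 intensity units, clipped at
  zero. Real confocal noise levels are not published; the default keeps
  the polarized/flat contrast far above noise (amplitude/σ = 100) so that
  clustering failures indicate implementation errors, not noise. Tests at
  this setting therefore say nothing about behaviour near the detection
  limit.
* **Determinism** — one `numpy.random.Generator` per call consumes draws
  in a fixed order (nucleus positions, radii, DAPI noise, reporter
  noise); identical parameters and seed reproduce bit-identical rasters.

## Synthetic count matrices

Seven populations are planted: `hox_positive`, `brain_like`,
`spinal_like`, `dorsal`, `midline`, `ventral` and `background` (default
50 cells each). Each cell switches "on" exactly its class's marker genes —
the full Hox list for Hox-positive cells, all 30 brain markers for
brain-like cells, the spinal exclusion gene (Fgfbp3) for spinal-like
cells, one dorsal/midline/ventral triplet each for the DV classes, and
nothing for background. On-counts are `1 + Poisson(s·(μ − 1))` with
marker mean μ = 10 and a per-cell Gamma size factor `s` (mean 1, sd
`library_noise` = 0.3); the +1 shift guarantees at least one count before
dropout, so zero-dropout recovery is exact by construction. Dropout zeroes
each on-count independently with probability `dropout_rate`. Twenty
low-level background genes (`bg000`…) carry Poisson(1) counts in every
cell so no cell is empty. This emulates only the marker logic the rules
consume — not library-size heterogeneity across cell types, ambient RNA,
doublets, or correlated dropout — so classifier accuracy on it is an
upper bound for real data.

## Morphometry

* **Feret diameters** are computed exactly by rotating calipers on the
  convex hull of the object's pixel *corners* (each pixel contributes its
  four corners). Corner augmentation makes a `s × s` square measure
  exactly `s√2` across the diagonal and keeps the disk elongation index
  within 1% at radius ≥ 50 px; pixel centers would bias both by one
  pixel. Minimum width is taken flush with a hull edge, which is exact
  for convex polygons.
* **Elongation index** = Feret max / Feret min; **circularity**
  = `√(4·area/(π·FeretMax²))`, clamped at 1.05 before filtering because
  rasterization can push it fractionally above 1.
* **Structure segmentation**: Gaussian smoothing (default σ 1 µm,
  configurable — acquisition resolution varies), then Otsu on intensity,
  or for brightfield-like images Otsu on a local-variance map (window
  15 px default), hole filling, watershed splitting, and removal of
  objects under 5 000 µm² (debris; whole gastruloids are 10⁴–10⁵ µm²).
* **Watershed seeding** uses connected components of the h-maxima of the
  Euclidean distance transform, `h = 0.3 ×` the component's EDT maximum.
  For a convex object the EDT superlevel set is connected, so a single
  elongated body always yields one seed and is never split, while
  dumbbells with a neck shallower than 70% of the lobe radius split into
  two. Seeding on plain distance-transform local maxima with a minimum
  separation was rejected: the EDT ridge of an ellipse carries several
  near-equal maxima at any separation, which oversplits exactly the
  elongated structures this pipeline measures. `min_separation`
  (default 10 µm structures / 5 µm nuclei) additionally merges seed
  components closer than that distance.
* **Nucleus quantification**: smoothing → rolling-ball background
  subtraction (radius 50 µm default; the original background-subtraction
  method is unnamed, rolling-ball is the standard choice) → Otsu →
  watershed. Records carry area, circularity, per-channel mean intensity
  and area-normalized intensity (integrated intensity / area in µm²).
  The filters — area 100–1000 µm², circularity 0.6–1 — are applied as a
  flag, never by dropping records, so consumers can audit what was
  excluded.

## A-P profiling

* **Midline**: by default the principal-axis chord through the mask
  centroid, clipped to the mask (the original lines were drawn by hand;
  a polyline argument reproduces that mode). Intensities are bilinearly
  interpolated at 1-px steps; profile length is the arc length in µm.
* **Orientation**: images alone cannot identify the anatomical anterior,
  so the reporter-brighter half is mapped to relative position 1
  (posterior, where T accumulates); an exact tie keeps the input
  orientation, making the flat case deterministic.
* **Binning**: relative position = absolute position / length; bin `i`
  averages samples in `[i/100, (i+1)/100)`, last bin closed — always
  exactly 100 bins. DAPI normalization divides each *sample* before
  averaging (the alternative, normalizing bin averages, differs only for
  non-uniform DAPI within a bin; per-sample division is the conservative
  reading of "normalized to DAPI and binned"). DAPI is floored at
  `1e-6 × max(DAPI)` to avoid division blow-ups. Empty bins (possible
  only for sparse polylines; dense 1-px sampling never produces them)
  are filled by linear interpolation between non-empty neighbours.
* **Scaling**: optional min–max to [0, 1]; a constant profile raises
  rather than returning 0/0. Both DAPI-normalized and additionally 0–1
  scaled vectors can be clustered, since published figures use both.
* **Clustering**: Euclidean k-means, k-means++ with 10 restarts at a
  fixed seed. Clusters are renumbered by descending centroid mean so
  "cluster 0" is always the high-signal cluster regardless of the
  k-means initialization. The **polarized cluster** is the one whose
  centroid's posterior-quartile mean most exceeds its anterior-quartile
  mean, accepted only if the excess exceeds a threshold (default 2 × the
  pooled SD of all profile values — no numeric definition of a
  "T-positive pole" is published, so the threshold is configurable).
  The per-condition fraction of structures in that cluster is the
  polarization rate.

## Single-cell rules

* **QC**: keep cells with 200 ≤ features ≤ 2500 and mitochondrial
  fraction ≤ 5%. The removal rules are "fewer than 200", "more than
  2500" and "above 5%", so the bounds themselves are kept.
  Mitochondrial genes are identified by the case-insensitive `mt-` name
  prefix.
* **CPM filter** (bulk orientation): keep genes with CPM strictly
  > 0.4 in at least 2 samples; a gene at exactly 0.4 CPM everywhere is
  dropped.
* **Neural categorization**, in precedence order: ≥ 1 of 28 Hox genes
  expressed → `hox_positive`; else ≥ 5 of 30 fore/midbrain markers and
  Fgfbp3 not expressed → `brain_like`; else `spinal_like`. "Expressed"
  means raw count ≥ 1 (threshold configurable; whether the original
  calls were on raw or normalized data is unstated, and raw counts with
  threshold 1 is the only parameter-free reading).
* **DV categorization**: a cell is dorsal/midline/ventral iff it
  expresses ≥ 1 gene of that module and 0 genes of the other two;
  otherwise `unassigned`. Overlapping module lists are a configuration
  error.
* **Marker lists**: the exact 28 Hox genes, 30 fore/midbrain markers and
  three-gene DV modules are cited from reference atlases but not printed
  anywhere reusable; the shipped defaults are placeholders from standard
  mouse nomenclature (28 Hox genes in cluster order; 30 canonical
  fore/midbrain transcription factors; Pax3/Pax7/Msx1, Shh/Foxa2/Ntn1,
  Nkx2-2/Olig2/Nkx6-1). Analyses of real data must supply their own
  lists via `RuleSet` or a YAML rules file.
* **Abundance**: per-state proportions within each condition;
  `log2(prop_condition / prop_reference)` per non-reference condition.
  States with < 10 cells summed across all conditions are excluded;
  a state absent on one side reports ±inf with a flag instead of being
  dropped. The separate < 5-cell rule in the original figures is a
  display (labeling) rule only and not part of the computation.
* **Pseudo-bulk**: per-group arithmetic mean of either raw counts or
  cells scaled to 10 000 counts and log1p-transformed (the upstream
  single-cell normalization).

## Problem sizes and numerical checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
data: 20 images for segmentation recovery (mean absolute relative error
of area and elongation index ≈ 0.2%, bound 5%), 100 structures (30
polarized planted) for clustering recovery (label accuracy 100%,
recovered fraction 30% within the binomial CI), 350 cells across seven
planted classes for rule recovery (100% at zero dropout), and 100 random
toy matrices for filter-oracle agreement, including cells pinned at
exactly the feature bounds and genes pinned at exactly 0.4 CPM. Shape
oracles use a radius-100 px disk, a 200 px square and a 150 × 50 px
ellipse. These sizes were chosen so rasterization error (∝ 1/diameter)
sits well inside the stated tolerances.

## Known limitations

Single 2D structures only — no 3D light-sheet volumes, no tracking, no
lumen detection, no PSF/optics model. The generator plants one structure
per image; multi-structure fields are supported by the segmentation but
not generated. Published headline numbers that depend on the original
raw data (e.g. absolute cell counts after QC, the 71.5% DV-assigned
fraction, per-structure intensity curves) are not reproduced — only the
procedures that computed them are, validated against planted truth.
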
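# Methods

This document describes the image-analysis model implemented by `isletquant`,
the meaning and default of every parameter, the synthetic generator used for
validation, and the numerical design decisions.

## 1. Pipeline model

A field is a set of registered 2D planes keyed by channel role: `nuclear`,
`insulin`, `glucagon`, `igfbp7`, accompanied by an 8-bit islet pixel
probability map (in practice produced by a trained pixel classifier; here
either read from disk or emulated by the generator).

### 1.1 Islet-region segmentation (`segment.segment_islet`)

The probability map is offset by subtracting 40 grey levels (clipped at 0),
Gaussian-blurred with σ = 20 px, rounded back to integer levels, and
thresholded with the Huang minimum-fuzziness method; the islet mask is the
set of pixels strictly above the selected threshold. Degenerate maps are
handled explicitly: a constant positive map yields a full mask, a zero map
yields an empty mask with a warning.

*Parameters* (`IsletParams`): `offset = 40`, `blur_sigma_px = 20`. The offset
suppresses low-confidence classifier output before smoothing; the large blur
merges per-pixel classifier speckle into one coherent region.

### 1.2 Nucleus detection (`segment.detect_nuclei`)

The nuclear channel is masked to the islet, rescaled to the 8-bit range, and
blurred with σ = 9 px. Local maxima with height ≥ 0.7 of the global peak
become candidates; each receives a radius from the mean distance to
half-maximum along the four axis directions (clipped to [4, 14] px) and a
score equal to its normalized height. Greedy non-maximum suppression in
descending score (ties toward smaller (row, col)) removes any candidate whose
disk IoU with an already-kept one exceeds 0.8. Kept detections are painted as
disks onto a blank label image in descending score, never overwriting, so
seed regions are disjoint.

*Parameters* (`NucleiParams`): `blur_sigma_px = 9`, `peak_threshold = 0.7`,
`overlap_threshold = 0.8`, `min_radius_px = 4`, `max_radius_px = 14`. The
probability threshold 0.7 and NMS threshold 0.8 mirror the conventions of
pretrained star-convex nucleus detectors, for which this detector is a
deterministic, dependency-free replacement with the same interface.

### 1.3 Cell-boundary determination (`segment.propagate_cells`)

The guide image is the pixel-wise maximum of the three stain channels after
rescaling each to the full intensity range. The guide is smoothed (σ = 1 px)
and the growth region is the set of pixels whose smoothed value exceeds
`threshold_correction ×` the minimum cross-entropy (Li–Lee) threshold of the
smoothed guide, united with the seed pixels. Each growth pixel receives the
label of the seed reachable at minimum accumulated cost, where a step from
pixel p to 8-neighbor q costs

```
sqrt( (I(p) − I(q))² + λ · d(p,q)² ),   λ = 0.25
```

with d the Euclidean step length (1 or √2). Cost ties go to the smaller
label id. Seed pixels always keep their painted label.

*Parameters* (`PropagationParams`): `regularization_lambda = 0.25`,
`smoothing_sigma_px = 1`, `threshold_correction = 1`, `connectivity = 8`.
λ trades intensity fidelity against spatial compactness: λ = 0 follows
iso-intensity paths arbitrarily far; large λ approaches a Voronoi partition
of the growth region.

### 1.4 Classification and quantification (`quantify`)

Per-cell medians of each channel are taken over the propagated cell region
(raw channels, not the rescaled guide). A cell is a **β-cell** when its
median insulin is at least 1.5× its median glucagon, an **α-cell** when the
mirrored condition holds; the boundary is inclusive ("at least 50% more").
Cells satisfying neither (including both-zero cells) are `unclassified` and
excluded from group summaries but counted.

Colocalization is the Manders overlap coefficient
`MOC = Σab / sqrt(Σa² · Σb²)` of IGFBP7 with the cell's defining hormone over
the cell region; MOC is symmetric, bounded in [0, 1] (Cauchy–Schwarz) and
invariant to separate positive rescaling of either channel.

Group comparisons of per-cell median IGFBP7 (ND vs T2D within each class) use
the Mann-Whitney U test: exact enumeration when n_x + n_y ≤ 12 with no ties,
otherwise the normal approximation with tie and continuity corrections. MOC
comparisons use the classical pooled-variance two-sample t test.

### 1.5 Annotation-guided parameter search (`gridsearch`, `pipeline.run_gridsearch`)

Parameter grids are expanded in lexicographic order. For the islet-mask task
each combination is scored by the Jaccard index against the manual mask,
averaged over the testing fields; for the nucleus task by the absolute count
error and the mean nearest-neighbor distance from manual to automatic
centroids. The optimum is selected deterministically: maximal Jaccard (mask)
or lexicographically minimal (count error, NN distance) (nuclei), ties broken
by grid order.

## 2. Synthetic generator (`synthgen`)

The generator provides fields with exact ground truth; it exists for
validation and power analysis, not biological realism.

- **Geometry**: a centered circular islet (default radius 180 px in a
  512×512 field). Nucleus centers are placed by dart throwing with a minimum
  spacing (default 44 px, default 25 cells), radii 9 px with ±8% jitter.
  Random sequential placement jams at roughly 55% of the hexagonal packing
  capacity; requested densities should stay well below that, and placement
  deterministically restarts (up to 5×) before raising `PlacementError`.
  Cell territories are the nearest-centroid partition of the islet disk;
  types are i.i.d. with P(α) = 0.35.
- **Intensities**: class-defining hormone levels 0.65 (own hormone) vs 0.08
  (other); IGFBP7 levels anchored to published group medians — α: 0.0863 (ND)
  × 1.182 (T2D), β: 0.102 (ND) × 1.038 (T2D). Per-cell variability is a
  mean-preserving lognormal factor (CV 0.2) applied to all channels of a
  cell; pixel noise is Gaussian (σ 0.02) plus a 0.005 background, clipped to
  [0, 1].
- **Probability maps**: the true mask at 255, blurred (σ 5 px), plus Gaussian
  noise (σ 8 grey levels), rounded to 8-bit.
- **Annotations**: `perturb_truth` emulates imperfect manual annotation by
  jittering/dropping centroids and dilating/eroding the mask.

Scope limits: circular islets only, no overlapping nuclei, no uneven
illumination, no channel bleed-through, i.i.d. cell types without spatial
clustering. These idealizations are deliberate — the generator's job is to
make pipeline errors attributable.

## 3. Numerical design decisions

- **Thresholds on 256-level histograms.** Both selectors scan every
  threshold t between the first and last occupied level, computing their
  criterion from cumulative sums; ties resolve to the smallest t, and
  foreground is strictly above t. Huang's fuzziness uses membership
  μ = 1/(1 + |g − m_class| / C) with C the occupied dynamic range and natural
  logarithms; the Li–Lee cross-entropy shifts levels by +1 so zero is valid.
  Float images are binned to 256 levels over their own range and the selected
  bin edge mapped back to intensity. Tests verify both selectors against
  direct-summation exhaustive scans.
- **Deterministic propagation ties.** Accumulated path costs are snapped to
  a 1e-7 quantum so that mathematically tied paths (e.g. mirror-symmetric
  routes whose float sums differ in the last bits) compare equal, and the
  Dijkstra heap orders by (cost, label), so ties always resolve to the
  smaller label regardless of visit order. The validation oracle is an
  independent Bellman-Ford relaxation with the same quantum.
- **Huang mask dilation.** Thresholding a blurred probability map places the
  boundary on the blur shoulder, dilating the mask by a roughly constant
  band (≈ 8 px at σ 20). This is a perimeter effect: mask Jaccard against
  ground truth approaches 1 as region size grows but is bounded near 0.92
  for a radius-100 disk. Recovery tests therefore use large discs.
- **MOC clipping.** The float quotient can exceed 1 by an ulp; the
  implementation clips at 1.0, which the mathematical bound guarantees.
- **Mann-Whitney approximation accuracy.** Exhaustively over all sample-size
  pairs with n_x + n_y ≤ 10 and all achievable U, the exact mode agrees with
  direct enumeration to ≤ 1e-12. The asymptotic mode (continuity-corrected
  normal) has a worst-case error of 0.1289 (n=1 vs 3) and 0.0172 even at
  5 vs 5; a t-reference or an Edgeworth kurtosis correction only reduces the
  worst case to 0.096 / 0.069. No sub-0.01 "approximation" exists at these
  sizes short of secretly computing the exact distribution, so the package
  keeps the standard approximation and uses exact mode automatically whenever
  n_x + n_y ≤ 12 without ties. One acceptance test documents this as a known
  failure rather than weakening the assertion.
- **Determinism.** A single master seed drives cohort generation, probability
  maps, and all derived per-field seeds through `numpy.random.SeedSequence`
  (values reduced mod 2³¹); a rerun of `pipeline.run` with the same config is
  byte-identical in `cells.csv` and `summary.json`.

## 4. Problem sizes used in validation

Validation sizes are the package's own choices, selected for CPU budgets, not
tuned to outcomes: 9-field default cohorts for end-to-end recovery; a
96-field balanced cohort (6 ND donors × 8 fields vs 3 T2D donors × 16) giving
≥ 500 α-cells per group for effect recovery; 20 fields for grid-search
identifiability; 100+ random fixtures for oracle and property checks.

## 5. Limitations

- The propagation solver is pure-Python Dijkstra (~1 s per 512×512 field);
  adequate for validation-scale work, not for thousands of fields.
- The nucleus detector assumes roughly disk-like nuclei within the configured
  radius band; it replaces learned detectors functionally, not statistically.
- Group tests treat cells as independent units (as in the anchored analysis);
  donor-level aggregation is available (`donor_aggregation`) but not the
  default.
- 8-bit image IO quantizes intensities to 1/255.
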
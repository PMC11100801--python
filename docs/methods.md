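# Methods

This note documents the models and procedures implemented in `mgquant`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Image model and conventions

All imaging stages operate on `VolumeImage`, a `(channel, z, y, x)`
intensity grid with physical voxel sizes `(dz, dy, dx)` in µm; 2D images
carry a singleton z axis. Coordinates are 0-based, physical position =
index × voxel size at voxel centres. Every volume is a voxel count times
the voxel volume — no mesh rendering, surface smoothing, or partial-voxel
interpolation anywhere. Raw voxel counts are emitted next to µm³ values
for auditability. Connectivity is 26-connected in 3D and 8-connected in
2D throughout.

Two acquisition geometries are built in as presets: a high-resolution
engulfment geometry (dz = 0.33 µm, dx = dy = 0.1 µm, emulating 60×
confocal stacks) and a low-magnification counting geometry (dz = 1 µm,
dx = dy = 0.3 µm, emulating 20× stacks analyzed as projections).

## Segmentation

Pixel classification is classical thresholding: Otsu's bimodal criterion
for channels whose foreground occupies an appreciable histogram mass
(cell bodies, nuclei), an explicit `("fixed", t)` cutoff, or a robust
background threshold — median + 8 × MAD-σ — for sparse-signal channels.
The robust option exists because a bimodal criterion provably fails when
the foreground is ≪ 1% of voxels (synaptic and FISH puncta channels):
the between-class variance is then maximized by splitting the background
itself. Every chosen threshold is recorded in the run manifest.

Objects are connected components above a size floor. The default floor
is **half** the voxel count of a 2 µm-radius soma (sphere in 3D, disc on
a projected z = 1 lattice): anything smaller than half a soma is debris,
while the half factor tolerates somata clipped by stack or image
boundaries. Removed components are counted in the log, never dropped
silently.

A cell's reported soma centroid is the centroid of its *eroded core* —
the voxels whose anisotropic distance to the object boundary is within
90% of the maximum depth — because for a ramified cell the raw mask
centroid can fall outside the soma, or outside the mask entirely.

Touching-cell splitting (watershed) is out of scope: the generators
enforce cell separation, and the counting contract is defined for
well-separated cells.

## Engulfment volumetrics

Nested masking at the voxel level: lysosome = cell ∩ CD68, engulfed =
lysosome ∩ VGlut2. Phagocytic capacity = 100 × lysosome/cell volume;
engulfed volume is also reported normalized to cell volume. Boolean
conjunction makes the nesting chain engulfed ≤ lysosome ≤ cell a
structural invariant, verified by property tests on adversarial random
masks. Per-cell computation runs inside the cell's bounding box padded
by 2 µm — an optimization only; a test asserts bit-equality with the
whole-field conjunction.

## Sholl analysis

2D only, on the maximum-intensity projection of the selected cell:
skeletonize (topology-preserving medial axis), then count, for each ring
radius, the connected runs of skeleton pixels in a ring band. The band
half-width is 0.75 pixels: an 8-connected path moving outward advances
its radial distance by at most √2 pixels per step, so a band of width
1.5 pixels cannot be tunnelled through — every true crossing deposits at
least one pixel, and a run counts once however obliquely it crosses.
Rings default to 1 µm spacing starting one spacing outside the soma
radius (neither value is dictated by the measurement itself; both are
explicit parameters). Rings clipped by the image border are measured on
the part inside and flagged per-ring, not silently truncated. The
implementation is cross-checked against a brute-force oracle
(distance-bin every skeleton pixel, cluster with union-find) on random
phantoms, and against k-arm star phantoms where the answer is exactly k.

## Marker-intensity binning

Per-cell marker expression is the mean gray value within the cell's Iba1
mask, normalized to the same cell's Iba1 mean gray value. Division is
the default operator; subtraction is available by flag (which operator a
given manual protocol used is typically unstated, so the choice is
explicit and logged). Cutoffs between Lo/Mid/Hi are derived **once from
the pooled all-animal distribution** — never per experimental group,
which would manufacture circular group differences. Two rules:

* `tertile` (default): 33.3/66.7 percentiles. Always defined,
  permutation invariant, equivariant under positive affine rescaling.
* `valley`: the two deepest interior local minima of a Gaussian-KDE
  density (Scott bandwidth, 512-point grid). Requires the density to
  actually have two antimodes; otherwise it errors with guidance to use
  tertiles rather than inventing boundaries.

Boundary values tie inward to Mid. Animal summaries report the
percentage of that animal's cells in each of the 9 joint
(CD68 × TMEM119) categories plus per-marker marginals; the nominal
sampling plan of 12 cells per animal (4 cells × 3 images) is enforced in
strict mode and relaxed with a logged warning otherwise.

## FISH scoring

Nuclei are segmented from DAPI with the robust background threshold
(degrades gracefully to zero objects on an empty field, where a bimodal
criterion would split the noise) and size-filtered. Puncta are detected
per probe channel with the robust threshold and a 1–30 voxel size
window; larger blobs are rejected and logged, and blended puncta are not
split (the generator guarantees separability; on real data the window
bounds the error). Each punctum is assigned to the nucleus containing
its centroid voxel; background puncta are tallied, so assigned +
unassigned = detected.

Typing uses a count margin (default 3 puncta): glutamatergic if
VGlut1 ≥ Gad2 + margin, GABAergic for the reverse, otherwise ambiguous.
Ambiguous cells are excluded from type averages and counted in the log.
The Fos call scales the 6-punctum base threshold linearly with nucleus
volume relative to the field median — "adjusted for cell size" admits
several functional forms; linear scaling is the simplest monotone one
and coincides with cutting the puncta *density* at 6 per median volume,
and the base threshold itself is a parameter. The
inequality is strict: exactly 6 puncta at median volume is Fos−. Target
density is count / DAPI volume (puncta/µm³), averaged per (animal, type)
so the animal is the unit of analysis.

## Synaptic colocalization

Puncta per channel via robust threshold + size window. Two criteria:
voxel overlap (default — closest to "overlap of the two signals"), and
centroid distance ≤ r. Matching is greedy one-to-one, best pair first
(largest overlap / smallest distance), ties broken by lower punctum
index for determinism; one-to-one prevents a single large punctum from
scoring several synapses. Counts are verified against an exhaustive
pure-python matcher on small fields. Density is reported per 100 µm² of
analyzed area.

## Assays and statistics

Closed forms: ΔCt = Ct_target − Ct_18S, ΔΔCt = ΔCt − mean control ΔCt,
fold change = 2^−ΔΔCt; ELISA pg per 100 mg protein =
(pg/mL × 100)/(mg/mL × 1000). Technical Ct triplicates are averaged
after discarding replicates more than 0.5 cycles from the replicate
median (a common bench rule; applied uniformly and logged).

The statistics contract: group comparisons run on animal-level summaries
(unweighted mean of each animal's cells/images), never on raw cell rows.
Models are fit first with sex as a factor; if sex shows no main effect
at α = 0.05 the model is refit pooled across sexes, and the decision is
reported. Pairwise group comparisons are Welch t tests with Šidák
adjustment over the number of pairs. The ANOVA machinery is standard
(statsmodels OLS + type-II ANOVA); only the aggregation, sex-pooling,
and nesting conventions are bespoke and tested.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with ground
truth recorded **from the emitted voxel grids** (so re-counting the
grids reproduces the truth exactly, and recovery tests measure pipeline
geometry, not bookkeeping).

* **Microglia fields**: spherical somata (radius 2 µm) with 4
  persistent-random-walk processes (length 6 µm, radius 0.3 µm, steps
  confined to a ball of radius soma + process length); lysosomal blobs
  (radius 0.5 µm) placed inside each cell until a target fraction
  (default 5%) of its volume; synaptic puncta (~1.5 px radius) of which
  exactly `round(engulfed_fraction × n)` are centred on lysosome voxels
  and the rest on background clear of any cell. Each cell also carries a
  Lo/Mid/Hi TMEM119 expression state (intensity multipliers 0.25 / 0.55
  / 1.0).
* **Placement**: somata sit on a jittered grid whose pitch guarantees
  pairwise separation of at least 2 × (soma + process length) + 1 µm
  (never below 4 × soma radius), so cell masks are disjoint by
  construction and the field auto-sizes to the requested cell count.
  With an explicit field shape, placement falls back to bounded
  dart-throwing and raises a "field too crowded" error on failure.
* **FISH fields**: nuclei of radius 3 µm (±10%), half glutamatergic and
  half GABAergic; per-cell counts drawn negative-binomially
  (var = µ + µ²/k, k = 10 by default; k → ∞ recovers Poisson) with
  type-dependent means — target (IL34) mean 10 in excitatory vs 5 in
  inhibitory cells, i.e. the two-fold expression asymmetry the scoring
  stage must recover. Puncta occupy a jittered anisotropic lattice
  inside each nucleus whose pitch leaves two clear voxels between
  puncta under 26-connectivity, so same-channel puncta can never blend;
  a drawn count exceeding the nucleus's lattice capacity is capped, and
  the truth records what was actually placed.
* **Synapse fields**: planar; `round(p × n)` pre/post pairs placed
  overlapping, all other puncta on separated sites, so the planted pair
  count is exact under both criteria.
* **Intensity model** (all fields): piecewise-constant levels
  (background 10, foreground 100) plus additive Gaussian noise
  (σ = 5), clipped at zero. The 18 σ class separation is deliberate:
  thresholds then recover the painted masks essentially exactly, so
  recovery tolerances measure geometry and assignment logic rather than
  noise luck.
* **Assay tables**: a true fold change f shifts the target Ct by
  −log₂ f around a control ΔCt of 10; ELISA concentrations scale
  multiplicatively with f under lognormal noise.
* **Animal summaries**: per-animal means vary lognormally around the
  group mean with a 30% coefficient of variation (a typical
  between-animal spread for imaging endpoints), sexes balanced.

Determinism: every generator draws from a single RNG stream derived from
(seed, stage name), so outputs are bit-identical for a given config and
independent across stages.

**What passing recovery tests does not show.** The phantoms have no
point-spread function, no depth attenuation or bleaching, no touching
cells, no autofluorescence, and noise-free class separation far beyond
real immunostains. Recovery therefore validates the measurement
definitions, mask algebra, assignment rules, and statistics plumbing —
not robustness to real acquisition artifacts. On real data, thresholds
and size windows need tuning, and counts near the resolution limit will
blend.

## Problem sizes used in validation

The shipped validation runs use: 10-cell engulfment fields across 10
seeds and an engulfed-fraction sweep {0, 0.25, 0.5}; counting fields at
N ∈ {1, 5, 20, 50} across 20 seeds; 400-nucleus FISH fields (200 per
type) across 10 seeds; 200-puncta synapse fields; 1000 randomized mask
triples for the nesting property; and 500 null / 200 effect simulations
for the statistics contract. These sizes keep the full suite to a few
minutes while leaving the recovery margins far from their tolerances.

## Known limitations

* Otsu thresholding replaces trained pixel classifiers; the
  segmentation contract (binary class → objects → counts) is preserved,
  the classifier is not, and equality with any given tool's counts on
  real data is not claimed. Likewise the voxel-mask volumetrics replace
  mesh-based surface reconstruction.
* The two-step sex-screening ANOVA is mildly anti-conservative under
  the generator's skewed (lognormal) between-animal noise at 6 animals
  per group: its long-run type-I rate is ≈ 0.060 at nominal 0.05.
  This is inherent to Gaussian ANOVA on skewed small samples plus
  pre-testing, and is left visible rather than patched over; analysts
  wanting exact calibration should log-transform multiplicative
  measures.
* The greedy one-to-one matcher is not a maximum matching; on
  pathological overlap graphs it can undercount relative to the
  optimum. For puncta at realistic densities the two coincide (tested
  against the exhaustive matcher).
* `read_volume` handles plain and package-written TIFFs only;
  proprietary formats must be converted upstream.
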
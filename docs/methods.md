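# Methods

## Problem and scope

Commercial and in-house auto-segmentation tools delineate organs at
risk (OARs) on radiotherapy planning CT. Their output must be graded:
can a contour be used as-is, with some editing, with heavy editing, or
not at all? `socgrade` implements the three grading routes used in
clinical QA — geometric objective indexes with threshold schemes, an
expert's slice-review (subjective) grade, and the combined route that
anchors geometric index ranges to subjective levels per organ — plus
the synthetic-data machinery needed to test all of it without access
to patient data.

Out of scope: atlas construction and the auto-segmentation algorithms
themselves, DICOM RT-STRUCT parsing or polygon rasterization, image
registration, and inter-observer modelling (the subjective standard
presumes a single expert reviewer).

## Voxel-mask model and conventions

A contour is a 3D boolean occupancy grid with per-axis physical
spacing in mm (axes ordered x, y, z; the third axis is axial). The
physical location of voxel (i, j, k) is `origin + (i, j, k) * spacing`
— voxel *centers*, not face midpoints; sub-voxel geometry is not
modelled. All internal distances are in mm and converted to cm only at
reporting boundaries, since QA reports conventionally print cm.

Surface extraction uses 6-connectivity: an occupied voxel is on the
surface iff at least one face neighbor is background, and the outside
of the grid counts as background, so grid-edge voxels are surface.
26-connectivity would classify slightly fewer voxels as surface; the
face-neighbor definition matches distance-transform conventions and is
fixed by decree.

NIfTI masks are read with nibabel; a voxel is occupied iff its value
exceeds 0.5. Only axis-aligned affines (permutation and flips of a
diagonal matrix) are accepted; rotation or shear would require
resampling, which is out of scope, so such files are rejected with a
clear error. Flips are folded into the data-axis frame: distances,
volumes and overlaps are invariant under them.

## The five indexes

For reference mask A (manual, the declared gold standard) and test
mask B (auto-segmented), validated to share shape, spacing (relative
tolerance 1e-6) and origin, and both nonempty:

* **DSC** `2|A∩B| / (|A|+|B|)` by voxel counts. Symmetric.
* **ΔCMD** Euclidean distance between the unweighted centroids of the
  occupied-voxel centers, in physical space. Symmetric.
* **ΔV** `100 |V_B − V_A| / V_A` with physical volumes. Asymmetric by
  construction: the manual volume is the denominator because it is the
  gold standard.
* **MHD/AHD** over the two surface point sets, with directed
  nearest-neighbor distances d(a,B) = min_b ‖a−b‖:
  MHD = max(max_a d(a,B), max_b d(b,A)),
  AHD = ½(mean_a d(a,B) + mean_b d(b,A)). Both symmetric; AHD ≤ MHD
  always. Several "average Hausdorff" variants exist in the literature
  (max of means, pooled mean); this package uses the symmetrized
  average of the two directed means, stated here explicitly.

Nearest-neighbor queries run through a k-d tree on the physical
surface points, which handles anisotropic spacing naturally. The test
suite checks the k-d tree route against an independent all-pairs
(`cdist`) brute-force oracle on grids up to ~16³, where the two must
agree to floating-point precision because they operate on identical
point sets.

Metrics on empty masks are undefined and raise, rather than returning
sentinel values: an empty auto-contour is a pipeline failure to
report, not a data point.

## Objective grading schemes

A scheme assigns each index value a level via two ordered cutpoints
(plus an optional "perfect" value). Built-ins, shipped as versioned
JSON and loadable by name:

| scheme | indexes | levels | cutpoints |
|---|---|---|---|
| `our_center` | all five | 1–4 | DSC 0.7/0.8; ΔCMD 0.5/1.0 cm; ΔV 10/20%; MHD 1.0/2.2 cm; AHD 0.2/0.4 cm |
| `velker` | DSC | 1–3 | 0.6/0.8 |
| `ciardo` | DSC, ΔCMD, AHD | 1–3 | DSC 0.6/0.8; ΔCMD 0.2/0.5 cm; AHD 0.15/0.4 cm |

Two conventions matter and are fixed package-wide:

* **Boundary convention.** A value exactly on a cutpoint takes the
  *better* adjacent level (intervals closed on the better side). This
  is forced by the bundled benchmark: a centroid distance of exactly
  1.00 cm grades Level 2, a DSC lower bound of 0.8 is inclusive for
  "good", and a subjective 10% modified grades Level 3. With this
  convention all 65 objective level cells of the bundled 13-organ
  benchmark reproduce from the published index means.
* **Level 4.** Only the exact perfect value (DSC 1, distance 0, within
  1e-9) earns Level 4 — "can completely replace manual delineation".
  Three-level schemes simply never return 4.

Grading is monotone (improving an index never lowers the level) and
the level partition is total and disjoint; both are property-tested.

## Subjective standard

An expert reviews the auto-contour slice by slice and records the
number of slices needing modification. The grade depends on organ
length, because one bad slice means something different in a 120-slice
skin contour than in a 9-slice pulmonary vein:

| level | > 10 slices (pct modified) | 3–10 slices (count) | < 3 slices (count) |
|---|---|---|---|
| 4 | 0 | 0 | 0 |
| 3 | (0, 10%] | 1 | 1 |
| 2 | (10%, 20%] | 2–3 | 2 |
| 1 | (20%, 100%] | > 3 | ≥ 3 |

The < 3-slice Level-1 threshold of "≥ 3" is kept as published even
though it is unreachable when the total is below 3 and the modified
count cannot exceed the total; in practice Level 1 for such organs is
then reached only via a 2-of-2 → Level 2 boundary, and the published
cell may have been intended as "2". Percentages may be supplied
directly (e.g. cohort averages of per-patient percentages) or derived
from counts; when derived, grading uses the unrounded value.

The consistency report compares per-organ subjective and objective
levels and counts organs graded exactly one level lower subjectively,
equal, or otherwise, with percentages rounded to one decimal. On the
bundled benchmark this yields 6 of 13 organs (46.2%) one level lower
subjectively than the DSC grade — the observation motivating the
combined standard.

## SOC derivation

Input: per-case records (patient, organ, five indexes, subjective
level, optional exclusion flag — excluded cases are dropped, no
automatic outlier rejection is performed). Per organ and index:

1. Group cases by subjective level; record exact per-level min, max,
   mean.
2. **Single observed level**: one half-bounded interval, anchored at
   the observed extreme that faces the absent adjacent levels and
   extended to the theoretical limit on the level's own quality side.
   Good levels (3/4): DSC [min, 1], distances [0, max]. The worst
   level (1): DSC [0, max], distances [min, ∞). A single observed
   Level 2 (adjacent levels on both sides; not exhibited in the
   benchmark) keeps its observed closed [min, max].
3. **Multiple levels**: for each pair of adjacent *observed* levels,
   compare the closed [min, max] intervals. Disjoint → the observed
   ranges are the standard. Overlapping (shared endpoints count) →
   fall back to per-level means, provided the means are monotone in
   the index's improvement direction; otherwise the entries are marked
   `undefined` rather than silently emitting an unusable standard.
   Mixed outcomes across pairs are preserved per level; a level
   touched by any overlapping pair becomes mean-based.

When a derived range-based standard is later used to grade new values,
unobserved gaps between adjacent ranges are assigned to the worse
level — conservative in the clinical sense that borderline contours
get flagged for more review, not less. Values beyond the observed
extremes clamp to the nearest observed level. Mean-based standards do
not partition the axis and refuse to grade.

DSC is the headline index: in the benchmark, the first-type organs
support all five indexes but the multi-level organs correspond cleanly
to subjective levels only through DSC, so the grading helpers default
to it. The derivation itself is implemented for all five indexes.

## Synthetic data

The study's per-patient contours were never deposited, so the
generators provide inputs whose expected outputs are known
independently:

* **Box pairs** (solid box vs whole-voxel-shifted copy): Dice and ΔV
  by exact voxel counting, ΔCMD from the shift vector, Hausdorff
  distances from the brute-force oracle.
* **Eroded spheres** (digital sphere vs k-fold 6-connected erosion):
  ΔV by exact counting, ΔCMD zero by symmetry, Dice from counts.
* **Simulated cohorts**: per organ and subjective level, DSC drawn
  from a uniform interval or clipped normal; the other four indexes
  drawn uniformly from level-consistent bands aligned with the
  four-level thresholds (the Level-3 MHD band starts above the AHD
  band so AHD ≤ MHD holds by construction; Level-4 cases are exactly
  perfect). One explicit seeded generator; identical seeds give
  identical cohorts bit for bit.

What the synthetic data does *not* emulate: real organ morphology,
atlas-failure modes (missing lobes, leakage into adjacent structures),
correlated index noise, or inter-patient volume variation. Passing
tests therefore demonstrate correctness of the computations and the
derivation logic, not clinical performance of any segmentation tool.

The bundled 13-organ thoracic benchmark contains published cohort
*summaries* only (per-organ index means, level tables, slice-review
averages). It is used as a worked example and as fixtures: applying
the built-in schemes to the published means must reproduce the
published level tables (65/65 objective cells, 13/13 subjective
scores, the 46.2% consistency statistic). Per-case quantities — and
hence the published per-organ standard ranges themselves — cannot be
recomputed from summaries and are not claimed.

## Numerical choices and problem sizes

* Perfection tolerance 1e-9 (Level 4, and zero-distance checks).
* Pair validation: spacing relative tolerance 1e-6.
* CSV display precision: DSC 4 decimals, distances 2 decimals (cm),
  ΔV 1 decimal; JSON retains full precision.
* Property tests run on grids ≤ 16³ where the brute-force oracles are
  exact and fast; cohort-recovery tests use 200 cases per level, at
  which the expected gap between a uniform interval's endpoint and the
  observed extreme, width/(n+1), is well below the assertion
  tolerance (6·width/(n+1)), and mean recovery is asserted within 3
  standard errors.
* Hypothesis property tests are derandomized for reproducibility.

## Known limitations

* Hausdorff distances are computed between boundary-voxel centers, so
  they are quantized at voxel resolution; published values computed on
  contour polygon vertices may differ by up to about one voxel
  diagonal.
* Rotated or sheared NIfTI affines are rejected rather than resampled.
* The volume-difference denominator is always the reference volume;
  swapping arguments changes ΔV (documented, intentional).
* Non-monotone per-level means (small cohorts) yield `undefined`
  entries; the package does not attempt pooling or smoothing.
* The subjective standard encodes a single expert's protocol;
  inter-observer spread is not modelled.
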
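# socgrade

Grading the accuracy of organ-at-risk (OAR) auto-segmentation for
radiotherapy planning, with a subjective–objective-combined (SOC)
approach.

Auto-segmentation software delineates OARs on planning CT, but the
contours must still be reviewed and often edited by a radiation
oncologist. Two evaluation traditions exist: *geometric objective*
grading, where contour-comparison indexes are thresholded into quality
levels, and *subjective* grading, where an expert counts how many CT
slices need manual modification. The two disagree systematically —
geometrically similar contours can still need editing — so this
package also implements the combined approach: derive, per organ, the
geometric index ranges that correspond to each subjective level, and
use those organ-specific ranges as the grading standard.

## What it computes

**Five geometric indexes** between a reference (manual) mask A and a
test (auto-segmented) mask B on a common voxel grid:

- DSC = 2|A ∩ B| / (|A| + |B|), the Dice similarity coefficient ∈ [0, 1];
- ΔCMD, the Euclidean distance between centers of mass (cm);
- ΔV = 100·|V_B − V_A| / V_A, the absolute relative volume difference (%);
- MHD = max(max_a d(a, B), max_b d(b, A)), the symmetrized maximum
  Hausdorff distance between the two surface point sets (cm);
- AHD = ½(mean_a d(a, B) + mean_b d(b, A)), the symmetrized average
  Hausdorff distance (cm),

where d(a, B) = min_b ‖a − b‖ over boundary-voxel centers in physical
millimetres (anisotropic spacing honoured; 3 mm CT slices are typical).

**Objective grading** maps each index to Level 1–4 through configurable
threshold schemes (three built-ins ship as versioned JSON: a
four-level scheme over all five indexes, and two published three-level
comparison schemes). A value exactly on a cutpoint takes the better
level; Level 4 is reserved for exact perfection (DSC 1, distance 0).

**Subjective grading** maps slice-review records to Level 1–4 by organ
length class: organs longer than 10 slices by the percentage of slices
to modify (≤10% → 3, ≤20% → 2, else 1), organs of 3–10 slices by the
modified-slice count, shorter organs by a stricter count; zero
modified slices is always Level 4.

**SOC derivation**: from a cohort of per-case (indexes, subjective
level) records for one organ, compute per-level index ranges. Disjoint
adjacent-level ranges become the grading standard directly; overlapping
ranges fall back to per-level means when those are monotone, and are
reported as undefined otherwise. Single-level organs get one
half-bounded interval anchored at the observed extreme.

A bundled 13-organ thoracic benchmark (per-organ index means, level
tables, and slice-review summaries from a published clinical
evaluation) serves as a worked example and regression fixture.

## Worked example

```python
import socgrade as sg

# a synthetic pair: 20-voxel box vs the same box shifted (3, 0, 1) voxels
ref, test, _ = sg.make_box_pair(size=20, shift=(3, 0, 1), spacing=(1.0, 1.0, 3.0))
m = sg.compute_metric_set(ref, test)
print(f"DSC={m.dsc:.4f}  dCMD={m.cmd_cm:.2f} cm  dV={m.dv_pct:.1f}%  "
      f"MHD={m.mhd_cm:.2f} cm  AHD={m.ahd_cm:.2f} cm")
print(sg.grade_metric_set(m, sg.load_scheme("our_center")))

rec = sg.SubjectiveRecord(oar="L Lung", total_slices=71, modified_slices=7)
print("subjective level:", sg.subjective_grade(rec))

spec = sg.CohortSpec(oars={"Heart": {
    2: sg.LevelSpec(n=20, low=0.70, high=0.86),
    3: sg.LevelSpec(n=20, low=0.82, high=0.96),
}}, seed=7)
std = sg.derive_soc_standard(sg.simulate_cohort(spec), indexes=["dsc"])
print(sg.format_standard_table([std], indexes=["dsc"]))
```

prints

```
DSC=0.8075  dCMD=0.42 cm  dV=0.0%  MHD=0.42 cm  AHD=0.19 cm
{'dsc': 3, 'cmd': 3, 'dv': 4, 'mhd': 3, 'ahd': 3}
subjective level: 3
Structure	DSC L1	DSC L2	DSC L3
Heart	–	0.79	0.90
```

The shifted box overlaps its reference well (DSC 0.81, Level 3); the
boxes are congruent, so ΔV is exactly 0 and earns the perfect Level 4.
Seven of 71 lung slices to modify is 9.9%, within the ≤10% band of
Level 3. The simulated heart cohort's Level-2 and Level-3 DSC ranges
overlap, so the derived standard falls back to the per-level means
(0.79 and 0.90).

## Command line

```sh
socgrade metrics --ref-dir manual/ --test-dir auto/ -o metrics.csv
socgrade grade --scheme our_center --metrics metrics.csv -o levels.csv
socgrade subjective --cases slices.csv -o subjective.csv
socgrade consistency --subjective subjective.csv --objective levels.csv -o report.json
socgrade simulate --spec cohort.yaml --seed 17 -o cohort.csv
socgrade derive --cases cohort.csv --index dsc -o standard.json
socgrade pipeline --metrics cohort.csv --slices slices.csv -o out/
```

Masks are NIfTI (`.nii`/`.nii.gz`, voxel occupied iff value > 0.5,
axis-aligned affines); tables are CSV; schemes and standards are JSON.
Exit codes distinguish validation failures (2), runtime failures (1)
and partial batch failures (3). Logs go to stderr only.

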
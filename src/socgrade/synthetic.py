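"""Synthetic mask pairs and cohorts with known expected values.

Real paired manual/auto contours from the underlying study were never
deposited, so every other module is exercised on constructs whose
metric values are known in closed form or by independent brute force:

* axis-aligned boxes shifted by whole voxels (Dice and centroid
  distance are exact integer arithmetic);
* solid spheres eroded by k voxels (volume difference by exact voxel
  counting, centroid distance zero by symmetry);
* simulated cohorts of (subjective level, index values) records with
  controlled per-level DSC distributions, for testing the SOC
  derivation end to end.

All randomness flows through one explicit ``numpy.random.Generator``;
nothing touches global state, so identical seeds give identical
cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .geometry_metrics import MM_PER_CM, MetricSet
from .mask_core import VoxelMask, extract_surface
from .soc_derivation import CaseRecord


def brute_force_hausdorff(points_a: np.ndarray, points_b: np.ndarray) -> tuple[float, float]:
    """All-pairs maximum and average Hausdorff distance, cm.

    Independent O(|A|·|B|) oracle over two physical point sets (mm);
    intended for small synthetic masks, not production use.
    """
    d = cdist(np.atleast_2d(points_a), np.atleast_2d(points_b))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    mhd = max(float(d_ab.max()), float(d_ba.max()))
    ahd = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    return mhd / MM_PER_CM, ahd / MM_PER_CM


def _as_triple(v) -> tuple:
    if np.isscalar(v):
        return (v, v, v)
    t = tuple(v)
    if len(t) != 3:
        raise ValueError(f"expected a scalar or 3-tuple, got {v!r}")
    return t


def make_box_pair(
    size,
    shift=(0, 0, 0),
    spacing=(1.0, 1.0, 1.0),
) -> tuple[VoxelMask, VoxelMask, MetricSet]:
    """A solid box and a whole-voxel-shifted copy, with expected metrics.

    Expected Dice and ΔV come from exact voxel counting (ΔV is 0: the
    boxes are congruent), the centroid distance from the shift vector,
    and the Hausdorff distances from the brute-force oracle on the two
    surface point sets.
    """
    size = tuple(int(s) for s in _as_triple(size))
    shift = tuple(int(s) for s in _as_triple(shift))
    spacing = tuple(float(s) for s in _as_triple(spacing))
    if min(size) < 1:
        raise ValueError("box size must be at least 1 voxel per axis")
    pad = 1
    grid_shape = tuple(s + abs(d) + 2 * pad for s, d in zip(size, shift))
    ref_grid = np.zeros(grid_shape, dtype=bool)
    test_grid = np.zeros(grid_shape, dtype=bool)
    ref_start = tuple(pad + max(0, -d) for d in shift)
    test_start = tuple(r + d for r, d in zip(ref_start, shift))
    ref_grid[tuple(slice(a, a + s) for a, s in zip(ref_start, size))] = True
    test_grid[tuple(slice(a, a + s) for a, s in zip(test_start, size))] = True
    reference = VoxelMask(ref_grid, spacing=spacing)
    test = VoxelMask(test_grid, spacing=spacing)

    volume = int(np.prod(size))
    overlap = int(np.prod([max(0, s - abs(d)) for s, d in zip(size, shift)]))
    expected_dice = 2.0 * overlap / (2.0 * volume)
    expected_cmd = float(
        np.linalg.norm(np.asarray(shift) * np.asarray(spacing))
    ) / MM_PER_CM
    mhd_cm, ahd_cm = brute_force_hausdorff(
        extract_surface(reference).points, extract_surface(test).points
    )
    expected = MetricSet(
        dsc=expected_dice, cmd_cm=expected_cmd, dv_pct=0.0,
        mhd_cm=mhd_cm, ahd_cm=ahd_cm,
    )
    return reference, test, expected


def make_sphere_mask(
    radius: int,
    spacing=(1.0, 1.0, 1.0),
    margin: int = 2,
) -> VoxelMask:
    """Solid digital sphere: voxels whose center lies within *radius* (voxel
    units) of the grid center."""
    if radius < 1:
        raise ValueError("radius must be at least 1 voxel")
    n = 2 * radius + 2 * margin + 1
    c = n // 2
    ax = np.arange(n) - c
    dist2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return VoxelMask(dist2 <= radius * radius, spacing=_as_triple(spacing))


def make_eroded_pair(
    radius: int,
    erosion: int = 0,
    spacing=(1.0, 1.0, 1.0),
) -> tuple[VoxelMask, VoxelMask, dict]:
    """A solid sphere and a k-fold 6-connected erosion of it.

    Expected ΔV and Dice follow from exact voxel counts (the eroded
    mask is a subset of the reference); the centroid distance is 0 by
    symmetry of the erosion.
    """
    if erosion < 0 or erosion >= radius:
        raise ValueError("erosion must satisfy 0 <= k < radius")
    reference = make_sphere_mask(radius, spacing)
    struct = ndimage.generate_binary_structure(3, 1)
    grid = reference.grid
    if erosion:
        grid = ndimage.binary_erosion(grid, struct, iterations=erosion, border_value=1)
    if not grid.any():
        raise ValueError(f"eroding a radius-{radius} sphere {erosion} times empties it")
    test = VoxelMask(grid, spacing=reference.spacing)
    n_ref, n_test = reference.n_voxels, test.n_voxels
    expected = {
        "dv_pct": 100.0 * (1.0 - n_test / n_ref),
        "dice": 2.0 * n_test / (n_ref + n_test),
        "cmd_cm": 0.0,
    }
    return reference, test, expected


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class LevelSpec:
    """How to draw DSC for the cases of one subjective level.

    Either a uniform interval (``low``/``high``) or a normal
    distribution (``mean``/``sd``, clipped to [0, 1]).
    """

    n: int
    low: float | None = None
    high: float | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("case count must be nonnegative")
        uniform = self.low is not None and self.high is not None
        normal = self.mean is not None and self.sd is not None
        if uniform == normal:
            raise ValueError("specify exactly one of (low, high) or (mean, sd)")
        if uniform and not (0.0 <= self.low <= self.high <= 1.0):
            raise ValueError(f"DSC interval [{self.low}, {self.high}] invalid")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.low is not None:
            return rng.uniform(self.low, self.high, size=n)
        return np.clip(rng.normal(self.mean, self.sd, size=n), 0.0, 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Per-organ, per-level case counts and DSC sampling distributions."""

    oars: Mapping[str, Mapping[int, LevelSpec]]
    seed: int | None = None

    def __post_init__(self) -> None:
        for oar, levels in self.oars.items():
            for level in levels:
                if level not in (1, 2, 3, 4):
                    raise ValueError(f"{oar}: level {level} outside 1–4")


#: Value bands per subjective level for the four non-DSC indexes, used
#: to fill simulated cases with level-consistent draws. Bands follow
#: the four-level objective thresholds; Level-3 MHD is kept above the
#: AHD band so that AHD ≤ MHD holds by construction.
_LEVEL_BANDS = {
    # level: (cmd_lo, cmd_hi), (dv_lo, dv_hi), (mhd_lo, mhd_hi), (ahd_lo, ahd_hi)
    3: ((0.0, 0.5), (0.0, 10.0), (0.25, 1.0), (0.0, 0.2)),
    2: ((0.5, 1.0), (10.0, 20.0), (1.0, 2.2), (0.2, 0.4)),
    1: ((1.0, 2.5), (20.0, 60.0), (2.2, 6.0), (0.4, 1.0)),
}


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> list[CaseRecord]:
    """Draw a reproducible cohort of cases from a CohortSpec.

    DSC comes from the spec's per-level distributions; the other four
    indexes are filled with uniform draws from level-consistent bands
    (Level 4 cases are exactly perfect on every index).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    cases: list[CaseRecord] = []
    for oar in sorted(spec.oars):
        levels = spec.oars[oar]
        for level in sorted(levels):
            lspec = levels[level]
            dsc = lspec.draw(lspec.n, rng)
            for i in range(lspec.n):
                if level == 4:
                    metrics = MetricSet(1.0, 0.0, 0.0, 0.0, 0.0)
                else:
                    (c_lo, c_hi), (v_lo, v_hi), (m_lo, m_hi), (a_lo, a_hi) = _LEVEL_BANDS[level]
                    metrics = MetricSet(
                        dsc=float(dsc[i]),
                        cmd_cm=float(rng.uniform(c_lo, c_hi)),
                        dv_pct=float(rng.uniform(v_lo, v_hi)),
                        mhd_cm=float(rng.uniform(m_lo, m_hi)),
                        ahd_cm=float(rng.uniform(a_lo, a_hi)),
                    )
                cases.append(
                    CaseRecord(
                        patient_id=f"sim-{oar}-{level}-{i:03d}",
                        oar=oar,
                        metrics=metrics,
                        subjective_level=level,
                    )
                )
    return cases


def cohort_spec_from_dict(cfg: dict) -> CohortSpec:
    """Build a CohortSpec from a plain dict (e.g. parsed YAML)."""
    oars = {}
    for oar, levels in cfg["oars"].items():
        oars[oar] = {
            int(level): LevelSpec(
                n=int(lspec["n"]),
                low=lspec.get("low"), high=lspec.get("high"),
                mean=lspec.get("mean"), sd=lspec.get("sd"),
            )
            for level, lspec in levels.items()
        }
    return CohortSpec(oars=oars, seed=cfg.get("seed"))
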
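"""Voxel-mask data model for contour comparison.

A delineated organ (manual or auto-segmented) is represented as a 3D
boolean occupancy grid with anisotropic physical voxel spacing — the
common case in radiotherapy planning CT is ~1 mm in-plane and 3 mm
between axial slices. All geometric indexes consume this representation;
physical coordinates are voxel *centers*, ``origin + index * spacing``,
in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage


class MaskError(ValueError):
    """Base class for mask-domain errors."""


class EmptyMaskError(MaskError):
    """An operation that is undefined on empty masks received one."""


class GeometryMismatchError(MaskError):
    """Two masks that must share a voxel grid do not."""


#: Accepted axis identifiers for slice counting; the axial (z) axis is
#: the third array axis by convention.
_AXIS_ALIASES = {
    "x": 0, "y": 1, "z": 2, "axial": 2,
    0: 0, 1: 1, 2: 2,
}

_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class VoxelMask:
    """A 3D binary occupancy grid with physical spacing.

    Parameters
    ----------
    grid
        3D boolean array, axes ordered (x, y, z).
    spacing
        Physical voxel size per axis, mm; all components strictly positive.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3 or min(grid.shape) < 1:
            raise MaskError(
                f"mask grid must be 3D with nonzero extents, got shape {grid.shape}"
            )
        if grid.dtype != bool:
            grid = grid.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or len(origin) != 3:
            raise MaskError("spacing and origin must have three components")
        if any(s <= 0 for s in spacing):
            raise MaskError(f"spacing components must be positive, got {spacing}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_voxels(self) -> int:
        """Number of occupied voxels."""
        return int(self.grid.sum())

    @property
    def volume_mm3(self) -> float:
        """Physical volume: occupied-voxel count times voxel volume."""
        return self.n_voxels * float(np.prod(self.spacing))

    @property
    def is_empty(self) -> bool:
        return not self.grid.any()

    def indices(self) -> np.ndarray:
        """(N, 3) integer indices of occupied voxels."""
        return np.argwhere(self.grid)

    def to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices to physical voxel-center coordinates (mm)."""
        return np.asarray(self.origin) + np.asarray(indices) * np.asarray(self.spacing)


@dataclass(frozen=True)
class SurfacePointSet:
    """Physical coordinates (mm) of a mask's boundary-voxel centers."""

    points: np.ndarray  # (N, 3), mm
    source_mask_id: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise MaskError("surface points must be an (N, 3) array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def validate_pair(reference: VoxelMask, test: VoxelMask) -> tuple[VoxelMask, VoxelMask]:
    """Check that two masks live on the same grid and are both nonempty.

    All five geometric indexes presuppose a shared voxel lattice; they are
    undefined when either contour is empty.
    """
    if reference.shape != test.shape:
        raise GeometryMismatchError(
            f"shape mismatch: reference {reference.shape} vs test {test.shape}"
        )
    if not np.allclose(reference.spacing, test.spacing, rtol=_SPACING_RTOL, atol=0.0):
        raise GeometryMismatchError(
            f"spacing mismatch: reference {reference.spacing} vs test {test.spacing}"
        )
    if not np.allclose(reference.origin, test.origin, rtol=_SPACING_RTOL, atol=1e-9):
        raise GeometryMismatchError(
            f"origin mismatch: reference {reference.origin} vs test {test.origin}"
        )
    if reference.is_empty:
        raise EmptyMaskError("reference mask is empty; metrics are undefined")
    if test.is_empty:
        raise EmptyMaskError("test mask is empty; metrics are undefined")
    return reference, test


# 6-connectivity: face neighbors only. A voxel is on the surface when at
# least one face neighbor is background; voxels on the grid edge count as
# surface (outside the grid is background).
_SURFACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def extract_surface(mask: VoxelMask, mask_id: str = "") -> SurfacePointSet:
    """Return the boundary-voxel centers of a mask in physical mm.

    The surface is the set of occupied voxels with at least one empty
    6-connected (face) neighbor; these are the point sets the Hausdorff
    distances compare.
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(mask.grid, _SURFACE_STRUCT, border_value=0)
    surface = mask.grid & ~interior
    return SurfacePointSet(mask.to_physical(np.argwhere(surface)), mask_id)


def center_of_mass(mask: VoxelMask) -> np.ndarray:
    """Unweighted centroid of occupied-voxel centers, physical mm."""
    if mask.is_empty:
        raise EmptyMaskError("center of mass of an empty mask is undefined")
    return mask.to_physical(mask.indices().mean(axis=0))


def slice_count(mask: VoxelMask, axis: int | str = "z") -> int:
    """Number of planes along *axis* that contain at least one occupied voxel.

    Defaults to the third (axial) axis, matching CT slice counting.
    """
    try:
        ax = _AXIS_ALIASES[axis if isinstance(axis, int) else str(axis).lower()]
    except KeyError:
        raise MaskError(f"invalid axis {axis!r}; use one of x, y, z, axial, 0, 1, 2")
    other = tuple(a for a in range(3) if a != ax)
    return int(mask.grid.any(axis=other).sum())


# ---------------------------------------------------------------------------
# NIfTI I/O


def _axis_aligned_geometry(affine: np.ndarray) -> tuple[tuple, tuple]:
    """Extract per-data-axis spacing and origin from an axis-aligned affine.

    Affines whose linear part is a permutation/flip of a diagonal matrix are
    accepted; rotation or shear is rejected because resampling is out of
    scope. Flips are folded into the data-axis frame: distances and volumes
    are invariant, which is all the indexes need.
    """
    lin = np.asarray(affine, dtype=float)[:3, :3]
    spacing = []
    origin = []
    seen_rows = set()
    for col in range(3):
        column = lin[:, col]
        nz = np.flatnonzero(np.abs(column) > 1e-6 * max(np.abs(column).max(), 1e-12))
        if len(nz) != 1:
            raise MaskError(
                "NIfTI affine has rotation or shear; only axis-aligned "
                "(permutation/flip) orientations are supported"
            )
        row = int(nz[0])
        if row in seen_rows:
            raise MaskError("NIfTI affine is singular")
        seen_rows.add(row)
        spacing.append(abs(float(column[row])))
        origin.append(float(affine[row, 3]))
    return tuple(spacing), tuple(origin)


def read_nifti_mask(path: str | Path) -> VoxelMask:
    """Load a binary mask from a NIfTI file (voxel occupied iff value > 0.5)."""
    import nibabel as nib

    img = nib.load(str(path))
    spacing, origin = _axis_aligned_geometry(img.affine)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MaskError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    return VoxelMask(data > 0.5, spacing=spacing, origin=origin)


def write_nifti_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI with a diagonal affine."""
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    nib.save(img, str(path))


def mask_from_indices(
    indices: Sequence[Sequence[int]],
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VoxelMask:
    """Convenience constructor: build a mask from a list of occupied indices."""
    grid = np.zeros(shape, dtype=bool)
    idx = np.asarray(indices, dtype=int)
    if idx.size:
        grid[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return VoxelMask(grid, spacing=spacing, origin=origin)
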
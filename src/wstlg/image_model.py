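"""Volume/grid data model, geometry, resampling and mask algebra.

All downstream stages (SUV conversion, bone masking, lesion extraction)
operate on the three containers defined here:

``ImageGrid``
    An axis-aligned 3-D sampling grid in right-handed world millimetres.
    A voxel is a point sample at its centre; voxel ``(i, j, k)`` sits at
    ``origin + (i, j, k) * spacing``.
``VolumeImage``
    One scalar per voxel plus the unit of that scalar (HU, Bq/mL, SUV, SUL).
``BinaryMask``
    A boolean per voxel with a free-text provenance trail recording every
    threshold and exclusion that produced it.

The central geometric operation is :func:`resample_mask_to_grid`, which
harmonises the CT grid (typically 512x512 at sub-millimetre pixels) with the
coarser PET grid (typically 192x192 at 2.6 mm) by trilinear interpolation of
the HU values followed by strict thresholding.  Interpolating values before
thresholding gives smooth partial-volume behaviour at bone edges; the
alternative (nearest-neighbour transport of a pre-thresholded mask) produces
blocky masks and is deliberately not offered.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "VolumeImage",
    "BinaryMask",
    "ValueKind",
    "resample_mask_to_grid",
    "mask_difference",
    "read_nifti_volume",
    "write_nifti_volume",
    "read_nifti_mask",
    "write_nifti_mask",
    "read_dicom_series",
]

ValueKind = Literal["HU", "activity_Bq_per_mL", "SUV", "SUL"]

#: Fill value used for points outside the source CT's field of view during
#: resampling.  Far below any physical HU, so such points never threshold
#: into the bone mask.
_OUTSIDE_HU = -32768.0

_GEOM_ATOL = 1e-6


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned 3-D sampling grid in world millimetres."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: World-axis alignment descriptor (anatomical axis codes of i, j, k).
    axcodes: str = "RAS"

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centre(s); index may be (..., 3)."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous voxel index of world point(s) in mm."""
        return (np.asarray(world) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners of the grid's world extent, including the half
        voxel beyond the outermost sample centres."""
        sp = np.asarray(self.spacing)
        lo = np.asarray(self.origin) - 0.5 * sp
        hi = np.asarray(self.origin) + (np.asarray(self.shape) - 0.5) * sp
        return lo, hi

    def same_geometry(self, other: "ImageGrid", atol: float = _GEOM_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centres."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )


@dataclass
class VolumeImage:
    """A scalar 3-D volume with an explicit physical unit.

    HU volumes admit negatives (air is -1000); SUV/SUL/activity volumes must
    be non-negative.  Negative values above ``-1e-6`` (interpolation jitter)
    are clipped to zero rather than rejected.
    """

    grid: ImageGrid
    values: np.ndarray
    value_kind: ValueKind

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid {self.grid.shape}"
            )
        if self.value_kind not in ("HU", "activity_Bq_per_mL", "SUV", "SUL"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind != "HU":
            vmin = values.min() if values.size else 0.0
            if vmin < -1e-6:
                raise ValueError(
                    f"{self.value_kind} volume has negative values (min {vmin:g})"
                )
            if vmin < 0:
                values = np.clip(values, 0.0, None)
        self.values = values

    def with_values(self, values: np.ndarray, value_kind: ValueKind) -> "VolumeImage":
        return VolumeImage(grid=self.grid, values=values, value_kind=value_kind)


@dataclass
class BinaryMask:
    """A boolean volume plus a provenance trail of how it was produced."""

    grid: ImageGrid
    membership: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        membership = np.asarray(self.membership)
        if membership.shape != self.grid.shape:
            raise ValueError(
                f"membership shape {membership.shape} does not match grid "
                f"{self.grid.shape}"
            )
        self.membership = membership.astype(bool)

    @property
    def n_members(self) -> int:
        return int(self.membership.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_members * self.grid.voxel_volume_ml


def _check_world_overlap(a: ImageGrid, b: ImageGrid) -> None:
    lo_a, hi_a = a.world_bounds()
    lo_b, hi_b = b.world_bounds()
    if np.any(hi_a <= lo_b) or np.any(hi_b <= lo_a):
        raise ValueError(
            "CT and target grids do not overlap in world space; the inputs "
            "appear misregistered (check NIfTI affines / DICOM geometry)"
        )


def resample_mask_to_grid(
    ct_volume: VolumeImage,
    target: ImageGrid,
    hu_threshold: float = 152.0,
    *,
    fill_holes: bool = False,
) -> BinaryMask:
    """Bone mask on ``target`` from a CT volume by interpolate-then-threshold.

    The CT is interpolated trilinearly onto the target voxel centres and a
    voxel becomes a member iff its interpolated attenuation is *strictly*
    greater than ``hu_threshold`` (default 152 HU, the bone/soft-tissue
    boundary used throughout).  Target voxels outside the CT field of view
    are non-members by definition.

    Parameters
    ----------
    ct_volume : VolumeImage with value_kind ``"HU"``.
    target : grid to produce the mask on (typically the PET grid).
    hu_threshold : attenuation above which a voxel counts as bone.
    fill_holes : if True, fill cavities fully enclosed by the thresholded
        mask (binary hole filling).  Off by default; useful when osteolytic
        lesions carve sub-threshold cavities inside otherwise intact bone
        that should still count as skeletal territory.

    Raises
    ------
    ValueError : if the CT is not an HU volume or the world extents of the
        two grids are disjoint (misregistered inputs).
    """
    if ct_volume.value_kind != "HU":
        raise ValueError(
            f"resample_mask_to_grid needs an HU volume, got {ct_volume.value_kind}"
        )
    _check_world_overlap(ct_volume.grid, target)

    if ct_volume.grid.same_geometry(target):
        resampled = ct_volume.values
    else:
        # Continuous source indices of every target voxel centre, built by
        # broadcasting per-axis 1-D coordinates.
        src = ct_volume.grid
        coords = [
            ((target.origin[a] + np.arange(target.shape[a]) * target.spacing[a])
             - src.origin[a]) / src.spacing[a]
            for a in range(3)
        ]
        ii = coords[0][:, None, None]
        jj = coords[1][None, :, None]
        kk = coords[2][None, None, :]
        grid_coords = np.broadcast_arrays(ii, jj, kk)
        resampled = ndimage.map_coordinates(
            ct_volume.values,
            np.stack([c.ravel() for c in grid_coords]),
            order=1,
            mode="constant",
            cval=_OUTSIDE_HU,
        ).reshape(target.shape)

    membership = resampled > hu_threshold
    provenance = [
        f"CT>{hu_threshold:g} HU (strict), trilinear resample "
        f"{ct_volume.grid.shape}@{ct_volume.grid.spacing} -> "
        f"{target.shape}@{target.spacing}",
    ]
    if fill_holes:
        membership = ndimage.binary_fill_holes(membership)
        provenance.append("binary hole filling (enclosed cavities kept as bone)")
    return BinaryMask(grid=target, membership=membership, provenance=provenance)


def mask_difference(mask: BinaryMask, exclusion: BinaryMask) -> BinaryMask:
    """Remove ``exclusion`` members from ``mask`` (mask AND NOT exclusion).

    This is the scriptable replacement for the manual deletion of metal
    artefacts and extra-skeletal calcification from the bone mask; the
    exclusion is recorded in the provenance trail.
    """
    if not mask.grid.same_geometry(exclusion.grid):
        raise ValueError("mask and exclusion are on different grids")
    return BinaryMask(
        grid=mask.grid,
        membership=mask.membership & ~exclusion.membership,
        provenance=[
            *mask.provenance,
            f"minus exclusion mask ({exclusion.n_members} voxels"
            + (f"; {'; '.join(exclusion.provenance)}" if exclusion.provenance else "")
            + ")",
        ],
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_affine(affine: np.ndarray, shape: Sequence[int]) -> ImageGrid:
    rot = affine[:3, :3]
    spacing = np.sqrt((rot ** 2).sum(axis=0))
    # Off-diagonal terms beyond rounding mean an oblique acquisition, which
    # the axis-aligned grid model does not represent.
    aligned = np.allclose(rot, np.diag(np.diag(rot)), atol=1e-3 * spacing.max())
    if not aligned:
        raise ValueError(
            "oblique NIfTI affine; reorient the image to an axis-aligned "
            "(canonical) orientation before loading"
        )
    signs = np.sign(np.diag(rot))
    if np.any(signs < 0):
        raise ValueError(
            "negative affine diagonal; load via nibabel.as_closest_canonical "
            "(read_nifti_volume does this automatically)"
        )
    return ImageGrid(
        shape=tuple(int(n) for n in shape),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in affine[:3, 3]),
    )


def _grid_affine(grid: ImageGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def read_nifti_volume(path: str | Path, value_kind: ValueKind) -> VolumeImage:
    """Load a NIfTI volume, reoriented to canonical RAS, as ``value_kind``."""
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(str(path)))
    grid = _grid_from_affine(img.affine, img.shape[:3])
    values = np.asarray(img.get_fdata(), dtype=np.float64)
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    return VolumeImage(grid=grid, values=values, value_kind=value_kind)


def write_nifti_volume(volume: VolumeImage, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(volume.values.astype(np.float32), _grid_affine(volume.grid))
    nib.save(img, str(path))


def read_nifti_mask(path: str | Path, provenance: str = "loaded from file") -> BinaryMask:
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(str(path)))
    grid = _grid_from_affine(img.affine, img.shape[:3])
    return BinaryMask(
        grid=grid,
        membership=np.asarray(img.get_fdata()) > 0.5,
        provenance=[f"{provenance}: {path}"],
    )


def write_nifti_mask(mask: BinaryMask, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(mask.membership.astype(np.uint8), _grid_affine(mask.grid))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Optional DICOM-series ingestion
# ---------------------------------------------------------------------------

def read_dicom_series(
    directory: str | Path,
) -> tuple[VolumeImage, dict]:
    """Assemble one axial DICOM series into a volume plus header metadata.

    Slices are sorted by their position along the slice axis; CT series are
    rescaled to HU via RescaleSlope/Intercept; PT series are returned as
    activity concentration (Bq/mL assumed) together with whatever acquisition
    metadata (weight, dose, times) the headers carry, under the same keys the
    JSON sidecar uses.

    Returns ``(volume, meta)`` where ``meta`` may be passed to
    :func:`wstlg.suv_quant.AcquisitionMeta.from_mapping`.
    """
    import pydicom

    paths = sorted(p for p in Path(directory).iterdir() if p.is_file())
    slices = []
    for p in paths:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {directory}")

    slices.sort(key=lambda ds: float(getattr(ds, "ImagePositionPatient", [0, 0, 0])[2]))
    first = slices[0]
    rows, cols = int(first.Rows), int(first.Columns)
    row_sp, col_sp = (float(x) for x in first.PixelSpacing)
    if len(slices) > 1:
        z0 = float(slices[0].ImagePositionPatient[2])
        z1 = float(slices[1].ImagePositionPatient[2])
        slice_sp = abs(z1 - z0)
    else:
        slice_sp = float(getattr(first, "SliceThickness", 1.0))

    stack = np.stack([s.pixel_array.astype(np.float64) for s in slices], axis=-1)
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    stack = stack * slope + intercept

    modality = str(getattr(first, "Modality", "")).upper()
    value_kind: ValueKind = "HU" if modality == "CT" else "activity_Bq_per_mL"

    origin = tuple(float(x) for x in getattr(first, "ImagePositionPatient", (0, 0, 0)))
    # pixel_array is (row, col); store as (i=col/x, j=row/y, k=slice/z).
    stack = np.transpose(stack, (1, 0, 2))
    grid = ImageGrid(
        shape=stack.shape, spacing=(col_sp, row_sp, slice_sp), origin=origin
    )

    meta: dict = {"modality": modality}
    if hasattr(first, "PatientWeight"):
        meta["body_weight_kg"] = float(first.PatientWeight)
    if hasattr(first, "PatientSize"):
        meta["body_height_m"] = float(first.PatientSize)
    if hasattr(first, "PatientSex"):
        meta["sex"] = {"M": "male", "F": "female"}.get(str(first.PatientSex), None)
    rpis = getattr(first, "RadiopharmaceuticalInformationSequence", None)
    if rpis:
        item = rpis[0]
        if hasattr(item, "RadionuclideTotalDose"):
            meta["injected_dose_mbq"] = float(item.RadionuclideTotalDose) / 1e6
        if hasattr(item, "RadiopharmaceuticalStartTime"):
            meta["injection_time"] = str(item.RadiopharmaceuticalStartTime)
        if hasattr(item, "RadionuclideHalfLife"):
            meta["half_life_min"] = float(item.RadionuclideHalfLife) / 60.0
    if hasattr(first, "AcquisitionTime"):
        meta["scan_start_time"] = str(first.AcquisitionTime)
    return VolumeImage(grid=grid, values=stack, value_kind=value_kind), meta
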
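"""Active whole-skeletal total lesion glycolysis (WS-TLG).

The biomarker is computed in three steps on a co-registered SUV volume and
CT-derived bone mask:

1. Candidate voxels are those inside the bone mask with SUV strictly above
   the cutoff (default 4.0).
2. Candidates are grouped into lesions as connected components (default
   26-connectivity, the standard for hot-spot labelling in PET).
3. Each lesion contributes its total lesion glycolysis,
   ``TLG = volume_mL * SUVmean``, and WS-TLG is the sum over all lesions.

Because ``TLG = |voxels| * voxel_volume * mean(SUV) = voxel_volume *
sum(SUV)``, WS-TLG is invariant to how the supra-cutoff set is partitioned
into components — the connectivity choice affects the per-lesion report, not
the total.  It also makes WS-TLG monotone non-increasing in both the SUV
cutoff and the HU threshold (each only shrinks the candidate set, whose
members all have positive SUV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_model import BinaryMask, VolumeImage

__all__ = [
    "Lesion",
    "StudyResult",
    "extract_lesions",
    "compute_wstlg",
    "roi_suvmax",
    "CONNECTIVITY_STRUCTURES",
]

#: Map from face/edge/corner voxel connectivity to a scipy label structure.
CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Lesion:
    """One connected supra-cutoff voxel set inside the bone compartment.

    ``tlg = volume_ml * suv_mean`` holds exactly by construction, and
    ``suv_mean`` is taken over the supra-threshold voxels only (the "volume
    above threshold"), not over any anatomical lesion extent.
    """

    label: int
    voxel_indices: np.ndarray  # (n, 3) int array of grid indices
    volume_ml: float
    suv_mean: float
    suv_max: float
    tlg: float
    centroid_mm: tuple[float, float, float]
    #: Smallest flattened (C-order) voxel index — a deterministic identity
    #: used for tie-breaking in target-lesion selection.
    min_flat_index: int
    #: Single-voxel lesions are kept (no minimum size is imposed) but flagged
    #: so reports can audit noise sensitivity.
    single_voxel: bool = False
    #: Optional SULpeak, filled in by response_criteria.sulpeak when needed.
    sul_peak: float | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])


@dataclass
class StudyResult:
    """All lesions plus their WS-TLG total for one scan at one setting."""

    lesions: list[Lesion]
    ws_tlg: float
    suv_cutoff: float
    hu_threshold: float
    exclusions_applied: bool = False

    def __post_init__(self) -> None:
        if self.ws_tlg < 0:
            raise ValueError("ws_tlg must be >= 0")

    @property
    def positive(self) -> bool:
        """WS-TLG positivity: any number above 0."""
        return self.ws_tlg > 0


def extract_lesions(
    suv_volume: VolumeImage,
    bone: BinaryMask,
    suv_cutoff: float = 4.0,
    connectivity: int = 26,
) -> list[Lesion]:
    """Connected supra-cutoff lesions inside the bone mask.

    Candidate voxels satisfy ``bone(v) and SUV(v) > suv_cutoff`` (strict);
    connected components of the candidate set under the chosen connectivity
    (6, 18 or 26) become lesions, each carrying volume, SUVmean, SUVmax and
    TLG.  An empty bone mask or an all-subthreshold volume yields an empty
    list, not an error.  Lesions are returned in scanning (label) order.
    """
    if suv_volume.value_kind not in ("SUV", "SUL"):
        raise ValueError(f"expected an SUV/SUL volume, got {suv_volume.value_kind}")
    if not suv_volume.grid.same_geometry(bone.grid):
        raise ValueError("SUV volume and bone mask are on different grids")
    if connectivity not in CONNECTIVITY_STRUCTURES:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")

    candidate = bone.membership & (suv_volume.values > suv_cutoff)
    labels, n_lesions = ndimage.label(
        candidate, structure=CONNECTIVITY_STRUCTURES[connectivity]
    )
    if n_lesions == 0:
        return []

    values = suv_volume.values
    index = np.arange(1, n_lesions + 1)
    sums = ndimage.sum_labels(values, labels, index)
    maxima = ndimage.maximum(values, labels, index)
    counts = np.bincount(labels.ravel(), minlength=n_lesions + 1)[1:]
    centroids = ndimage.center_of_mass(candidate, labels, index)
    voxel_volume = suv_volume.grid.voxel_volume_ml

    # Group member coordinates by label in one pass.
    coords = np.argwhere(candidate)
    coord_labels = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    order = np.argsort(coord_labels, kind="stable")
    coords = coords[order]
    splits = np.cumsum(counts)[:-1]
    per_lesion_coords = np.split(coords, splits)

    lesions: list[Lesion] = []
    for lab, lesion_coords, total, vmax, count, com in zip(
        index, per_lesion_coords, sums, maxima, counts, centroids
    ):
        count = int(count)
        mean = float(total) / count
        volume_ml = count * voxel_volume
        flat = np.ravel_multi_index(lesion_coords.T, suv_volume.grid.shape)
        lesions.append(
            Lesion(
                label=int(lab),
                voxel_indices=lesion_coords,
                volume_ml=volume_ml,
                suv_mean=mean,
                suv_max=float(vmax),
                tlg=volume_ml * mean,
                centroid_mm=tuple(
                    float(c) for c in suv_volume.grid.index_to_world(np.asarray(com))
                ),
                min_flat_index=int(flat.min()),
                single_voxel=bool(count == 1),
            )
        )
    return lesions


def compute_wstlg(
    lesions: list[Lesion],
    suv_cutoff: float = 4.0,
    hu_threshold: float = 152.0,
    exclusions_applied: bool = False,
) -> StudyResult:
    """Sum per-lesion TLG into the study's WS-TLG.

    Deterministic and order-independent; an empty lesion list gives 0.
    """
    return StudyResult(
        lesions=list(lesions),
        ws_tlg=float(sum(lesion.tlg for lesion in lesions)),
        suv_cutoff=suv_cutoff,
        hu_threshold=hu_threshold,
        exclusions_applied=exclusions_applied,
    )


def roi_suvmax(suv_volume: VolumeImage, roi: BinaryMask) -> float:
    """Maximum SUV over a region of interest (e.g., a normal-bone site).

    Used to survey physiologic marrow uptake (vertebrae, sternum, rib,
    ilium) in patients without skeletal metastasis when choosing a cutoff.
    """
    if not suv_volume.grid.same_geometry(roi.grid):
        raise ValueError("SUV volume and ROI are on different grids")
    if roi.n_members == 0:
        raise ValueError("ROI is empty")
    return float(suv_volume.values[roi.membership].max())
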
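"""End-to-end orchestration: CT + PET (+ metadata, exclusions) -> WS-TLG report.

``run_study`` executes the full measurement chain —

    resample CT -> bone mask -> subtract exclusions -> extract lesions -> sum

— and returns the :class:`~wstlg.wstlg_core.StudyResult` together with a
JSON-serialisable report carrying the per-lesion table, the WS-TLG total,
the verbatim configuration, and SHA-256 hashes of the input arrays so any
report can be traced back to its exact inputs.  Reruns with identical
inputs and configuration produce byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_model import (
    BinaryMask,
    VolumeImage,
    mask_difference,
    resample_mask_to_grid,
)
from .suv_quant import AcquisitionMeta, to_suv
from .wstlg_core import StudyResult, compute_wstlg, extract_lesions

__all__ = ["RunConfig", "run_study", "report_json", "lesion_table", "load_config"]

log = logging.getLogger("wstlg")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings, serialised verbatim into every report.

    ``fill_bone_cavities`` keeps sub-threshold cavities fully enclosed by
    bone (e.g., the carved interior of an osteolytic lesion) inside the
    skeletal territory; off by default so the mask is the plain strict
    HU-threshold rule.
    """

    suv_cutoff: float = 4.0
    hu_threshold: float = 152.0
    connectivity: int = 26
    calibration_factor: float = 1.0
    fill_bone_cavities: bool = False
    #: PERCIST target evaluation mode ("sum" of up-to-two SULpeaks or
    #: "hottest" single lesion); recorded for provenance of response runs.
    percist_target_mode: str = "sum"

    def __post_init__(self) -> None:
        if self.suv_cutoff <= 0 or self.hu_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.calibration_factor <= 0:
            raise ValueError("calibration_factor must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """RunConfig from an optional YAML file, with keyword overrides."""
    data: dict = {}
    if path is not None:
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _array_hash(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()


def run_study(
    config: RunConfig,
    ct: VolumeImage,
    pet: VolumeImage,
    meta: AcquisitionMeta | None = None,
    exclusion: BinaryMask | None = None,
) -> tuple[StudyResult, dict]:
    """Run the full WS-TLG measurement on one co-registered study.

    ``pet`` may be an activity-concentration volume (requires ``meta`` for
    SUV conversion) or already in SUV units (passed through; a non-unit
    ``calibration_factor`` then rescales it directly).  The optional
    ``exclusion`` mask removes metal artefacts / extra-skeletal
    calcification from the bone mask and must share the PET grid.
    """
    input_hashes = {"ct_sha256": _array_hash(ct.values), "pet_sha256": _array_hash(pet.values)}

    if pet.value_kind == "activity_Bq_per_mL":
        if meta is None:
            raise ValueError("activity-concentration PET needs acquisition metadata")
        if config.calibration_factor != 1.0:
            meta = dataclasses.replace(
                meta, calibration_factor=config.calibration_factor
            )
        suv = to_suv(pet, meta)
        log.info("stage suv: converted activity to SUV (%d voxels)", suv.grid.n_voxels)
    elif pet.value_kind == "SUV":
        suv = pet
        if config.calibration_factor != 1.0:
            suv = pet.with_values(
                pet.values * config.calibration_factor, "SUV"
            )
        log.info("stage suv: input already in SUV units (%d voxels)", suv.grid.n_voxels)
    else:
        raise ValueError(f"PET volume must be activity or SUV, got {pet.value_kind}")

    bone = resample_mask_to_grid(
        ct,
        suv.grid,
        config.hu_threshold,
        fill_holes=config.fill_bone_cavities,
    )
    log.info(
        "stage bone-mask: %d of %d voxels above %g HU",
        bone.n_members,
        bone.grid.n_voxels,
        config.hu_threshold,
    )

    exclusions_applied = False
    if exclusion is not None:
        before = bone.n_members
        bone = mask_difference(bone, exclusion)
        exclusions_applied = True
        log.info(
            "stage exclusion: removed %d voxels (%d -> %d)",
            before - bone.n_members,
            before,
            bone.n_members,
        )
        input_hashes["exclusion_sha256"] = _array_hash(exclusion.membership)

    lesions = extract_lesions(
        suv, bone, suv_cutoff=config.suv_cutoff, connectivity=config.connectivity
    )
    log.info(
        "stage lesions: %d lesions, %d supra-cutoff voxels",
        len(lesions),
        sum(l.n_voxels for l in lesions),
    )

    study = compute_wstlg(
        lesions,
        suv_cutoff=config.suv_cutoff,
        hu_threshold=config.hu_threshold,
        exclusions_applied=exclusions_applied,
    )
    log.info("stage wstlg: WS-TLG = %.4f mL*SUV", study.ws_tlg)

    report = {
        "config": config.to_dict(),
        "inputs": input_hashes,
        "bone_mask": {
            "n_voxels": bone.n_members,
            "volume_ml": bone.volume_ml,
            "provenance": bone.provenance,
        },
        "lesions": [
            {
                "id": lesion.label,
                "centroid_mm": [round(c, 4) for c in lesion.centroid_mm],
                "n_voxels": lesion.n_voxels,
                "volume_ml": lesion.volume_ml,
                "suv_mean": lesion.suv_mean,
                "suv_max": lesion.suv_max,
                "tlg": lesion.tlg,
                "single_voxel": lesion.single_voxel,
            }
            for lesion in study.lesions
        ],
        "n_single_voxel_lesions": int(sum(l.single_voxel for l in study.lesions)),
        "ws_tlg": study.ws_tlg,
        "ws_tlg_positive": bool(study.positive),
    }
    return study, report


def report_json(report: dict) -> str:
    """Canonical JSON serialisation (sorted keys, stable float repr)."""
    return json.dumps(report, sort_keys=True, indent=2)


def lesion_table(study: StudyResult) -> pd.DataFrame:
    """Per-lesion rows (id, centroid, volume, SUVmean, SUVmax, TLG)."""
    return pd.DataFrame(
        [
            {
                "id": lesion.label,
                "centroid_x_mm": lesion.centroid_mm[0],
                "centroid_y_mm": lesion.centroid_mm[1],
                "centroid_z_mm": lesion.centroid_mm[2],
                "n_voxels": lesion.n_voxels,
                "volume_ml": lesion.volume_ml,
                "suv_mean": lesion.suv_mean,
                "suv_max": lesion.suv_max,
                "tlg": lesion.tlg,
                "single_voxel": lesion.single_voxel,
            }
            for lesion in study.lesions
        ],
        columns=[
            "id",
            "centroid_x_mm",
            "centroid_y_mm",
            "centroid_z_mm",
            "n_voxels",
            "volume_ml",
            "suv_mean",
            "suv_max",
            "tlg",
            "single_voxel",
        ],
    )
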
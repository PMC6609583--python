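"""SUV and SUL quantitation from activity-concentration volumes.

The standardized uptake value normalises tissue activity concentration by
the decay-corrected injected dose per body mass::

    SUV(v) = calibration * activity(v) / (decayed_dose_Bq / body_weight_g)

with the injected dose decayed from injection to scan start,
``decayed = injected * 2**(-dt / half_life)``.  The usual 1 g/mL tissue
density is assumed, so SUV is dimensionless.  SUL substitutes lean body
mass (Janmahasatian prediction, the PERCIST-recommended form) for total
weight, making uptake comparable across body compositions.

The dimensionless ``calibration_factor`` rescales SUVs measured on scanners
whose reconstructions under- or over-read a reference phantom (older
systems may read 20-30% low); it multiplies every voxel and defaults to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from datetime import datetime, time as dtime
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .image_model import VolumeImage

__all__ = [
    "F18_HALF_LIFE_MIN",
    "AcquisitionMeta",
    "decayed_dose_bq",
    "to_suv",
    "to_sul",
    "lean_body_mass",
    "load_acquisition_meta",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

Sex = Literal["male", "female"]


def _parse_timestamp(value) -> datetime | float:
    """Accept datetimes, minutes-as-number, ISO strings, or DICOM HHMMSS."""
    if isinstance(value, datetime):
        return value
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip()
    try:
        return datetime.fromisoformat(s)
    except ValueError:
        pass
    # DICOM TM format HHMMSS(.frac)
    base = s.split(".")[0]
    if base.isdigit() and len(base) in (4, 6):
        hh, mm = int(base[:2]), int(base[2:4])
        ss = int(base[4:6]) if len(base) == 6 else 0
        frac = float("0." + s.split(".")[1]) if "." in s else 0.0
        t = dtime(hh, mm, ss)
        return datetime.combine(datetime(2000, 1, 1).date(), t).replace(
            microsecond=int(frac * 1e6)
        )
    raise ValueError(f"cannot parse timestamp {value!r}")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata needed to convert activity to SUV/SUL.

    Parameters
    ----------
    injected_dose_mbq : administered activity in MBq at injection time.
    injection_time, scan_start_time : datetimes, DICOM/ISO time strings, or
        plain minutes; scan start must not precede injection.
    body_weight_kg : patient weight in kg.
    body_height_m, sex : required only for SUL (lean-body-mass) conversion.
    half_life_min : tracer half-life in minutes (default F-18).
    calibration_factor : scanner cross-calibration scalar, > 0.
    """

    injected_dose_mbq: float
    injection_time: datetime | float | str
    scan_start_time: datetime | float | str
    body_weight_kg: float
    body_height_m: float | None = None
    sex: Sex | None = None
    half_life_min: float = F18_HALF_LIFE_MIN
    calibration_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected_dose_mbq must be > 0")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be > 0")
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be > 0")
        if self.calibration_factor <= 0:
            raise ValueError("calibration_factor must be > 0")
        if self.uptake_minutes < 0:
            raise ValueError("scan_start_time precedes injection_time")

    @property
    def uptake_minutes(self) -> float:
        t0 = _parse_timestamp(self.injection_time)
        t1 = _parse_timestamp(self.scan_start_time)
        if isinstance(t0, float) != isinstance(t1, float):
            raise ValueError("injection and scan times must share a representation")
        if isinstance(t0, float):
            return t1 - t0
        return (t1 - t0).total_seconds() / 60.0

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AcquisitionMeta":
        known = {
            k: data[k]
            for k in (
                "injected_dose_mbq",
                "injection_time",
                "scan_start_time",
                "body_weight_kg",
                "body_height_m",
                "sex",
                "half_life_min",
                "calibration_factor",
            )
            if k in data and data[k] is not None
        }
        return cls(**known)


def load_acquisition_meta(path: str | Path) -> AcquisitionMeta:
    """Read acquisition metadata from a JSON or YAML sidecar file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return AcquisitionMeta.from_mapping(data)


def decayed_dose_bq(meta: AcquisitionMeta) -> float:
    """Injected dose in Bq decay-corrected to scan start."""
    return (
        meta.injected_dose_mbq
        * 1e6
        * 2.0 ** (-meta.uptake_minutes / meta.half_life_min)
    )


def lean_body_mass(weight_kg: float, height_m: float, sex: Sex) -> float:
    """Predicted lean body mass in kg (Janmahasatian).

    male:   9270 W / (6680 + 216 BMI)
    female: 9270 W / (8780 + 244 BMI),  BMI = W / height^2.

    Always below total weight for physiologic inputs.
    """
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be > 0")
    bmi = weight_kg / height_m**2
    if sex == "male":
        return 9270.0 * weight_kg / (6680.0 + 216.0 * bmi)
    if sex == "female":
        return 9270.0 * weight_kg / (8780.0 + 244.0 * bmi)
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


def _normalise(volume: VolumeImage, meta: AcquisitionMeta, mass_g: float,
               kind: str) -> VolumeImage:
    if volume.value_kind != "activity_Bq_per_mL":
        raise ValueError(
            f"expected an activity_Bq_per_mL volume, got {volume.value_kind}; "
            "volumes already in SUV units need no conversion"
        )
    if np.any(volume.values < 0):
        raise ValueError("negative activity concentration")
    dose_per_gram = decayed_dose_bq(meta) / mass_g
    values = meta.calibration_factor * volume.values / dose_per_gram
    return volume.with_values(values, kind)


def to_suv(volume: VolumeImage, meta: AcquisitionMeta) -> VolumeImage:
    """Body-weight SUV volume from an activity-concentration volume."""
    return _normalise(volume, meta, meta.body_weight_kg * 1000.0, "SUV")


def to_sul(volume: VolumeImage, meta: AcquisitionMeta) -> VolumeImage:
    """Lean-body-mass SUL volume; requires height and sex in the metadata.

    Voxelwise, SUL = SUV * (LBM / weight): the same normalisation with lean
    body mass in grams in place of total body weight.
    """
    if meta.body_height_m is None or meta.sex is None:
        raise ValueError("SUL conversion needs body_height_m and sex")
    lbm_kg = lean_body_mass(meta.body_weight_kg, meta.body_height_m, meta.sex)
    return _normalise(volume, meta, lbm_kg * 1000.0, "SUL")
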
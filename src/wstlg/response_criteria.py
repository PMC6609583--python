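"""Bone-restricted PERCIST / EORTC response classification and WS-TLG
trajectory grouping.

Both criteria are applied to skeletal lesions only, ignoring other organs.
Up to two osseous target lesions with the highest uptake are followed:
PERCIST evaluates the change in summed SULpeak (lean-body-mass-normalised
peak uptake), EORTC the change in summed SUVmax.  When baseline uptake is
too low for PERCIST (summed SULpeak of 0), the EORTC path applies.

Category rules (evaluated in order):

PERCIST
    PMD  — a new lesion, or SULpeak increase >= 30% AND >= 0.8 SUL units
    CMR  — follow-up uptake at or below the background level, no new lesion
    PMR  — SULpeak decrease >= 30% AND >= 0.8 SUL units
    SMD  — anything between PMR and PMD
EORTC
    PMD  — a new lesion, or summed SUVmax increase >= 25%
    CMR  — complete resolution of uptake in all lesions
    PMR  — summed SUVmax decrease >= 25%
    SMD  — the remainder

Longitudinal WS-TLG series are grouped by the signs of successive
differences: *favorable* if the series never increases, *progressive* if it
never decreases and increases at least once, *fluctuating* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .image_model import VolumeImage
from .wstlg_core import Lesion

__all__ = [
    "TargetLesionSet",
    "ResponseAssessment",
    "TrajectoryClass",
    "sulpeak",
    "select_targets",
    "percist_classify",
    "eortc_classify",
    "trajectory_classify",
    "classify_followup_table",
]

Category = Literal["CMR", "PMR", "SMD", "PMD"]
MetricKind = Literal["SULpeak", "SUVmax"]


@dataclass
class TargetLesionSet:
    """Up to two target-lesion measurements from one study."""

    lesions: list[Lesion]
    metric_values: list[float]
    metric: MetricKind
    study_time: str = ""
    regimen_id: str = ""

    def __post_init__(self) -> None:
        if len(self.lesions) > 2:
            raise ValueError("at most two target lesions are followed")
        if len(self.metric_values) != len(self.lesions):
            raise ValueError("one metric value per lesion required")

    @property
    def summed_value(self) -> float:
        return float(sum(self.metric_values))

    @property
    def hottest_value(self) -> float:
        return float(max(self.metric_values)) if self.metric_values else 0.0


@dataclass
class ResponseAssessment:
    """A CMR/PMR/SMD/PMD call with the deltas that justify it."""

    criterion: Literal["PERCIST", "EORTC"]
    category: Category
    percent_change: float | None
    absolute_change: float | None = None  # SUL units; PERCIST only
    new_lesion: bool = False
    background_level: float | None = None  # SUL reference used for CMR


@dataclass
class TrajectoryClass:
    label: Literal["favorable", "progressive", "fluctuating"]
    series: list[float]


def sulpeak(
    sul_volume: VolumeImage,
    lesion: Lesion,
    sphere_volume_ml: float = 1.0,
) -> float:
    """Peak SUL: the highest mean SUL within a ~1 mL sphere in the lesion.

    Sphere centres are placed at every member-voxel centre; for each centre
    the mean is taken over all voxels (inside or outside the lesion) whose
    centres lie within the sphere radius, and the maximum of these means is
    returned.  At grid borders the mean is over the in-grid voxels only.

    If the sphere is smaller than a single voxel the measure degenerates to
    the lesion SUVmax (with a warning).
    """
    if lesion.n_voxels == 0:
        raise ValueError("lesion has no member voxels")
    grid = sul_volume.grid
    radius_mm = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

    # Boolean footprint of voxel-centre offsets within the sphere radius.
    half = [int(np.floor(radius_mm / s)) for s in grid.spacing]
    if all(h == 0 for h in half):
        warnings.warn(
            f"{sphere_volume_ml} mL sphere covers a single voxel centre at "
            f"spacing {grid.spacing}; SULpeak degenerates to SUVmax",
            stacklevel=2,
        )
        return lesion.suv_max
    offsets = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, grid.spacing)],
        indexing="ij",
    )
    footprint = sum(o**2 for o in offsets) <= radius_mm**2

    # Restrict the convolution to the lesion's bounding box padded by the
    # footprint radius — full-volume correlation would be needlessly slow.
    lo = np.maximum(lesion.voxel_indices.min(axis=0) - half, 0)
    hi = np.minimum(
        lesion.voxel_indices.max(axis=0) + half + 1, np.asarray(grid.shape)
    )
    window = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    values = sul_volume.values[window]

    kernel = footprint.astype(np.float64)
    sums = ndimage.correlate(values, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(
        np.ones_like(values), kernel, mode="constant", cval=0.0
    )
    means = sums / counts

    local = lesion.voxel_indices - lo
    return float(means[local[:, 0], local[:, 1], local[:, 2]].max())


def select_targets(
    lesions: Sequence[Lesion],
    by: MetricKind = "SULpeak",
    metric_values: Sequence[float] | None = None,
    study_time: str = "",
    regimen_id: str = "",
) -> TargetLesionSet:
    """Pick the (up to) two hottest lesions by the chosen metric.

    ``by="SUVmax"`` reads each lesion's ``suv_max``; ``by="SULpeak"`` reads
    ``lesion.sul_peak`` unless ``metric_values`` supplies the numbers
    directly.  Exact ties break deterministically by larger volume, then by
    lowest member voxel index, so the selection is stable under permutation
    of the input.  An empty input yields an empty set.
    """
    lesions = list(lesions)
    if metric_values is not None:
        if len(metric_values) != len(lesions):
            raise ValueError("metric_values must align with lesions")
        metrics = [float(m) for m in metric_values]
    elif by == "SUVmax":
        metrics = [lesion.suv_max for lesion in lesions]
    else:
        if any(lesion.sul_peak is None for lesion in lesions):
            raise ValueError(
                "SULpeak selection needs lesion.sul_peak set (see sulpeak()) "
                "or explicit metric_values"
            )
        metrics = [float(lesion.sul_peak) for lesion in lesions]

    order = sorted(
        range(len(lesions)),
        key=lambda i: (-metrics[i], -lesions[i].volume_ml, lesions[i].min_flat_index),
    )[:2]
    return TargetLesionSet(
        lesions=[lesions[i] for i in order],
        metric_values=[metrics[i] for i in order],
        metric=by,
        study_time=study_time,
        regimen_id=regimen_id,
    )


def _summed(value: "TargetLesionSet | float") -> float:
    if isinstance(value, TargetLesionSet):
        return value.summed_value
    return float(value)


def percist_classify(
    baseline: "TargetLesionSet | float",
    followup: "TargetLesionSet | float",
    new_lesion: bool = False,
    background: float = 0.0,
) -> ResponseAssessment:
    """PERCIST category from baseline/follow-up summed target SULpeak.

    Requires a positive baseline; a baseline of 0 cannot anchor the percent
    change and such cases are assessed with the EORTC path instead.  The
    30% and 0.8-SUL-unit conditions are conjunctive in both directions.
    """
    b = _summed(baseline)
    f = _summed(followup)
    if b <= 0:
        raise ValueError(
            "PERCIST needs baseline SULpeak > 0; use eortc_classify for "
            "low-uptake baselines"
        )
    pct = 100.0 * (f - b) / b
    delta = f - b
    if new_lesion:
        category: Category = "PMD"
    elif pct >= 30.0 and delta >= 0.8:
        category = "PMD"
    elif f <= background:
        category = "CMR"
    elif pct <= -30.0 and delta <= -0.8:
        category = "PMR"
    else:
        category = "SMD"
    return ResponseAssessment(
        criterion="PERCIST",
        category=category,
        percent_change=pct,
        absolute_change=delta,
        new_lesion=new_lesion,
        background_level=background,
    )


def eortc_classify(
    baseline_sum_suvmax: float,
    followup_sum_suvmax: float,
    new_lesion: bool = False,
    all_resolved: bool = False,
) -> ResponseAssessment:
    """EORTC category from baseline/follow-up summed SUVmax (25% rule)."""
    b = float(baseline_sum_suvmax)
    f = float(followup_sum_suvmax)
    if b < 0 or f < 0:
        raise ValueError("summed SUVmax must be >= 0")
    if b > 0:
        pct: float | None = 100.0 * (f - b) / b
    else:
        pct = None
    if new_lesion:
        category: Category = "PMD"
    elif pct is not None and pct >= 25.0:
        category = "PMD"
    elif pct is None and f > 0:
        # Uptake appearing where baseline had none is progression.
        category = "PMD"
    elif all_resolved:
        category = "CMR"
    elif pct is not None and pct <= -25.0:
        category = "PMR"
    else:
        category = "SMD"
    return ResponseAssessment(
        criterion="EORTC",
        category=category,
        percent_change=pct,
        new_lesion=new_lesion,
    )


def trajectory_classify(
    series: Sequence[float], tolerance: float = 0.0
) -> TrajectoryClass:
    """Group a time-ordered WS-TLG series by the signs of its differences.

    favorable    — no successive increase (all deltas <= tolerance)
    progressive  — no successive decrease and at least one increase
    fluctuating  — at least one increase and at least one decrease

    The default tolerance of 0 treats any strict change as a move; a
    nonzero tolerance ignores changes of magnitude <= tolerance.
    """
    values = [float(v) for v in series]
    if len(values) < 2:
        raise ValueError("a trajectory needs at least two studies")
    deltas = np.diff(values)
    has_increase = bool(np.any(deltas > tolerance))
    has_decrease = bool(np.any(deltas < -tolerance))
    if not has_increase:
        label = "favorable"
    elif not has_decrease:
        label = "progressive"
    else:
        label = "fluctuating"
    return TrajectoryClass(label=label, series=values)


def classify_followup_table(
    table,
    background: float = 0.0,
    trajectory_tolerance: float = 0.0,
) -> dict:
    """Classify a longitudinal measurement table patient by patient.

    ``table`` is a pandas DataFrame with columns (patient, study_time,
    regimen, metric_kind, lesion_id, value, new_lesion); ``metric_kind`` is
    ``SULpeak`` (PERCIST), ``SUVmax`` (EORTC) or ``WSTLG`` (used only for
    the trajectory).  Within a patient, studies are taken in row order;
    a change of ``regimen`` resets the baseline to the first study of the
    new regimen, mirroring re-selection of target lesions.

    Returns ``{patient: {"intervals": [...], "trajectory": label}}``.  Each
    interval entry records the criterion, category and deltas versus the
    current baseline.  The trajectory label is computed over the per-study
    WSTLG series when present, else over the summed metric series.
    """
    import pandas as pd

    table = pd.DataFrame(table)
    required = {"patient", "study_time", "regimen", "metric_kind", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measurement table is missing columns {sorted(missing)}")
    if "new_lesion" not in table.columns:
        table = table.assign(new_lesion=False)

    out: dict = {}
    for patient, rows in table.groupby("patient", sort=False):
        # Per-study summed metric, in first-appearance order.
        studies = []
        for study_time, srows in rows.groupby("study_time", sort=False):
            metric_rows = srows[srows["metric_kind"] != "WSTLG"]
            wstlg_rows = srows[srows["metric_kind"] == "WSTLG"]
            studies.append(
                {
                    "study_time": str(study_time),
                    "regimen": str(srows["regimen"].iloc[0]),
                    "metric_kind": (
                        str(metric_rows["metric_kind"].iloc[0])
                        if len(metric_rows)
                        else None
                    ),
                    "summed": float(metric_rows["value"].sum()),
                    "wstlg": (
                        float(wstlg_rows["value"].iloc[0]) if len(wstlg_rows) else None
                    ),
                    "new_lesion": bool(srows["new_lesion"].astype(bool).any()),
                }
            )
        intervals = []
        baseline = studies[0]
        for study in studies[1:]:
            if study["regimen"] != baseline["regimen"]:
                baseline = study  # regimen change: this study re-baselines
                intervals.append(
                    {
                        "study_time": study["study_time"],
                        "category": None,
                        "note": "baseline reset (regimen change)",
                    }
                )
                continue
            metric = study["metric_kind"] or baseline["metric_kind"]
            if metric == "SULpeak" and baseline["summed"] > 0:
                assessment = percist_classify(
                    baseline["summed"],
                    study["summed"],
                    new_lesion=study["new_lesion"],
                    background=background,
                )
            else:
                assessment = eortc_classify(
                    baseline["summed"],
                    study["summed"],
                    new_lesion=study["new_lesion"],
                    all_resolved=study["summed"] == 0,
                )
            intervals.append(
                {
                    "study_time": study["study_time"],
                    "criterion": assessment.criterion,
                    "category": assessment.category,
                    "percent_change": assessment.percent_change,
                    "absolute_change": assessment.absolute_change,
                    "new_lesion": assessment.new_lesion,
                }
            )
        if all(s["wstlg"] is not None for s in studies):
            series = [s["wstlg"] for s in studies]
        else:
            series = [s["summed"] for s in studies]
        trajectory = (
            trajectory_classify(series, tolerance=trajectory_tolerance).label
            if len(series) >= 2
            else None
        )
        out[str(patient)] = {"intervals": intervals, "trajectory": trajectory}
    return out
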
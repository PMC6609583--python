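"""Cohort-level cutoff selection and summaries.

WS-TLG positivity is binary — "any number above 0" — so for a cohort with a
reference diagnosis the specificity at a given SUV cutoff is the fraction of
non-metastatic patients whose WS-TLG is 0, and the sensitivity the fraction
of metastatic patients whose WS-TLG is positive.  Because WS-TLG is
monotone non-increasing in the cutoff, raising the cutoff can only turn
positives negative: specificity never falls and sensitivity never rises.

"Comparing specificity and sensitivity" to pick a cutoff is operationalised
as Youden's J = sensitivity + specificity - 100 (ties go to the lowest
cutoff); a minimum-specificity constraint is available as an alternative
rule.  Percentages are rounded half-up to integers to match clinical
reporting style, with the unrounded values always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortRecord",
    "SensSpec",
    "CutoffEntry",
    "CutoffScanResult",
    "sens_spec",
    "cutoff_scan",
    "scan_from_rates",
    "select_cutoff",
    "stratify_by_ct_type",
    "normal_bone_stats",
    "NormalBoneStats",
    "round_half_up",
]

CTType = Literal["blastic", "intertrabecular", "lytic", "mixed", "none"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (printed style)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CohortRecord:
    """One patient's WS-TLG measurements across candidate cutoffs."""

    patient_id: str
    has_bone_metastasis: bool
    wstlg_by_cutoff: Mapping[float, float]
    ct_type: CTType = "none"

    def __post_init__(self) -> None:
        items = sorted(self.wstlg_by_cutoff.items())
        prev = math.inf
        for cutoff, value in items:
            if value < 0:
                raise ValueError(f"WS-TLG must be >= 0, got {value} at {cutoff}")
            if value > prev + 1e-9:
                raise ValueError(
                    f"WS-TLG must be non-increasing in cutoff "
                    f"(patient {self.patient_id}: {prev} -> {value})"
                )
            prev = value
        object.__setattr__(self, "wstlg_by_cutoff", dict(items))

    def positive_at(self, cutoff: float) -> bool:
        return self.wstlg_by_cutoff[cutoff] > 0


class SensSpec(NamedTuple):
    """Sensitivity/specificity in percent, unrounded and printed-style."""

    sensitivity: float
    specificity: float
    sensitivity_rounded: int
    specificity_rounded: int
    n_positive: int  # test-positive among metastatic
    n_metastatic: int
    n_negative: int  # test-negative among non-metastatic
    n_nonmetastatic: int


@dataclass(frozen=True)
class CutoffEntry:
    cutoff: float
    rates: SensSpec

    @property
    def youden_j(self) -> float:
        return self.rates.sensitivity + self.rates.specificity - 100.0


@dataclass
class CutoffScanResult:
    entries: list[CutoffEntry]
    selected_cutoff: float | None = None


def _rates_from_counts(
    n_negative: int, n_nonmetastatic: int, n_positive: int, n_metastatic: int
) -> SensSpec:
    if n_nonmetastatic <= 0 or n_metastatic <= 0:
        raise ValueError("both diagnostic classes must be present")
    sens = 100.0 * n_positive / n_metastatic
    spec = 100.0 * n_negative / n_nonmetastatic
    return SensSpec(
        sensitivity=sens,
        specificity=spec,
        sensitivity_rounded=round_half_up(sens),
        specificity_rounded=round_half_up(spec),
        n_positive=n_positive,
        n_metastatic=n_metastatic,
        n_negative=n_negative,
        n_nonmetastatic=n_nonmetastatic,
    )


def sens_spec(records: Sequence[CohortRecord], cutoff: float) -> SensSpec:
    """Sensitivity/specificity of WS-TLG positivity at one cutoff."""
    met = [r for r in records if r.has_bone_metastasis]
    nonmet = [r for r in records if not r.has_bone_metastasis]
    if not met or not nonmet:
        raise ValueError("records must contain both metastatic and non-metastatic patients")
    n_positive = sum(r.positive_at(cutoff) for r in met)
    n_negative = sum(not r.positive_at(cutoff) for r in nonmet)
    return _rates_from_counts(n_negative, len(nonmet), n_positive, len(met))


def cutoff_scan(
    records: Sequence[CohortRecord], cutoffs: Sequence[float]
) -> CutoffScanResult:
    """Scan candidate cutoffs, computing rates at each."""
    if not cutoffs:
        raise ValueError("at least one candidate cutoff is required")
    entries = [
        CutoffEntry(cutoff=float(c), rates=sens_spec(records, c)) for c in cutoffs
    ]
    return CutoffScanResult(entries=entries)


def scan_from_rates(
    triples: Iterable[tuple[float, float, float]],
    n_nonmetastatic: int = 100,
    n_metastatic: int = 100,
) -> CutoffScanResult:
    """Build a scan from printed (cutoff, specificity %, sensitivity %)
    triples, e.g. when only a published table is available."""
    entries = []
    for cutoff, spec, sens in triples:
        n_negative = round_half_up(spec / 100.0 * n_nonmetastatic)
        n_positive = round_half_up(sens / 100.0 * n_metastatic)
        rates = _rates_from_counts(
            n_negative, n_nonmetastatic, n_positive, n_metastatic
        )._replace(sensitivity=float(sens), specificity=float(spec),
                   sensitivity_rounded=round_half_up(sens),
                   specificity_rounded=round_half_up(spec))
        entries.append(CutoffEntry(cutoff=float(cutoff), rates=rates))
    return CutoffScanResult(entries=entries)


def select_cutoff(
    scan: CutoffScanResult,
    rule: Literal["youden", "min_specificity"] = "youden",
    min_specificity: float = 90.0,
) -> float:
    """Pick the working cutoff from a scan.

    ``youden`` (default) maximises J = sensitivity + specificity - 100;
    ``min_specificity`` picks the most sensitive cutoff whose specificity
    meets ``min_specificity``.  Ties go to the lowest cutoff; the result is
    independent of the scan's entry order.
    """
    if not scan.entries:
        raise ValueError("empty cutoff scan")
    entries = sorted(scan.entries, key=lambda e: e.cutoff)
    if rule == "youden":
        best = max(entries, key=lambda e: (e.youden_j, -e.cutoff))
    elif rule == "min_specificity":
        eligible = [e for e in entries if e.rates.specificity >= min_specificity]
        if not eligible:
            raise ValueError(
                f"no cutoff reaches specificity {min_specificity}%"
            )
        best = max(eligible, key=lambda e: (e.rates.sensitivity, -e.cutoff))
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    scan.selected_cutoff = best.cutoff
    return best.cutoff


def stratify_by_ct_type(
    records: Sequence[CohortRecord],
    cutoff: float = 4.0,
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-CT-type WS-TLG summary for metastatic patients at one cutoff.

    Returns a DataFrame indexed by CT type with columns ``n``,
    ``n_positive``, ``positive_pct`` (rounded half-up), ``mean_wstlg`` and
    ``sd_wstlg``.  ``ddof=0`` (population SD) is the default; pass
    ``ddof=1`` for the sample convention.  Empty strata appear with n=0 and
    absent (NaN) summaries.
    """
    met = [r for r in records if r.has_bone_metastasis]
    if not met:
        raise ValueError("no metastatic records to stratify")
    order = ["blastic", "intertrabecular", "lytic", "mixed"]
    rows = {}
    groups = {t: [r for r in met if r.ct_type == t] for t in order}
    groups["total"] = met
    for ct_type, group in groups.items():
        if not group:
            rows[ct_type] = dict(
                n=0, n_positive=0, positive_pct=np.nan,
                mean_wstlg=np.nan, sd_wstlg=np.nan,
            )
            continue
        values = np.array([r.wstlg_by_cutoff[cutoff] for r in group])
        n_pos = int(sum(v > 0 for v in values))
        rows[ct_type] = dict(
            n=len(group),
            n_positive=n_pos,
            positive_pct=round_half_up(100.0 * n_pos / len(group)),
            mean_wstlg=float(values.mean()),
            sd_wstlg=float(values.std(ddof=ddof)) if len(values) > ddof else np.nan,
        )
    return pd.DataFrame.from_dict(rows, orient="index")


class NormalBoneStats(NamedTuple):
    """The six per-site summaries of physiologic bone SUVmax."""

    mean: float
    sd: float
    mean_plus_2sd: float
    mean_plus_3sd: float
    minimum: float
    maximum: float


def normal_bone_stats(values: Sequence[float], ddof: int = 1) -> NormalBoneStats:
    """Summaries of normal-bone SUVmax at one site (>= 2 measurements).

    The mean + 2SD and mean + 3SD columns bound physiologic uptake and
    motivate the starting point of the cutoff search (vertebral mean + 3SD
    is about 3.5).  Sample SD (ddof=1) by default.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("at least two measurements are needed for an SD")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=ddof))
    return NormalBoneStats(
        mean=mean,
        sd=sd,
        mean_plus_2sd=mean + 2 * sd,
        mean_plus_3sd=mean + 3 * sd,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )
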
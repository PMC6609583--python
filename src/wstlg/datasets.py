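"""Bundled clinical reference tables for WS-TLG validation.

These are the published reference values from the original single-centre
breast-cancer evaluation of the biomarker: physiologic bone SUVmax
summaries, the cutoff scan (85 patients without / 35 with skeletal
metastasis at SUV cutoffs 3.5/4.0/4.5), the CT-type stratification of the
35 newly diagnosed metastatic patients, and the 15 longitudinal WS-TLG
follow-up series with their published per-interval PERCIST/EORTC calls.

They serve as fixed inputs for worked examples and validation — cutoff
selection, rate arithmetic and trajectory grouping can all be recomputed
from them offline.
"""

from __future__ import annotations

from .cohort_stats import CutoffScanResult, scan_from_rates

__all__ = [
    "NORMAL_BONE_SUVMAX",
    "CUTOFF_SCAN_COUNTS",
    "CT_TYPE_SUMMARY",
    "FOLLOWUP_SERIES",
    "FOLLOWUP_GROUPS",
    "followup_series",
    "cutoff_scan_table",
]

#: Physiologic SUVmax summaries at five frequently involved sites measured
#: in 41 breast-cancer patients without skeletal metastasis:
#: (mean, SD, minimum, maximum, mean+2SD, mean+3SD).
NORMAL_BONE_SUVMAX: dict[str, tuple[float, float, float, float, float, float]] = {
    "sternum": (1.43, 0.33, 0.86, 2.17, 2.09, 2.42),
    "rib": (1.27, 0.43, 0.78, 2.37, 2.13, 2.56),
    "Th7": (2.29, 0.36, 1.66, 2.97, 3.01, 3.37),
    "L3": (2.33, 0.36, 1.56, 3.26, 3.05, 3.41),
    "ilium": (1.66, 0.31, 1.09, 2.33, 2.28, 2.59),
}

#: Cutoff scan counts: per SUV cutoff, (WS-TLG-negative among 85 patients
#: without skeletal metastasis, WS-TLG-positive among 35 with).
CUTOFF_SCAN_COUNTS: dict[float, tuple[int, int]] = {
    3.5: (69, 34),
    4.0: (77, 34),
    4.5: (80, 32),
}
N_WITHOUT_METASTASIS = 85
N_WITH_METASTASIS = 35

#: Published printed rates for the same scan:
#: cutoff -> (specificity %, sensitivity %).
CUTOFF_SCAN_RATES: dict[float, tuple[int, int]] = {
    3.5: (81, 97),
    4.0: (91, 97),
    4.5: (94, 91),
}

#: CT-type stratification of the 35 newly diagnosed metastatic patients at
#: cutoff 4.0: type -> (n, n WS-TLG-positive, positive %, mean, SD).
CT_TYPE_SUMMARY: dict[str, tuple[int, int, int, float, float]] = {
    "blastic": (5, 5, 100, 30.9, 45.6),
    "intertrabecular": (6, 5, 83, 30.9, 43.3),
    "lytic": (12, 12, 100, 208.7, 326.3),
    "mixed": (12, 12, 100, 393.7, 680.0),
    "total": (35, 34, 97, 216.2, 454.7),
}

#: Time-ordered WS-TLG series of the 15 followed patients (case number ->
#: values from the pre-treatment study through the follow-ups, regimen
#: changes included in order).
FOLLOWUP_SERIES: dict[int, list[float]] = {
    1: [11.6, 0.0, 0.0],
    2: [0.0, 0.0, 0.0, 0.0],
    3: [22.0, 0.5, 0.0, 0.0],
    4: [22.4, 0.0, 0.0, 0.0],
    5: [2.8, 76.7, 532.5],
    6: [0.4, 15.3, 509.8],
    7: [0.0, 6.6, 23.2],
    8: [0.0, 1.0, 234.8],
    9: [0.2, 199.2, 889.4],
    10: [254.7, 43.5, 107.1],
    11: [15.5, 0.0, 4.6],
    12: [13.6, 0.0, 0.0, 0.0, 1.0],
    13: [73.4, 80.2, 0.4],
    14: [24.5, 0.0, 0.0, 3.8, 12.8],
    15: [13.3, 72.4, 0.1, 10.2, 14.1],
}

#: Published response group per case (the grouping the trajectory rule
#: reproduces: 4 favorable, 5 progressive, 6 fluctuating).
FOLLOWUP_GROUPS: dict[int, str] = {
    **{case: "favorable" for case in (1, 2, 3, 4)},
    **{case: "progressive" for case in (5, 6, 7, 8, 9)},
    **{case: "fluctuating" for case in (10, 11, 12, 13, 14, 15)},
}


def followup_series() -> dict[int, list[float]]:
    """The 15 longitudinal WS-TLG series, case number -> ordered values."""
    return {case: list(values) for case, values in FOLLOWUP_SERIES.items()}


def cutoff_scan_table(source: str = "rates") -> CutoffScanResult:
    """The published cutoff scan as a :class:`CutoffScanResult`.

    ``source="rates"`` builds the scan from the printed percentages;
    ``source="counts"`` recomputes the rates from the printed counts
    (69/77/80 negatives of 85; 34/34/32 positives of 35) — the two agree
    after half-up rounding.
    """
    if source == "rates":
        return scan_from_rates(
            [(c, spec, sens) for c, (spec, sens) in sorted(CUTOFF_SCAN_RATES.items())],
            n_nonmetastatic=N_WITHOUT_METASTASIS,
            n_metastatic=N_WITH_METASTASIS,
        )
    if source == "counts":
        triples = []
        for cutoff, (n_neg, n_pos) in sorted(CUTOFF_SCAN_COUNTS.items()):
            spec = 100.0 * n_neg / N_WITHOUT_METASTASIS
            sens = 100.0 * n_pos / N_WITH_METASTASIS
            triples.append((cutoff, spec, sens))
        return scan_from_rates(
            triples,
            n_nonmetastatic=N_WITHOUT_METASTASIS,
            n_metastatic=N_WITH_METASTASIS,
        )
    raise ValueError(f"source must be 'rates' or 'counts', got {source!r}")
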
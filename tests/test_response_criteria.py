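"""PERCIST/EORTC rule tables, SULpeak, target selection, trajectories."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import full_mask, make_suv
from wstlg import (
    ImageGrid,
    VolumeImage,
    classify_followup_table,
    eortc_classify,
    extract_lesions,
    percist_classify,
    select_targets,
    sulpeak,
    trajectory_classify,
)
from wstlg.datasets import FOLLOWUP_GROUPS, FOLLOWUP_SERIES


def sul_volume(grid, values):
    return VolumeImage(grid=grid, values=values, value_kind="SUL")


def lesions_from(grid, values, cutoff=4.0):
    return extract_lesions(make_suv(grid, values), full_mask(grid), suv_cutoff=cutoff)


class TestSulpeak:
    def test_uniform_large_lesion(self):
        """For a uniform lesion much larger than 1 mL the peak mean equals
        the uniform value."""
        grid = ImageGrid(shape=(20, 20, 20), spacing=(2, 2, 2))
        values = np.zeros(grid.shape)
        values[4:16, 4:16, 4:16] = 4.0
        lesion = lesions_from(grid, values, cutoff=1.0)[0]
        assert sulpeak(sul_volume(grid, values), lesion) == pytest.approx(4.0)

    def test_single_hot_voxel_center_counting(self):
        """One voxel of 10 among zeros with spacing (3, 6, 6) mm: the 1 mL
        sphere (radius 6.2035 mm) covers exactly 9 voxel centres, so the
        peak mean is 10/9."""
        grid = ImageGrid(shape=(11, 11, 11), spacing=(3.0, 6.0, 6.0))
        values = np.zeros(grid.shape)
        values[5, 5, 5] = 10.0
        lesion = lesions_from(grid, values)[0]
        assert sulpeak(sul_volume(grid, values), lesion) == pytest.approx(10.0 / 9.0)

    def test_never_exceeds_suvmax(self):
        grid = ImageGrid(shape=(14, 14, 14), spacing=(2.6, 2.6, 3.0))
        rng = np.random.default_rng(11)
        values = np.where(rng.random(grid.shape) > 0.7, rng.uniform(4.1, 9, grid.shape), 0.0)
        for lesion in lesions_from(grid, values):
            assert sulpeak(sul_volume(grid, values), lesion) <= lesion.suv_max + 1e-12

    def test_degenerates_to_suvmax_for_tiny_sphere(self):
        grid = ImageGrid(shape=(8, 8, 8), spacing=(20, 20, 20))
        values = np.zeros(grid.shape)
        values[4, 4, 4] = 5.0
        lesion = lesions_from(grid, values)[0]
        with pytest.warns(UserWarning, match="degenerates"):
            assert sulpeak(sul_volume(grid, values), lesion) == pytest.approx(5.0)

    def test_monotone_under_voxelwise_increase(self):
        grid = ImageGrid(shape=(12, 12, 12), spacing=(2.6, 2.6, 3.0))
        values = np.zeros(grid.shape)
        values[4:8, 4:8, 4:8] = 5.0
        lesion = lesions_from(grid, values)[0]
        low = sulpeak(sul_volume(grid, values), lesion)
        high = sulpeak(sul_volume(grid, values + 0.5), lesion)
        assert high > low


class TestSelectTargets:
    def _toy_lesions(self, grid, hot):
        values = np.zeros(grid.shape)
        for (i, j, k), v in hot.items():
            values[i, j, k] = v
        return lesions_from(grid, values, cutoff=1.0)

    def test_top_two_by_metric(self):
        grid = ImageGrid(shape=(12, 12, 12), spacing=(2, 2, 2))
        hot = {(1, 1, 1): 2, (3, 3, 3): 5, (5, 5, 5): 3, (7, 7, 7): 5, (9, 9, 9): 1.5}
        lesions = self._toy_lesions(grid, hot)
        targets = select_targets(lesions, by="SUVmax")
        assert len(targets.lesions) == 2
        assert targets.metric_values == [5.0, 5.0]

    def test_single_and_empty_inputs(self):
        grid = ImageGrid(shape=(8, 8, 8), spacing=(2, 2, 2))
        lesions = self._toy_lesions(grid, {(2, 2, 2): 6})
        assert len(select_targets(lesions, by="SUVmax").lesions) == 1
        empty = select_targets([], by="SUVmax")
        assert empty.lesions == [] and empty.summed_value == 0.0

    def test_tie_break_stable_under_permutation(self):
        """Exact metric ties resolve by volume then lowest voxel index,
        identically for every input permutation of a 4-lesion toy."""
        grid = ImageGrid(shape=(14, 14, 14), spacing=(2, 2, 2))
        values = np.zeros(grid.shape)
        values[1, 1, 1] = 5.0                 # single voxel, metric 5
        values[4, 4, 4:6] = 5.0               # two voxels, metric 5 (bigger)
        values[8, 8, 8] = 5.0                 # single voxel, metric 5, later index
        values[11, 11, 11] = 2.0              # colder
        lesions = lesions_from(grid, values, cutoff=1.0)
        reference = select_targets(lesions, by="SUVmax")
        ref_ids = [l.min_flat_index for l in reference.lesions]
        # two-voxel lesion first (volume tie-break), then lowest index single
        assert ref_ids[0] == lesions[1].min_flat_index
        assert ref_ids[1] == lesions[0].min_flat_index
        for perm in itertools.permutations(lesions):
            got = select_targets(list(perm), by="SUVmax")
            assert [l.min_flat_index for l in got.lesions] == ref_ids

    def test_sulpeak_selection_needs_values(self):
        grid = ImageGrid(shape=(8, 8, 8), spacing=(2, 2, 2))
        lesions = self._toy_lesions(grid, {(2, 2, 2): 6})
        with pytest.raises(ValueError, match="SULpeak"):
            select_targets(lesions, by="SULpeak")
        got = select_targets(lesions, by="SULpeak", metric_values=[3.2])
        assert got.summed_value == pytest.approx(3.2)


class TestPercist:
    def test_pmr_requires_both_thresholds(self):
        out = percist_classify(5.0, 3.0, background=1.0)
        assert out.category == "PMR"
        assert out.percent_change == pytest.approx(-40.0)
        assert out.absolute_change == pytest.approx(-2.0)

    def test_pmd_on_increase(self):
        assert percist_classify(5.0, 7.0).category == "PMD"

    def test_percent_without_absolute_is_stable(self):
        """-35% but only -0.7 SUL units: both conditions are required."""
        assert percist_classify(2.0, 1.3).category == "SMD"

    def test_absolute_without_percent_is_stable(self):
        assert percist_classify(10.0, 8.0).category == "SMD"  # -20%, -2.0

    def test_new_lesion_always_pmd(self):
        assert percist_classify(5.0, 0.1, new_lesion=True, background=1.0).category == "PMD"

    def test_cmr_at_background(self):
        assert percist_classify(5.0, 0.8, background=1.0).category == "CMR"

    def test_zero_baseline_directs_to_eortc(self):
        with pytest.raises(ValueError, match="[Ee]ortc"):
            percist_classify(0.0, 3.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        b=st.floats(0.5, 20.0),
        f=st.floats(0.0, 40.0),
        k=st.floats(0.1, 10.0),
    )
    def test_percent_scale_invariance_absolute_not(self, b, f, k):
        """Scaling both time points preserves the percent change; the 0.8
        SUL clause is deliberately not scale-invariant."""
        a1 = percist_classify(b, f)
        a2 = percist_classify(k * b, k * f)
        assert a1.percent_change == pytest.approx(a2.percent_change, abs=1e-6)
        assert a2.absolute_change == pytest.approx(k * a1.absolute_change, rel=1e-9, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        b=st.floats(0.5, 20.0), f=st.floats(0.0, 40.0),
        new=st.booleans(), bg=st.floats(0.0, 2.0),
    )
    def test_exactly_one_category(self, b, f, new, bg):
        out = percist_classify(b, f, new_lesion=new, background=bg)
        assert out.category in {"CMR", "PMR", "SMD", "PMD"}


class TestEortc:
    def test_examples(self):
        assert eortc_classify(10.0, 7.0).category == "PMR"     # -30%
        assert eortc_classify(10.0, 13.0).category == "PMD"    # +30%
        assert eortc_classify(10.0, 0.0, all_resolved=True).category == "CMR"
        assert eortc_classify(10.0, 9.0).category == "SMD"
        assert eortc_classify(10.0, 2.0, new_lesion=True).category == "PMD"

    def test_uptake_appearing_from_zero_baseline(self):
        assert eortc_classify(0.0, 4.0).category == "PMD"
        assert eortc_classify(0.0, 0.0, all_resolved=True).category == "CMR"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(b=st.floats(0.5, 20.0), f=st.floats(0.0, 40.0), k=st.floats(0.1, 10.0))
    def test_scale_invariance(self, b, f, k):
        assert (
            eortc_classify(b, f).category == eortc_classify(k * b, k * f).category
        )


class TestTrajectory:
    @pytest.mark.parametrize(
        "series,label",
        [
            ([11.6, 0, 0], "favorable"),
            ([0, 0, 0, 0], "favorable"),
            ([2.8, 76.7, 532.5], "progressive"),
            ([254.7, 43.5, 107.1], "fluctuating"),
        ],
    )
    def test_published_examples(self, series, label):
        assert trajectory_classify(series).label == label

    def test_all_fifteen_published_series(self):
        for case, series in FOLLOWUP_SERIES.items():
            assert trajectory_classify(series).label == FOLLOWUP_GROUPS[case], case

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            trajectory_classify([5.0])

    def test_tolerance_ignores_small_moves(self):
        assert trajectory_classify([10, 10.4, 9.8], tolerance=0.5).label == "favorable"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1000), min_size=2, max_size=8))
    def test_exactly_one_label(self, series):
        assert trajectory_classify(series).label in {
            "favorable", "progressive", "fluctuating",
        }


class TestFollowupTable:
    def test_regimen_change_resets_baseline(self):
        table = pd.DataFrame(
            [
                # regimen A: baseline 5.0 then 3.0 -> PMR
                ("p1", "t0", "A", "SULpeak", "l1", 5.0, False),
                ("p1", "t1", "A", "SULpeak", "l1", 3.0, False),
                # regimen B: new baseline 4.0 then 6.0 -> PMD (+50%, +2.0)
                ("p1", "t2", "B", "SULpeak", "l2", 4.0, False),
                ("p1", "t3", "B", "SULpeak", "l2", 6.0, False),
            ],
            columns=[
                "patient", "study_time", "regimen", "metric_kind",
                "lesion_id", "value", "new_lesion",
            ],
        )
        out = classify_followup_table(table, background=1.0)
        intervals = out["p1"]["intervals"]
        assert intervals[0]["category"] == "PMR"
        assert intervals[1]["note"] == "baseline reset (regimen change)"
        assert intervals[2]["category"] == "PMD"

    def test_low_baseline_uses_eortc(self):
        table = pd.DataFrame(
            [
                ("p2", "t0", "A", "SUVmax", "l1", 10.0, False),
                ("p2", "t1", "A", "SUVmax", "l1", 7.0, False),
            ],
            columns=[
                "patient", "study_time", "regimen", "metric_kind",
                "lesion_id", "value", "new_lesion",
            ],
        )
        out = classify_followup_table(table)
        assert out["p2"]["intervals"][0]["criterion"] == "EORTC"
        assert out["p2"]["intervals"][0]["category"] == "PMR"

    def test_trajectory_from_wstlg_rows(self):
        rows = []
        for t, (sul, ws) in enumerate([(5.0, 254.7), (3.0, 43.5), (4.0, 107.1)]):
            rows.append(("p3", f"t{t}", "A", "SULpeak", "l1", sul, False))
            rows.append(("p3", f"t{t}", "A", "WSTLG", "", ws, False))
        table = pd.DataFrame(
            rows,
            columns=[
                "patient", "study_time", "regimen", "metric_kind",
                "lesion_id", "value", "new_lesion",
            ],
        )
        out = classify_followup_table(table)
        assert out["p3"]["trajectory"] == "fluctuating"
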
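"""Cycle matching, accuracy conventions and agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivusgate import (
    EvaluationConfig,
    ReferenceAnnotation,
    VesselEvaluation,
    bland_altman,
    build_results_table,
    chi_square_table,
    classify_correct_fixed,
    classify_correct_relative,
    compute_accuracy,
    match_estimates_to_cycles,
    rmse,
    table_percentages,
)


def ann(frames, fps=30.0):
    return ReferenceAnnotation(ed_frames=frames, fps=fps)


class TestMatching:
    def test_nearest_reference_assignment_with_extra_and_missed(self):
        match = match_estimates_to_cycles(ann([10, 40, 70]), ann([11, 41, 43]))
        assert [(m.ref_frame, m.est_frame) for m in match.matched] == [(10, 11), (40, 41)]
        assert match.extra == [43]
        assert match.missed == [70]

    def test_perfect_estimates_all_match_with_zero_diffs(self):
        match = match_estimates_to_cycles(ann([5, 30, 55]), ann([5, 30, 55]))
        assert match.counts == (3, 0, 0)
        assert np.all(match.diffs_ms == 0)

    def test_empty_estimates_miss_everything(self):
        match = match_estimates_to_cycles(ann([5, 30]), ann([]))
        assert match.counts == (0, 0, 2)

    def test_fps_mismatch_rejected(self):
        with pytest.raises(ValueError, match="fps"):
            match_estimates_to_cycles(ann([5], fps=30), ann([5], fps=15))

    def test_signed_differences_in_ms(self):
        match = match_estimates_to_cycles(ann([10]), ann([13]))
        assert match.matched[0].diff_frames == 3
        assert match.matched[0].diff_ms == pytest.approx(100.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_of_references_and_estimates(self, seed):
        rng = np.random.default_rng(seed)
        ref = np.unique(rng.integers(0, 300, size=rng.integers(1, 15)))
        est = np.unique(rng.integers(0, 300, size=rng.integers(0, 15)))
        match = match_estimates_to_cycles(ann(ref), ann(est))
        m, x, s = match.counts
        assert m + s == len(ref)
        assert m + x == len(est)


class TestCorrectness:
    def test_three_frames_at_30fps_is_exactly_100ms_and_correct(self):
        match = match_estimates_to_cycles(ann([50]), ann([53]))
        ok, n = classify_correct_fixed(match)
        assert n == 1 and ok[0]

    def test_four_frames_at_30fps_is_incorrect(self):
        match = match_estimates_to_cycles(ann([50]), ann([54]))
        _, n = classify_correct_fixed(match)
        assert n == 0

    def test_zero_difference_always_correct(self):
        match = match_estimates_to_cycles(ann([50]), ann([50]))
        _, n = classify_correct_fixed(match)
        assert n == 1

    def test_relative_tolerance_uses_local_rr(self):
        # 25-frame cycles at 30 fps: RR = 833.3 ms, tolerance 83.3 ms
        ref = ann([0, 25, 50])
        match = match_estimates_to_cycles(ref, ann([2, 25, 50]))  # diff 66.7 ms
        _, n = classify_correct_relative(match, ref)
        assert n == 3

    def test_relative_tolerance_shrinks_with_short_rr(self):
        # 18-frame cycles at 30 fps: RR = 600 ms, tolerance 60 ms,
        # so a 2-frame difference (66.7 ms) now fails
        ref = ann([0, 18, 36])
        match = match_estimates_to_cycles(ref, ann([2, 18, 36]))
        _, n = classify_correct_relative(match, ref)
        assert n == 2

    def test_relative_needs_two_references(self):
        match = match_estimates_to_cycles(ann([10]), ann([10]))
        with pytest.raises(ValueError, match="2 reference"):
            classify_correct_relative(match, ann([10]))


class TestAccuracyConventions:
    def test_printed_count_examples(self):
        """Accuracy recomputed from published matched/correct counts."""
        match = match_estimates_to_cycles(ann([0]), ann([0]))
        match.matched = [None] * 2987  # counts drive the arithmetic
        match.extra = []
        assert round(compute_accuracy(2401, match), 1) == 80.4
        match.matched = [None] * 3034
        assert round(compute_accuracy(1182, match), 1) == 39.0

    def test_zero_correct_gives_zero_percent(self):
        match = match_estimates_to_cycles(ann([5]), ann([5]))
        assert compute_accuracy(0, match) == 0.0

    def test_all_estimates_denominator_includes_extras(self):
        match = match_estimates_to_cycles(ann([10, 40]), ann([10, 40, 42]))
        assert compute_accuracy(2, match, "matched") == 100.0
        assert compute_accuracy(2, match, "all_estimates") == pytest.approx(200 / 3)

    def test_zero_denominator_rejected(self):
        match = match_estimates_to_cycles(ann([5]), ann([]))
        with pytest.raises(ValueError, match="denominator"):
            compute_accuracy(0, match)


class TestTablePercentages:
    @pytest.mark.parametrize(
        "counts,expected",
        [((3034, 110, 133), (92.6, 3.4, 4.1)),
         ((2987, 95, 180), (91.6, 2.9, 5.5)),
         ((10, 0, 0), (100.0, 0.0, 0.0))],
    )
    def test_published_row_conventions(self, counts, expected):
        match = match_estimates_to_cycles(ann([0]), ann([0]))
        match.matched = [None] * counts[0]
        match.extra = [0] * counts[1]
        match.missed = [0] * counts[2]
        assert table_percentages(match) == expected

    def test_rows_sum_to_about_100(self, rng):
        for _ in range(20):
            m, x, s = rng.integers(1, 500, size=3)
            match = match_estimates_to_cycles(ann([0]), ann([0]))
            match.matched = [None] * int(m)
            match.extra = [0] * int(x)
            match.missed = [0] * int(s)
            # three independently rounded values can each be off by 0.05
            assert sum(table_percentages(match)) == pytest.approx(100.0, abs=0.15)


class TestAgreementStats:
    def test_zero_differences(self):
        stats = bland_altman([0.0, 0.0, 0.0])
        assert stats.mean_diff_ms == 0 and stats.sd_ms == 0
        assert stats.loa_low_ms == 0 and stats.loa_high_ms == 0

    def test_symmetric_pair(self):
        stats = bland_altman([-33.3, 33.3])
        assert stats.mean_diff_ms == pytest.approx(0.0)
        assert stats.sd_ms == pytest.approx(33.3 * np.sqrt(2), rel=1e-6)
        assert stats.loa_high_ms == pytest.approx(1.96 * 33.3 * np.sqrt(2), rel=1e-6)

    def test_translation_shifts_mean_and_loa_not_sd(self, rng):
        d = rng.normal(size=30)
        base = bland_altman(d)
        shifted = bland_altman(d + 50.0)
        assert shifted.mean_diff_ms == pytest.approx(base.mean_diff_ms + 50)
        assert shifted.sd_ms == pytest.approx(base.sd_ms)
        assert shifted.loa_low_ms == pytest.approx(base.loa_low_ms + 50)

    def test_rmse_examples_and_jensen_bound(self, rng):
        assert rmse([0.0, 0.0]) == 0.0
        assert rmse([100.0, -133.33]) == pytest.approx(117.85, abs=0.01)
        d = rng.normal(size=50)
        assert rmse(d) >= abs(d.mean())

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0])
        with pytest.raises(ValueError):
            rmse([])


class TestChiSquare:
    def test_identical_rows_give_zero_statistic(self):
        stat, dof, p = chi_square_table([[10, 20, 30], [10, 20, 30]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_two_by_two(self):
        stat, dof, _ = chi_square_table([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_dof_for_5x3_table(self, rng):
        table = rng.integers(1, 50, size=(5, 3))
        _, dof, _ = chi_square_table(table)
        assert dof == 8

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            chi_square_table([[0, 0], [1, 2]])


class TestResultsTable:
    def _vessel(self, vid, vtype, ref, est):
        match = match_estimates_to_cycles(ann(ref), ann(est))
        _, correct = classify_correct_fixed(match)
        return VesselEvaluation(vessel_id=vid, vessel_type=vtype, match=match,
                                correct_fixed=correct)

    def test_single_vessel_row_matches_own_stats(self):
        ev = self._vessel("v1", "LAD", [10, 40, 70], [11, 41, 43])
        table = build_results_table([ev])
        row = table[table.group == "all"].iloc[0]
        assert (row.matched, row.extra, row.missed) == (2, 1, 1)
        assert row.accuracy_matched_pct == pytest.approx(100.0)

    def test_overall_counts_sum_per_type(self):
        evs = [
            self._vessel("a", "LAD", [10, 40], [10, 40]),
            self._vessel("b", "RCA", [20, 50, 80], [20, 50]),
        ]
        table = build_results_table(evs)
        overall = table[table.group == "all"].iloc[0]
        assert overall.matched == 4
        assert overall.missed == 1
        assert set(table.group) == {"all", "LAD", "RCA"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_results_table([])
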
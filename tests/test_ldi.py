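"""Lost Data Index: slot classification, blink exemption, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeldi.ldi import (
    SampleStatus,
    TaskLDI,
    disruption_time,
    grid_statuses,
    repetition_ldis,
    score_recording,
    task_ldi,
    weighted_ldi,
)

from conftest import brute_force_ldi, make_window, random_recording, rec_from_statuses


def ldi_of(statuses: str, duration: float | None = None, **kw) -> TaskLDI:
    dur = duration if duration is not None else len(statuses) / 60.0
    return task_ldi(rec_from_statuses(statuses, **kw), make_window(dur))


class TestGridStatuses:
    def test_fully_valid_window(self):
        rec = rec_from_statuses("o" * 30)
        statuses = grid_statuses(rec, make_window(0.5))
        assert (statuses == SampleStatus.VALID_ON_SCREEN).all()

    def test_100ms_flanked_gap_is_excused(self):
        # 6 slots at 60 Hz = 100 ms < 150 ms, valid on-screen on both sides
        rec = rec_from_statuses("oooo" + "m" * 6 + "oooo")
        statuses = grid_statuses(rec, make_window(14 / 60.0))
        assert (statuses[4:10] == SampleStatus.EXCUSED_BLINK).all()

    def test_200ms_gap_is_lost(self):
        # 12 slots = 200 ms >= 150 ms, not exempt despite flanking
        rec = rec_from_statuses("oooo" + "m" * 12 + "oooo")
        statuses = grid_statuses(rec, make_window(20 / 60.0))
        assert (statuses[4:16] == SampleStatus.LOST).all()

    def test_gap_touching_window_boundary_is_not_excused(self):
        rec = rec_from_statuses("mmm" + "o" * 9)
        statuses = grid_statuses(rec, make_window(0.2))
        assert (statuses[:3] == SampleStatus.LOST).all()

    def test_missing_rows_and_invalid_rows_are_equivalent(self):
        with_rows = rec_from_statuses("oo" + "m" * 4 + "oo")
        without = rec_from_statuses("oo" + "m" * 4 + "oo", drop_missing_rows=True)
        w = make_window(8 / 60.0)
        np.testing.assert_array_equal(
            grid_statuses(with_rows, w), grid_statuses(without, w)
        )

    def test_off_screen_runs_are_never_excused(self):
        rec = rec_from_statuses("oooo" + "X" * 3 + "oooo")
        statuses = grid_statuses(rec, make_window(11 / 60.0))
        assert (statuses[4:7] == SampleStatus.OFF_SCREEN).all()

    def test_off_screen_slot_breaks_the_blink_flank(self):
        # gap flanked by an off-screen slot on one side: no blink evidence
        rec = rec_from_statuses("oooX" + "m" * 4 + "oooo")
        statuses = grid_statuses(rec, make_window(12 / 60.0))
        assert (statuses[4:8] == SampleStatus.LOST).all()


class TestTaskLDI:
    def test_absent_task_scores_one(self):
        t = task_ldi(None, make_window(10.0))
        assert t.ldi == 1.0 and t.absent

    def test_interrupted_before_window_scores_one(self):
        rec = rec_from_statuses("o" * 60, interruption_t=1000.0)
        t = task_ldi(rec, make_window(1.0, start=2.0))
        assert t.ldi == 1.0 and t.absent

    def test_two_seconds_lost_of_ten(self):
        # 600-slot window, 120 consecutive lost slots -> LDI 0.2
        rec = rec_from_statuses("o" * 240 + "m" * 120 + "o" * 240)
        t = task_ldi(rec, make_window(10.0))
        assert t.ldi == pytest.approx(0.2)
        assert t.n_total == 600 and t.n_lost == 120

    def test_single_flanked_blink_gap_gives_zero(self):
        rec = rec_from_statuses("o" * 297 + "m" * 6 + "o" * 297)
        t = task_ldi(rec, make_window(10.0))
        assert t.ldi == 0.0 and t.n_excused == 6

    def test_excused_slots_stay_in_the_denominator(self):
        t = ldi_of("o" * 100 + "m" * 6 + "o" * 94 + "X" * 100, duration=5.0)
        assert t.n_total == 300
        assert t.ldi == pytest.approx(100 / 300)

    def test_zero_duration_window_rejected(self):
        import dataclasses

        rec = rec_from_statuses("oo")
        bad = dataclasses.replace(make_window(1.0), duration=0.0)
        with pytest.raises(ValueError):
            task_ldi(rec, bad)

    def test_window_past_recording_end_joins_final_gap(self):
        rec = rec_from_statuses("o" * 30)  # recording covers 0.5 s
        t = task_ldi(rec, make_window(1.0))
        assert t.ldi == pytest.approx(0.5)


class TestBruteForceOracle:
    def test_matches_on_random_small_recordings(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(10, 400))
            rec = random_recording(rng, n)
            w = make_window(n / 60.0)
            assert task_ldi(rec, w).ldi == pytest.approx(brute_force_ldi(rec, w))

    def test_matches_with_offset_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(30, 300))
            rec = random_recording(rng, n, start=3.7)
            w = make_window(n / 60.0, start=3.7)
            assert task_ldi(rec, w).ldi == pytest.approx(brute_force_ldi(rec, w))


@st.composite
def status_strings(draw):
    return draw(st.text(alphabet="oXm.", min_size=12, max_size=240))


class TestProperties:
    @given(statuses=status_strings())
    @settings(max_examples=150, deadline=None)
    def test_ldi_is_bounded_and_matches_oracle(self, statuses):
        rec = rec_from_statuses(statuses)
        w = make_window(len(statuses) / 60.0)
        t = task_ldi(rec, w)
        assert 0.0 <= t.ldi <= 1.0
        assert t.ldi == pytest.approx(brute_force_ldi(rec, w))

    @given(
        statuses=status_strings(),
        gap_start=st.integers(1, 200),
        gap_len=st.integers(1, 8),
    )
    @settings(max_examples=150, deadline=None)
    def test_blink_insertion_invariance(self, statuses, gap_start, gap_len):
        """Replacing an interior run of on-screen slots (< 150 ms) with a gap
        flanked by on-screen slots never changes the LDI."""
        chars = list(statuses)
        n = len(chars)
        lo, hi = gap_start, gap_start + gap_len
        if hi + 1 >= n:
            return
        if any(c != "o" for c in chars[lo - 1 : hi + 1]):
            return  # need on-screen run including both flanks
        w = make_window(n / 60.0)
        before = task_ldi(rec_from_statuses(statuses), w).ldi
        chars[lo:hi] = "m" * (hi - lo)
        after = task_ldi(rec_from_statuses("".join(chars)), w).ldi
        assert after == pytest.approx(before)

    @given(statuses=status_strings(), pos=st.integers(0, 239))
    @settings(max_examples=100, deadline=None)
    def test_losing_a_slot_never_decreases_ldi(self, statuses, pos):
        if pos >= len(statuses) or statuses[pos] != "o":
            return
        w = make_window(len(statuses) / 60.0)
        before = task_ldi(rec_from_statuses(statuses), w).ldi
        mutated = statuses[:pos] + "X" + statuses[pos + 1 :]
        after = task_ldi(rec_from_statuses(mutated), w).ldi
        assert after >= before - 1e-12

    def test_ldi_invariant_under_time_rescaling(self):
        statuses = "o" * 40 + "X" * 10 + "m" * 20 + "o" * 50
        w60 = make_window(len(statuses) / 60.0)
        rec60 = rec_from_statuses(statuses, rate=60.0)
        rec30 = rec_from_statuses(statuses, rate=30.0)
        w30 = make_window(len(statuses) / 30.0)
        assert task_ldi(rec60, w60).ldi == pytest.approx(task_ldi(rec30, w30).ldi)


class TestAggregation:
    def test_equal_durations_average_plainly(self):
        tasks = [
            TaskLDI(make_window(10.0), 0.1, 600, 60, 0),
            TaskLDI(make_window(10.0, start=10.0), 0.3, 600, 180, 0),
        ]
        assert weighted_ldi(tasks) == pytest.approx(0.2)

    def test_duration_weighting(self):
        tasks = [
            TaskLDI(make_window(37.0), 0.0, 2220, 0, 0),
            TaskLDI(make_window(8.0, start=37.0), 1.0, 480, 480, 0),
        ]
        assert weighted_ldi(tasks) == pytest.approx(8 / 45)

    def test_constant_input_is_a_fixed_point(self):
        tasks = [
            TaskLDI(make_window(d, start=s), 0.37, int(d * 60), 0, 0)
            for d, s in [(9.0, 0.0), (11.6, 9.0), (6.5, 20.6)]
        ]
        assert weighted_ldi(tasks) == pytest.approx(0.37)

    def test_weighted_mean_lies_within_input_range(self):
        rng = np.random.default_rng(3)
        ldis = rng.uniform(0, 1, size=12)
        tasks = [
            TaskLDI(make_window(float(d)), float(l), 1, 0, 0)
            for l, d in zip(ldis, rng.uniform(5, 40, size=12))
        ]
        m = weighted_ldi(tasks)
        assert ldis.min() - 1e-12 <= m <= ldis.max() + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_ldi([])

    def test_whole_test_equals_weighted_mean_of_repetitions(
        self, standard_schedule
    ):
        rng = np.random.default_rng(11)
        tasks = [
            TaskLDI(w, float(rng.uniform()), int(w.duration * 60), 0, 0)
            for w in standard_schedule
        ]
        whole = weighted_ldi(tasks)
        reps = repetition_ldis(tasks)
        rep_dur = {
            k: sum(w.duration for w in standard_schedule if w.repetition == k)
            for k in (1, 2, 3, 4)
        }
        recombined = sum(r.ldi * rep_dur[r.repetition] for r in reps) / sum(
            rep_dur.values()
        )
        assert whole == pytest.approx(recombined)


class TestDisruptionTime:
    def test_scales_ldi_by_duration(self):
        assert disruption_time(
            TaskLDI(make_window(10.0), 0.2, 600, 120, 0)
        ) == pytest.approx(2.0)

    def test_zero_and_absent_extremes(self):
        assert disruption_time(TaskLDI(make_window(9.0), 0.0, 540, 0, 0)) == 0.0
        absent = task_ldi(None, make_window(37.0))
        assert disruption_time(absent) == pytest.approx(37.0)
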
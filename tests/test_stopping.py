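"""Dynamic stopping rule: admissibility, schedule walk, threshold sweep."""

import numpy as np
import pytest

from gazeldi.ldi import TaskLDI
from gazeldi.stopping import (
    StoppingConfig,
    cohort_summary,
    compare_durations,
    default_tau_grid,
    is_admissible,
    repetitions_required,
    simulate_stopping,
    sweep_thresholds,
)


def tasks_from_ldis(schedule, ldis):
    return [
        TaskLDI(w, float(l), int(w.duration * 60), 0, 0)
        for w, l in zip(schedule, ldis)
    ]


@pytest.fixture()
def cartoon(cartoon_schedule):
    return cartoon_schedule


class TestIsAdmissible:
    @pytest.mark.parametrize(
        "ldi, tau, expected",
        [(0.2, 0.2, True), (0.0, 0.0, True), (1.0, 0.99, False), (0.1, 0.2, True)],
    )
    def test_inclusive_comparison(self, ldi, tau, expected):
        assert is_admissible(ldi, tau) is expected

    def test_strict_variant(self):
        assert not is_admissible(0.2, 0.2, comparison="lt")
        assert is_admissible(0.19, 0.2, comparison="lt")


class TestSimulateStopping:
    def test_perfect_first_repetition_stops_after_twelve_tasks(self, cartoon):
        tasks = tasks_from_ldis(cartoon, [0.0] * 48)
        res = simulate_stopping(tasks, cartoon, StoppingConfig(tau=0.2))
        assert res.complete
        assert res.n_tasks_presented == 12
        assert res.duration == pytest.approx(157.0)
        assert res.repetitions_used == 1

    def test_nothing_admissible_runs_the_whole_test(self, cartoon):
        tasks = tasks_from_ldis(cartoon, [0.5] * 48)
        res = simulate_stopping(tasks, cartoon, StoppingConfig(tau=0.0))
        assert not res.complete
        assert res.duration == pytest.approx(628.0)
        assert res.n_tasks_presented == 48

    def test_one_slot_recovered_in_second_repetition(self, cartoon):
        # slot 1 fails in repetition 1 but passes in repetition 2: the walk
        # must continue into repetition 2 exactly until that task ends
        ldis = [0.0] * 48
        ldis[0] = 0.9
        tasks = tasks_from_ldis(cartoon, ldis)
        res = simulate_stopping(tasks, cartoon, StoppingConfig(tau=0.2))
        assert res.complete
        slot1_dur = cartoon[12].duration
        assert res.duration == pytest.approx(157.0 + slot1_dur)
        assert res.n_tasks_presented == 13
        assert res.repetitions_used == 2

    def test_lower_m_stops_earlier(self, cartoon):
        tasks = tasks_from_ldis(cartoon, [0.0] * 48)
        res = simulate_stopping(tasks, cartoon, StoppingConfig(tau=0.2, m_required=3))
        assert res.n_tasks_presented == 3
        assert res.duration == pytest.approx(sum(w.duration for w in cartoon[:3]))

    def test_misaligned_inputs_rejected(self, cartoon, standard_schedule):
        tasks = tasks_from_ldis(cartoon, [0.0] * 48)
        with pytest.raises(ValueError):
            simulate_stopping(tasks[:40], cartoon, StoppingConfig(tau=0.2))
        with pytest.raises(ValueError):
            simulate_stopping(tasks, standard_schedule, StoppingConfig(tau=0.2))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StoppingConfig(tau=1.2)
        with pytest.raises(ValueError):
            StoppingConfig(tau=0.2, m_required=13)


class TestSweepThresholds:
    def test_perfect_participant_gives_constant_curve(self, cartoon):
        tasks = tasks_from_ldis(cartoon, [0.0] * 48)
        curve = sweep_thresholds(tasks, cartoon)
        assert all(d == pytest.approx(157.0) for d in curve.durations)

    def test_rectangle_auc(self, cartoon):
        tasks = tasks_from_ldis(cartoon, [0.0] * 48)
        curve = sweep_thresholds(tasks, cartoon, taus=[0.0, 0.25])
        assert curve.auc == pytest.approx(0.25 * 157.0)

    def test_step_at_a_task_ldi(self, cartoon):
        ldis = [0.0] * 48
        ldis[0] = 0.15  # slot 1 inadmissible below tau=0.15, admissible at it
        tasks = tasks_from_ldis(cartoon, ldis)
        curve = sweep_thresholds(tasks, cartoon, taus=[0.10, 0.20])
        lo = simulate_stopping(tasks, cartoon, StoppingConfig(tau=0.10)).duration
        hi = simulate_stopping(tasks, cartoon, StoppingConfig(tau=0.20)).duration
        assert curve.durations == (pytest.approx(lo), pytest.approx(hi))
        assert lo > hi

    def test_durations_non_increasing_in_tau(self, cartoon):
        rng = np.random.default_rng(0)
        for _ in range(10):
            tasks = tasks_from_ldis(cartoon, rng.uniform(0, 1, size=48))
            curve = sweep_thresholds(tasks, cartoon, taus=default_tau_grid(0.05, 1.0))
            assert all(
                d2 <= d1 + 1e-9
                for d1, d2 in zip(curve.durations, curve.durations[1:])
            )

    def test_duration_non_decreasing_in_m(self, cartoon):
        rng = np.random.default_rng(1)
        for _ in range(10):
            tasks = tasks_from_ldis(cartoon, rng.uniform(0, 0.6, size=48))
            durs = [
                simulate_stopping(
                    tasks, cartoon, StoppingConfig(tau=0.3, m_required=m)
                ).duration
                for m in range(1, 13)
            ]
            assert all(b >= a - 1e-9 for a, b in zip(durs, durs[1:]))

    def test_tau_one_with_no_absent_tasks_completes_in_first_repetition(
        self, cartoon
    ):
        rng = np.random.default_rng(2)
        tasks = tasks_from_ldis(cartoon, rng.uniform(0, 1, size=48))
        res = simulate_stopping(tasks, cartoon, StoppingConfig(tau=1.0))
        assert res.complete and res.repetitions_used == 1

    def test_auc_bounded_by_rectangle_of_extreme_curves(self, cartoon):
        rng = np.random.default_rng(3)
        taus = default_tau_grid()
        span = taus[-1] - taus[0]
        tasks = tasks_from_ldis(cartoon, rng.uniform(0, 1, size=48))
        curve = sweep_thresholds(tasks, cartoon, taus=taus)
        assert 157.0 * span - 1e-9 <= curve.auc <= 628.0 * span + 1e-9

    def test_invalid_grids_rejected(self, cartoon):
        tasks = tasks_from_ldis(cartoon, [0.0] * 48)
        with pytest.raises(ValueError):
            sweep_thresholds(tasks, cartoon, taus=[])
        with pytest.raises(ValueError):
            sweep_thresholds(tasks, cartoon, taus=[0.2, 0.1])


class TestRepetitionsRequired:
    def test_all_admissible_needs_one(self, cartoon):
        tasks = tasks_from_ldis(cartoon, [0.0] * 48)
        assert repetitions_required(tasks, cartoon, StoppingConfig(tau=0.2)) == 1

    def test_slot_satisfied_only_in_third_repetition(self, cartoon):
        ldis = [0.0] * 48
        ldis[0] = ldis[12] = 0.9  # slot 1 fails in repetitions 1 and 2
        tasks = tasks_from_ldis(cartoon, ldis)
        assert repetitions_required(tasks, cartoon, StoppingConfig(tau=0.2)) == 3

    def test_never_satisfied_slot_marks_incomplete(self, cartoon):
        ldis = [0.0] * 48
        for i in (0, 12, 24, 36):
            ldis[i] = 0.9
        tasks = tasks_from_ldis(cartoon, ldis)
        assert repetitions_required(tasks, cartoon, StoppingConfig(tau=0.2)) is None


class TestCohortSummary:
    def test_matches_independent_recount(self, cartoon, standard_schedule):
        rng = np.random.default_rng(4)
        results = {"standard": [], "cartoon": []}
        raw = {"standard": [], "cartoon": []}
        scheds = {"standard": standard_schedule, "cartoon": cartoon}
        for variant, sched in scheds.items():
            for _ in range(10):
                tasks = tasks_from_ldis(sched, rng.uniform(0, 0.5, size=48))
                res = simulate_stopping(tasks, sched, StoppingConfig(tau=0.2))
                results[variant].append(res)
                raw[variant].append(res)
        df = cohort_summary(results, tau=0.2).set_index("variant")
        for variant in scheds:
            rs = raw[variant]
            assert df.loc[variant, "n_incomplete"] == sum(
                not r.complete for r in rs
            )
            assert df.loc[variant, "mean_duration"] == pytest.approx(
                np.mean([r.duration for r in rs])
            )
            assert df.loc[variant, "n_reps_1"] == sum(
                r.complete and r.repetitions_used == 1 for r in rs
            )

    def test_perfect_cohort_has_zero_incomplete(self, cartoon):
        tasks = tasks_from_ldis(cartoon, [0.0] * 48)
        res = simulate_stopping(tasks, cartoon, StoppingConfig(tau=0.0))
        df = cohort_summary({"cartoon": [res] * 5}, tau=0.0)
        assert df.frac_incomplete.iloc[0] == 0.0

    def test_forced_incomplete_cohort(self, cartoon):
        ldis = [0.0] * 48
        for i in (4, 16, 28, 40):  # the same slot fails in all repetitions
            ldis[i] = 1.0
        tasks = tasks_from_ldis(cartoon, ldis)
        res = simulate_stopping(tasks, cartoon, StoppingConfig(tau=0.5))
        df = cohort_summary({"cartoon": [res] * 4}, tau=0.5)
        assert df.frac_incomplete.iloc[0] == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary({"cartoon": []}, tau=0.2)


class TestCompareDurations:
    def test_alternative_is_cartoon_longer(self):
        res = compare_durations([100, 110, 120], [400, 410, 420])
        assert res.alternative == "greater"
        assert res.p == pytest.approx(0.05)
        assert res.alpha == pytest.approx(0.10)
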
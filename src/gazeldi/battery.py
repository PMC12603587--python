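"""Fixed task-battery timelines for the two test variants.

Both the standard and the gamified ("cartoon") test battery present the
same 12 tasks — four smooth-pursuit variants (two axes x two oscillation
periods), six visual-memory variants (two paradigms x three stimulus
modalities), one cued-attention task and one social-orienting task — and
repeat the block four times, for 48 tasks in total. The two variants share
the slot order; only the per-type durations differ (the cartoon tasks are
uniformly longer because of animations and transitions).

Per-task durations (seconds):

================  ========  =======
task type         standard  cartoon
================  ========  =======
smooth pursuit         9.0     10.0
memory                 9.0     12.0
attention             11.6     37.0
social                 6.5      8.0
================  ========  =======

which gives repetition lengths of 108.1 s (standard) and 157.0 s (cartoon)
and total lengths of 432.4 s and 628.0 s.

The exact within-repetition slot order is configurable; the default
alternates the dynamic tasks (pursuit, attention, social) with the
scene-exploration memory tasks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "TaskSpec",
    "TaskWindow",
    "BatterySchedule",
    "build_schedule",
    "repetition_start",
    "total_duration",
    "window_for_time",
    "DEFAULT_SLOT_ORDER",
    "TASK_TYPES",
    "TYPE_DURATIONS",
    "VARIANTS",
]

VARIANTS = ("standard", "cartoon")

#: task name -> task type for the 12 per-repetition tasks
TASK_TYPES: Mapping[str, str] = {
    "sp_h_1600": "smooth_pursuit",
    "sp_h_2400": "smooth_pursuit",
    "sp_v_1600": "smooth_pursuit",
    "sp_v_2400": "smooth_pursuit",
    "mem_col_a": "memory",
    "mem_col_b": "memory",
    "mem_sha_a": "memory",
    "mem_sha_b": "memory",
    "mem_fac_a": "memory",
    "mem_fac_b": "memory",
    "att": "attention",
    "soc": "social",
}

#: smooth-pursuit oscillation periods, ms (0.625 Hz and ~0.4 Hz)
_SP_PERIODS: Mapping[str, int] = {
    "sp_h_1600": 1600,
    "sp_v_1600": 1600,
    "sp_h_2400": 2400,
    "sp_v_2400": 2400,
}

#: per-type task durations in seconds for each variant
TYPE_DURATIONS: Mapping[str, Mapping[str, float]] = {
    "standard": {
        "smooth_pursuit": 9.0,
        "memory": 9.0,
        "attention": 11.6,
        "social": 6.5,
    },
    "cartoon": {
        "smooth_pursuit": 10.0,
        "memory": 12.0,
        "attention": 37.0,
        "social": 8.0,
    },
}

#: Default within-repetition slot order: dynamic tasks alternated with the
#: memory (scene-exploration) tasks.
DEFAULT_SLOT_ORDER: tuple[str, ...] = (
    "sp_h_1600",
    "mem_col_a",
    "sp_v_1600",
    "mem_col_b",
    "att",
    "mem_sha_a",
    "sp_h_2400",
    "mem_sha_b",
    "soc",
    "mem_fac_a",
    "sp_v_2400",
    "mem_fac_b",
)

N_REPETITIONS = 4
N_SLOTS = 12


@dataclass(frozen=True)
class TaskSpec:
    """Static description of one of the 12 per-repetition tasks.

    ``phases`` carries task-internal phase boundaries (e.g. initial
    fixation length) as metadata for generators and future outcome
    analyses; the data-quality pipeline itself only uses ``duration``.
    """

    name: str
    ttype: str
    duration: float
    period_ms: int | None = None
    phases: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"task duration must be positive, got {self.duration}")
        if (self.ttype == "smooth_pursuit") != (self.period_ms is not None):
            raise ValueError(
                "period_ms must be present iff the task is a smooth pursuit"
            )

    @property
    def frequency_hz(self) -> float | None:
        """Oscillation frequency of a smooth-pursuit task (1000 / period_ms)."""
        return None if self.period_ms is None else 1000.0 / self.period_ms


@dataclass(frozen=True)
class TaskWindow:
    """One task's time interval within the 48-task timeline.

    Windows are half-open ``[start, start + duration)`` so every in-range
    time maps to exactly one window.
    """

    index: int
    repetition: int
    slot: int
    spec: TaskSpec
    start: float
    duration: float

    @property
    def end(self) -> float:
        return self.start + self.duration


class BatterySchedule:
    """The fixed 48-task timeline (4 repetitions x 12 slots) of one variant."""

    def __init__(self, variant: str, windows: Sequence[TaskWindow]) -> None:
        if len(windows) != N_REPETITIONS * N_SLOTS:
            raise ValueError(f"expected 48 windows, got {len(windows)}")
        self.variant = variant
        self.windows = tuple(windows)
        self._starts = [w.start for w in self.windows]

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> TaskWindow:
        return self.windows[i]

    @property
    def slot_order(self) -> tuple[str, ...]:
        return tuple(w.spec.name for w in self.windows[:N_SLOTS])

    def repetition_start(self, k: int) -> float:
        if not 1 <= k <= N_REPETITIONS:
            raise ValueError(f"repetition must be in 1..{N_REPETITIONS}, got {k}")
        return self.windows[(k - 1) * N_SLOTS].start

    def total_duration(self) -> float:
        last = self.windows[-1]
        return last.start + last.duration

    def window_for_time(self, t: float) -> TaskWindow | None:
        if t < 0:
            raise ValueError(f"time must be >= 0, got {t}")
        if t >= self.total_duration():
            return None
        import bisect

        i = bisect.bisect_right(self._starts, t) - 1
        return self.windows[i]


def _task_spec(name: str, variant: str) -> TaskSpec:
    ttype = TASK_TYPES[name]
    duration = TYPE_DURATIONS[variant][ttype]
    phases = {"fixation": 1.5} if ttype in ("smooth_pursuit", "memory") else None
    return TaskSpec(
        name=name,
        ttype=ttype,
        duration=duration,
        period_ms=_SP_PERIODS.get(name),
        phases=phases,
    )


def build_schedule(
    variant: str,
    order: Sequence[str] | None = None,
    durations: Mapping[str, float] | None = None,
) -> BatterySchedule:
    """Build the 48-window timeline for one test variant.

    Parameters
    ----------
    variant
        ``"standard"`` or ``"cartoon"``.
    order
        Optional permutation of the 12 task names used as the slot order
        in every repetition; defaults to :data:`DEFAULT_SLOT_ORDER`.
    durations
        Optional per-type duration override (seconds), e.g. to analyse an
        alternative battery.

    Raises
    ------
    ValueError
        Unknown variant, or ``order`` not a permutation of the 12 names.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    slot_order = tuple(order) if order is not None else DEFAULT_SLOT_ORDER
    if sorted(slot_order) != sorted(TASK_TYPES):
        raise ValueError(
            "order must be a permutation of the 12 task names "
            f"{sorted(TASK_TYPES)}, got {list(slot_order)}"
        )
    dur_map = dict(TYPE_DURATIONS[variant])
    if durations:
        dur_map.update(durations)

    windows: list[TaskWindow] = []
    # accumulate starts in integer milliseconds to avoid float drift
    start_ms = 0
    idx = 0
    for rep in range(1, N_REPETITIONS + 1):
        for slot, name in enumerate(slot_order, start=1):
            spec = _task_spec(name, variant)
            dur = dur_map[spec.ttype]
            spec = TaskSpec(spec.name, spec.ttype, dur, spec.period_ms, spec.phases)
            windows.append(
                TaskWindow(
                    index=idx,
                    repetition=rep,
                    slot=slot,
                    spec=spec,
                    start=start_ms / 1000.0,
                    duration=dur,
                )
            )
            start_ms += round(dur * 1000)
            idx += 1
    return BatterySchedule(variant, windows)


def repetition_start(schedule: BatterySchedule, k: int) -> float:
    """Start time (seconds) of repetition ``k`` in 1..4."""
    return schedule.repetition_start(k)


def total_duration(schedule: BatterySchedule) -> float:
    """Total test length in seconds (sum of the 48 window durations)."""
    return schedule.total_duration()


def window_for_time(schedule: BatterySchedule, t: float) -> TaskWindow | None:
    """The task window containing time ``t`` (seconds), or None past the end."""
    return schedule.window_for_time(t)
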
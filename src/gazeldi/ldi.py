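"""The Lost Data Index (LDI): a per-task gaze data-quality/engagement metric.

The LDI of a task is the fraction of its nominal sample slots whose gaze
point is either missing or off-screen:

    LDI = (n_missing + n_off_screen) / n_total

Short interior gaps of missing samples (< 150 ms by default) that are
flanked by valid on-screen data are attributed to blinks — an unavoidable
loss that can be imputed downstream — and are *not* counted as lost. Gaps
touching a task boundary and off-screen excursions of any length are never
exempted. A task with no recording at all (e.g. the test was interrupted
before it started) gets LDI = 1.

LDI derives from the classical *robustness* data-quality metric (fraction
of non-missing samples) but additionally counts detected-but-unusable
gaze (outside the screen) and forgives blinks, which makes it less a
device property and more a measure of the avoidable disruption caused by
the participant — an indirect index of engagement.

Slots are laid on the task's nominal-rate grid (``n_total = round(duration
x rate)``), so stretches where the device delivered no rows at all remain
countable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .battery import BatterySchedule, TaskWindow
from .io import GazeRecording

__all__ = [
    "SampleStatus",
    "TaskLDI",
    "RepetitionLDI",
    "grid_statuses",
    "task_ldi",
    "score_recording",
    "weighted_ldi",
    "repetition_ldis",
    "disruption_time",
    "ldi_table",
]


class SampleStatus(enum.IntEnum):
    """Classification of one nominal-grid sample slot within a task window."""

    VALID_ON_SCREEN = 0
    OFF_SCREEN = 1
    LOST = 2
    EXCUSED_BLINK = 3


@dataclass(frozen=True)
class TaskLDI:
    """Per-task Lost Data Index with its sample bookkeeping.

    ``n_lost`` counts every slot in the LDI numerator (missing-and-not-
    excused plus off-screen); ``n_off_screen`` is the off-screen part of
    it. ``n_excused`` slots were part of exempted blink gaps and count as
    retained. ``absent`` marks tasks for which no recording exists; their
    LDI is 1 by convention.
    """

    window: TaskWindow
    ldi: float
    n_total: int
    n_lost: int
    n_excused: int
    n_off_screen: int = 0
    absent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.ldi <= 1.0:
            raise ValueError(f"LDI must lie in [0, 1], got {self.ldi}")

    @property
    def duration(self) -> float:
        return self.window.duration


@dataclass(frozen=True)
class RepetitionLDI:
    """Duration-weighted mean LDI over the 12 tasks of one repetition."""

    repetition: int
    ldi: float


def grid_statuses(
    rec: GazeRecording,
    window: TaskWindow,
    blink_max_ms: float = 150.0,
) -> np.ndarray:
    """Classify every nominal-grid slot of a task window.

    The window is discretised into ``round(duration x rate)`` slots. A slot
    containing at least one valid on-screen sample is VALID_ON_SCREEN; one
    with valid but only off-screen samples is OFF_SCREEN; slots with no
    valid sample form gaps. A maximal gap run is relabelled EXCUSED_BLINK
    iff it is strictly shorter than ``blink_max_ms`` *and* flanked on both
    sides, inside the same window, by VALID_ON_SCREEN slots. Off-screen
    slots are never exempted.

    The window may extend past the end of the recording (or past its
    interruption time): the missing slots simply join the final gap.
    """
    if blink_max_ms <= 0:
        raise ValueError(f"blink_max_ms must be positive, got {blink_max_ms}")
    rate = rec.rate
    if rate <= 0:
        raise ValueError(f"sampling rate must be positive, got {rate}")
    n_total = int(round(window.duration * rate))
    if n_total <= 0:
        raise ValueError(f"window duration {window.duration} yields no slots")

    status = np.full(n_total, SampleStatus.LOST, dtype=np.int8)

    # restrict to samples near the window (timestamps are sorted), then map
    # each to a slot index; the small epsilon absorbs float error for
    # samples sitting exactly on a slot boundary
    start_ms = window.start * 1000.0
    end_ms = start_ms + window.duration * 1000.0
    lo = int(np.searchsorted(rec.t, start_ms - 1.0))
    hi = int(np.searchsorted(rec.t, end_ms + 1.0))
    t_s = rec.t[lo:hi] / 1000.0
    idx = np.floor((t_s - window.start) * rate + 1e-6).astype(np.int64)
    in_win = (idx >= 0) & (idx < n_total)
    idx = idx[in_win]
    on = rec.on_screen_mask()[lo:hi][in_win]
    valid = rec.valid[lo:hi][in_win]

    off = valid & ~on
    has_off = np.zeros(n_total, dtype=bool)
    has_on = np.zeros(n_total, dtype=bool)
    has_off[idx[off]] = True
    has_on[idx[on]] = True
    status[has_off] = SampleStatus.OFF_SCREEN
    status[has_on] = SampleStatus.VALID_ON_SCREEN  # on-screen takes precedence

    _excuse_blinks(status, rate, blink_max_ms)
    return status


def _excuse_blinks(status: np.ndarray, rate: float, blink_max_ms: float) -> None:
    """Relabel short interior LOST runs flanked by on-screen data, in place."""
    n = status.size
    lost = status == SampleStatus.LOST
    if not lost.any():
        return
    edges = np.diff(lost.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if lost[0]:
        starts = np.concatenate([[0], starts])
    if lost[-1]:
        ends = np.concatenate([ends, [n]])
    for i, j in zip(starts, ends):
        run_ms = (j - i) * 1000.0 / rate
        flanked = (
            i > 0
            and j < n
            and status[i - 1] == SampleStatus.VALID_ON_SCREEN
            and status[j] == SampleStatus.VALID_ON_SCREEN
        )
        if flanked and run_ms < blink_max_ms:
            status[i:j] = SampleStatus.EXCUSED_BLINK


def task_ldi(
    rec: GazeRecording | None,
    window: TaskWindow,
    blink_max_ms: float = 150.0,
) -> TaskLDI:
    """Compute the Lost Data Index of one task.

    If ``rec`` is None, or the recording was interrupted at or before the
    window start, the task is scored absent with LDI = 1.
    """
    if window.duration <= 0:
        raise ValueError("zero-duration window has no LDI")
    absent = rec is None or (
        rec.interruption_t is not None
        and window.start * 1000.0 >= rec.interruption_t - 1e-6
    )
    if absent:
        rate = 60.0 if rec is None else rec.rate
        n_total = int(round(window.duration * rate))
        return TaskLDI(
            window=window,
            ldi=1.0,
            n_total=n_total,
            n_lost=n_total,
            n_excused=0,
            n_off_screen=0,
            absent=True,
        )
    status = grid_statuses(rec, window, blink_max_ms=blink_max_ms)
    n_total = status.size
    n_off = int(np.sum(status == SampleStatus.OFF_SCREEN))
    n_missing = int(np.sum(status == SampleStatus.LOST))
    n_excused = int(np.sum(status == SampleStatus.EXCUSED_BLINK))
    n_lost = n_missing + n_off
    return TaskLDI(
        window=window,
        ldi=n_lost / n_total,
        n_total=n_total,
        n_lost=n_lost,
        n_excused=n_excused,
        n_off_screen=n_off,
        absent=False,
    )


def score_recording(
    rec: GazeRecording | None,
    schedule: BatterySchedule,
    blink_max_ms: float = 150.0,
) -> list[TaskLDI]:
    """Score all 48 task windows of a schedule against one recording."""
    return [task_ldi(rec, w, blink_max_ms=blink_max_ms) for w in schedule]


def weighted_ldi(tasks: Sequence[TaskLDI]) -> float:
    """Duration-weighted mean LDI: sum(ldi_i * dur_i) / sum(dur_i)."""
    if not tasks:
        raise ValueError("weighted_ldi requires at least one task")
    num = sum(t.ldi * t.duration for t in tasks)
    den = sum(t.duration for t in tasks)
    if den <= 0:
        raise ValueError("total duration must be positive")
    return num / den


def repetition_ldis(tasks: Sequence[TaskLDI]) -> list[RepetitionLDI]:
    """Duration-weighted LDI per repetition, in repetition order."""
    reps = sorted({t.window.repetition for t in tasks})
    return [
        RepetitionLDI(k, weighted_ldi([t for t in tasks if t.window.repetition == k]))
        for k in reps
    ]


def disruption_time(t: TaskLDI) -> float:
    """Total disrupted time of a task in seconds: LDI x task duration."""
    return t.ldi * t.window.duration


def ldi_table(
    tasks: Sequence[TaskLDI],
    participant_id: str,
    variant: str,
) -> pd.DataFrame:
    """Flatten per-task LDIs into the pipeline's tabular output format."""
    rows = [
        {
            "participant_id": participant_id,
            "variant": variant,
            "index": t.window.index,
            "repetition": t.window.repetition,
            "slot": t.window.slot,
            "task": t.window.spec.name,
            "duration": t.window.duration,
            "n_total": t.n_total,
            "n_lost": t.n_lost,
            "n_excused": t.n_excused,
            "ldi": t.ldi,
            "absent": t.absent,
        }
        for t in tasks
    ]
    return pd.DataFrame(rows)
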
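"""Shared fixtures: schedules, hand-built recordings, and an independent
brute-force LDI oracle used to cross-check the vectorized implementation."""

from __future__ import annotations

import numpy as np
import pytest

from gazeldi.battery import BatterySchedule, TaskSpec, TaskWindow, build_schedule
from gazeldi.io import GazeRecording, ScreenGeometry

SCREEN = ScreenGeometry(1920.0, 1080.0)


@pytest.fixture(scope="session")
def cartoon_schedule() -> BatterySchedule:
    return build_schedule("cartoon")


@pytest.fixture(scope="session")
def standard_schedule() -> BatterySchedule:
    return build_schedule("standard")


@pytest.fixture(scope="session")
def screen() -> ScreenGeometry:
    return SCREEN


def make_window(
    duration: float,
    start: float = 0.0,
    name: str = "att",
    ttype: str = "attention",
    index: int = 0,
    repetition: int = 1,
    slot: int = 1,
) -> TaskWindow:
    spec = TaskSpec(name=name, ttype=ttype, duration=duration)
    return TaskWindow(
        index=index, repetition=repetition, slot=slot, spec=spec,
        start=start, duration=duration,
    )


def rec_from_statuses(
    statuses: str,
    start: float = 0.0,
    rate: float = 60.0,
    screen: ScreenGeometry = SCREEN,
    drop_missing_rows: bool = False,
    interruption_t: float | None = None,
) -> GazeRecording:
    """Build a recording from a compact status string, one char per slot.

    'o' = valid on-screen, 'X' = valid off-screen, 'm' = invalid/missing
    sample row, '.' = no row delivered at all for that slot.
    """
    t, x, y, valid = [], [], [], []
    dt = 1000.0 / rate
    for i, c in enumerate(statuses):
        if c == ".":
            continue
        if c == "m" and drop_missing_rows:
            continue
        t.append(start * 1000.0 + i * dt)
        if c == "o":
            x.append(screen.width / 2)
            y.append(screen.height / 2)
            valid.append(True)
        elif c == "X":
            x.append(screen.width + 50.0)
            y.append(screen.height / 2)
            valid.append(True)
        elif c == "m":
            x.append(np.nan)
            y.append(np.nan)
            valid.append(False)
        else:
            raise ValueError(f"unknown status char {c!r}")
    return GazeRecording(
        "test", "standard", t, x, y, valid, screen, rate=rate,
        interruption_t=interruption_t,
    )


def brute_force_ldi(
    rec: GazeRecording | None,
    window: TaskWindow,
    blink_max_ms: float = 150.0,
) -> float:
    """Independent per-slot LDI counter written with plain Python loops.

    Classifies every nominal slot of the window from the raw samples,
    excuses interior missing-data gaps shorter than the blink bound when
    both neighbours are valid on-screen, and counts the lost fraction.
    """
    rate = 60.0 if rec is None else rec.rate
    n = int(round(window.duration * rate))
    if rec is None or (
        rec.interruption_t is not None
        and window.start * 1000.0 >= rec.interruption_t - 1e-6
    ):
        return 1.0
    # slot classification: 'o', 'X' or 'gap'
    slots = ["gap"] * n
    w = 1.0 if rec.screen.normalized else rec.screen.width
    h = 1.0 if rec.screen.normalized else rec.screen.height
    for i in range(len(rec.t)):
        rel = rec.t[i] / 1000.0 - window.start
        k = int(np.floor(rel * rate + 1e-6))
        if not 0 <= k < n:
            continue
        if not rec.valid[i]:
            continue
        xi, yi = rec.x[i], rec.y[i]
        on = 0 <= xi <= w and 0 <= yi <= h
        if on:
            slots[k] = "o"
        elif slots[k] != "o":
            slots[k] = "X"
    # excuse short flanked gaps
    i = 0
    while i < n:
        if slots[i] != "gap":
            i += 1
            continue
        j = i
        while j < n and slots[j] == "gap":
            j += 1
        if (
            i > 0
            and j < n
            and slots[i - 1] == "o"
            and slots[j] == "o"
            and (j - i) * 1000.0 / rate < blink_max_ms
        ):
            for k in range(i, j):
                slots[k] = "blink"
        i = j
    lost = sum(1 for s in slots if s in ("gap", "X"))
    return lost / n


def random_recording(
    rng: np.random.Generator,
    n_slots: int,
    rate: float = 60.0,
    start: float = 0.0,
) -> GazeRecording:
    """Random small recording mixing all slot kinds, for oracle checks."""
    chars = rng.choice(
        list("ooXm."), size=n_slots, p=[0.55, 0.1, 0.1, 0.15, 0.1]
    )
    return rec_from_statuses("".join(chars), start=start, rate=rate)
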
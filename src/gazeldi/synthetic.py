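"""Seeded synthetic gaze cohorts with the loss structure of a real study.

The generator emulates what a screen-mounted 60 Hz eye tracker records
from a young child working through the 48-task battery:

* a baseline fraction ``p0`` of non-retained data (off-screen excursions
  plus long device gaps) that increases approximately linearly with
  testing time (engagement decay, slope per second);
* short blink gaps (< 150 ms) and spurious 1-2 sample device dropouts,
  both of which the LDI blink exemption is expected to forgive;
* off-screen excursions of realistic run length, realised through an
  episode process rather than per-sample coin flips so gap lengths are
  meaningful relative to the 150 ms exemption rule;
* a per-task interruption hazard that permanently truncates a recording
  (the operator stopping the test), after which every remaining task is
  absent;
* cohorts with between-participant heterogeneity in baseline loss and the
  variant order alternating across participants.

Every recording carries a ground-truth table of the exact generated lost
fraction per task, which downstream code can use for parameter-recovery
checks against the LDI pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import BatterySchedule, build_schedule
from .io import GazeRecording, ScreenGeometry

__all__ = [
    "EngagementParams",
    "CohortConfig",
    "CohortMember",
    "simulate_recording",
    "simulate_cohort",
    "default_study_params",
    "DEFAULT_SCREEN",
]

DEFAULT_SCREEN = ScreenGeometry(width=1920.0, height=1080.0)

_RATE = 60.0
_ON, _OFF, _MISSING = 0, 1, 2
# a missing-data episode must span >= 150 ms so the blink exemption never
# forgives it; at 60 Hz that is 9 slots
_MIN_MISSING_SLOTS = 9


@dataclass(frozen=True)
class EngagementParams:
    """Loss-process parameters for one test variant.

    Attributes
    ----------
    p0
        Baseline expected non-retained fraction at test start.
    slope
        Linear increase of the expected loss fraction per second of
        testing time (engagement decay).
    task_sd
        SD of the per-task jitter added to the expected loss fraction
        (captures task-to-task variability in attention).
    blink_rate
        Blinks per second; blink gaps are always shorter than 150 ms.
    blink_dur_ms
        (low, high) of the uniform blink-duration distribution, ms;
        must stay strictly below 150 ms.
    episode_dur_ms
        (low, high) of the uniform duration distribution of loss
        episodes (off-screen excursions / long device gaps), ms.
    offscreen_frac
        Fraction of loss episodes realised as off-screen gaze (the rest
        are missing-data gaps of >= 150 ms).
    device_loss_rate
        Spurious short (1-2 sample) invalid dropouts per second.
    interrupt_hazard
        Per-task probability that the test is permanently interrupted at
        that task's start.
    interrupt_growth
        Optional linear growth of the hazard with task index
        (hazard_k = interrupt_hazard * (1 + interrupt_growth * k)).
    cohort_conc
        Beta-distribution concentration used when drawing participant-
        level baselines around ``p0`` in cohort simulation; larger means
        a more homogeneous cohort.
    """

    p0: float = 0.2
    slope: float = 0.0011
    task_sd: float = 0.05
    blink_rate: float = 0.25
    blink_dur_ms: tuple[float, float] = (66.0, 133.0)
    episode_dur_ms: tuple[float, float] = (200.0, 800.0)
    offscreen_frac: float = 0.5
    device_loss_rate: float = 0.05
    interrupt_hazard: float = 0.0
    interrupt_growth: float = 0.0
    cohort_conc: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must lie in [0, 1], got {self.p0}")
        for name in ("task_sd", "blink_rate", "device_loss_rate", "cohort_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.offscreen_frac <= 1.0:
            raise ValueError("offscreen_frac must lie in [0, 1]")
        if not 0.0 <= self.interrupt_hazard <= 1.0:
            raise ValueError("interrupt_hazard must lie in [0, 1]")
        lo, hi = self.blink_dur_ms
        if not (0 < lo <= hi < 150.0):
            raise ValueError("blink durations must lie strictly below 150 ms")
        lo, hi = self.episode_dur_ms
        if not (0 < lo <= hi):
            raise ValueError("episode durations must be positive")


def default_study_params() -> dict[str, EngagementParams]:
    """Per-variant defaults emulating the study conditions.

    Baselines of 0.22 (standard) vs 0.11 (cartoon) reproduce the
    first-repetition ordering between the variants; the shared slope makes
    both converge toward high loss by the fourth repetition. Interruption
    hazards are calibrated so that roughly 40% of standard and 16% of
    cartoon synthetic tests interrupt before 432 s.
    """
    common = dict(slope=0.0011, task_sd=0.05, blink_rate=0.25, device_loss_rate=0.05)
    return {
        "standard": EngagementParams(p0=0.22, interrupt_hazard=0.0106, **common),
        "cartoon": EngagementParams(p0=0.11, interrupt_hazard=0.0053, **common),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Shape of a synthetic cohort.

    ``order_policy="alternate"`` assigns standard-first to even participant
    indices and cartoon-first to odd ones, mirroring alternated variant
    order across participants (n=25 gives a 13/12 split).
    """

    n_participants: int = 25
    seed: int = 0
    order_policy: str = "alternate"
    params: Mapping[str, EngagementParams] | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.order_policy not in ("alternate", "standard_first", "cartoon_first"):
            raise ValueError(f"unknown order_policy {self.order_policy!r}")


@dataclass
class CohortMember:
    """One synthetic participant: both recordings plus their ground truth."""

    participant_id: str
    order: tuple[str, str]
    recordings: dict[str, GazeRecording]
    truth: pd.DataFrame


def _episode_sizes(rng: np.random.Generator, n_off: int, params: EngagementParams):
    """Split ``n_off`` loss slots into episodes with realistic run lengths."""
    lo, hi = params.episode_dur_ms
    sizes: list[int] = []
    types: list[int] = []
    total = 0
    while total < n_off:
        s = max(1, int(round(rng.uniform(lo, hi) * _RATE / 1000.0)))
        s = min(s, n_off - total)
        kind = _OFF if rng.random() < params.offscreen_frac else _MISSING
        # a missing gap shorter than the blink bound would be excused by
        # the pipeline; realise it as off-screen instead
        if kind == _MISSING and s < _MIN_MISSING_SLOTS:
            kind = _OFF
        sizes.append(s)
        types.append(kind)
        total += s
    return sizes, types


def _realize_window(
    rng: np.random.Generator, n: int, p: float, params: EngagementParams
) -> tuple[np.ndarray, int]:
    """Status array (on/off/missing) for one task window hitting fraction p."""
    status = np.zeros(n, dtype=np.int8)
    n_off = int(round(p * n))
    if n_off <= 0:
        return status, 0
    if n_off >= n:
        status[:] = _OFF
        return status, n
    sizes, types = _episode_sizes(rng, n_off, params)
    n_on = n - n_off
    # keep at least one retained slot between episodes so they do not merge
    while len(sizes) - 1 > n_on:
        s = sizes.pop()
        k = types.pop()
        sizes[-1] += s
        types[-1] = _MISSING if (types[-1] == _MISSING and k == _MISSING) else _OFF
    n_ep = len(sizes)
    free = n_on - (n_ep - 1)
    extra = rng.multinomial(free, np.full(n_ep + 1, 1.0 / (n_ep + 1)))
    pos = int(extra[0])
    for i, (s, kind) in enumerate(zip(sizes, types)):
        status[pos : pos + s] = kind
        pos += s
        if i < n_ep - 1:
            pos += 1 + int(extra[i + 1])
    return status, n_off


def _insert_short_gaps(
    rng: np.random.Generator,
    status: np.ndarray,
    n_events: int,
    size_low: int,
    size_high: int,
) -> None:
    """Overwrite interior stretches of retained slots with short gaps.

    Each inserted gap keeps >= 1 retained slot on both sides (and never
    touches the window boundary), so the pipeline's blink exemption
    applies and the ground-truth lost fraction is unchanged.
    """
    for _ in range(n_events):
        size = int(rng.integers(size_low, size_high + 1))
        runs = _on_runs(status)
        candidates = [(a, b) for a, b in runs if b - a >= size + 2]
        if not candidates:
            continue
        weights = np.array([b - a - size - 1 for a, b in candidates], dtype=float)
        k = rng.choice(len(candidates), p=weights / weights.sum())
        a, b = candidates[k]
        off = int(rng.integers(1, b - a - size))
        status[a + off : a + off + size] = _MISSING


def _on_runs(status: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    n = status.size
    i = 0
    while i < n:
        if status[i] == _ON:
            j = i
            while j < n and status[j] == _ON:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def simulate_recording(
    schedule: BatterySchedule,
    params: EngagementParams,
    seed: int | np.random.SeedSequence | np.random.Generator,
    participant_id: str = "synthetic",
    screen: ScreenGeometry = DEFAULT_SCREEN,
) -> tuple[GazeRecording, pd.DataFrame]:
    """Generate one 60 Hz gaze recording over a battery schedule.

    Per task, the expected non-retained fraction at the window midpoint t
    is ``clip(p0 + slope * t + jitter, 0, 1)``, realised through loss
    episodes; blink and device gaps are added on top without affecting the
    ground truth. Returns the recording and a per-task ground-truth table
    (columns: index, repetition, slot, task, true_lost_fraction, absent).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dt_ms = 1000.0 / _RATE
    statuses: list[np.ndarray] = []
    truth_rows = []
    interruption_t: float | None = None
    for w in schedule:
        absent = interruption_t is not None
        if not absent:
            hazard = params.interrupt_hazard * (
                1.0 + params.interrupt_growth * w.index
            )
            if hazard > 0 and rng.random() < min(hazard, 1.0):
                interruption_t = w.start * 1000.0
                absent = True
        if absent:
            truth_rows.append(
                {
                    "participant_id": participant_id,
                    "variant": schedule.variant,
                    "index": w.index,
                    "repetition": w.repetition,
                    "slot": w.slot,
                    "task": w.spec.name,
                    "true_lost_fraction": 1.0,
                    "absent": True,
                }
            )
            continue
        n = int(round(w.duration * _RATE))
        t_mid = w.start + w.duration / 2.0
        p = float(
            np.clip(params.p0 + params.slope * t_mid + rng.normal(0, params.task_sd), 0, 1)
        )
        status, n_loss = _realize_window(rng, n, p, params)
        n_blinks = rng.poisson(params.blink_rate * w.duration)
        lo = max(1, int(round(params.blink_dur_ms[0] * _RATE / 1000.0)))
        hi = max(lo, int(round(params.blink_dur_ms[1] * _RATE / 1000.0)))
        hi = min(hi, _MIN_MISSING_SLOTS - 1)
        _insert_short_gaps(rng, status, n_blinks, lo, hi)
        n_blips = rng.poisson(params.device_loss_rate * w.duration)
        _insert_short_gaps(rng, status, n_blips, 1, 2)
        statuses.append(status)
        truth_rows.append(
            {
                "participant_id": participant_id,
                "variant": schedule.variant,
                "index": w.index,
                "repetition": w.repetition,
                "slot": w.slot,
                "task": w.spec.name,
                "true_lost_fraction": n_loss / n,
                "absent": False,
            }
        )

    status = (
        np.concatenate(statuses) if statuses else np.empty(0, dtype=np.int8)
    )
    n_samples = status.size
    t = np.arange(n_samples) * dt_ms
    x = np.full(n_samples, np.nan)
    y = np.full(n_samples, np.nan)
    valid = status != _MISSING

    on = status == _ON
    n_on = int(on.sum())
    x[on] = rng.uniform(0.15 * screen.width, 0.85 * screen.width, size=n_on)
    y[on] = rng.uniform(0.15 * screen.height, 0.85 * screen.height, size=n_on)

    off = status == _OFF
    n_off = int(off.sum())
    if n_off:
        side = rng.integers(0, 2, size=n_off)
        margin = rng.uniform(10.0, 120.0, size=n_off)
        x[off] = np.where(side == 0, -margin, screen.width + margin)
        y[off] = rng.uniform(0.0, screen.height, size=n_off)

    rec = GazeRecording(
        participant_id,
        schedule.variant,
        t,
        x,
        y,
        valid,
        screen,
        rate=_RATE,
        interruption_t=interruption_t,
    )
    return rec, pd.DataFrame(truth_rows)


def simulate_cohort(
    cfg: CohortConfig,
    schedules: Mapping[str, BatterySchedule] | None = None,
    screen: ScreenGeometry = DEFAULT_SCREEN,
) -> list[CohortMember]:
    """Generate a cohort: one standard and one cartoon recording each.

    Participant-level baselines are drawn from a Beta distribution with
    mean ``p0`` and concentration ``cohort_conc`` independently per
    variant; all randomness derives deterministically from ``cfg.seed``.
    """
    params = dict(cfg.params) if cfg.params is not None else default_study_params()
    if schedules is None:
        schedules = {v: build_schedule(v) for v in params}
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_participants)
    members: list[CohortMember] = []
    for i, child in enumerate(children):
        if cfg.order_policy == "alternate":
            order = ("standard", "cartoon") if i % 2 == 0 else ("cartoon", "standard")
        elif cfg.order_policy == "standard_first":
            order = ("standard", "cartoon")
        else:
            order = ("cartoon", "standard")
        pid = f"P{i:03d}"
        streams = child.spawn(2 * len(params))
        recordings: dict[str, GazeRecording] = {}
        truths = []
        for j, variant in enumerate(sorted(params)):
            base = params[variant]
            draw_rng = np.random.default_rng(streams[2 * j])
            if 0.0 < base.p0 < 1.0 and base.cohort_conc > 0:
                a = base.p0 * base.cohort_conc
                b = (1.0 - base.p0) * base.cohort_conc
                p0_i = float(draw_rng.beta(a, b))
            else:
                p0_i = base.p0
            member_params = replace(base, p0=p0_i)
            rec, truth = simulate_recording(
                schedules[variant],
                member_params,
                np.random.default_rng(streams[2 * j + 1]),
                participant_id=pid,
                screen=screen,
            )
            recordings[variant] = rec
            truths.append(truth)
        members.append(
            CohortMember(
                participant_id=pid,
                order=order,
                recordings=recordings,
                truth=pd.concat(truths, ignore_index=True),
            )
        )
    return members
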
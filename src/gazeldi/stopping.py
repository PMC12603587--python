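"""Simulated dynamic stopping criterion on per-task LDI.

A dynamic testing procedure could terminate the battery early once enough
usable data has been collected. The rule simulated here: a task is
*admissible* if its LDI does not exceed a threshold tau (inclusive by
default); the test stops at the end of the task that brings the number of
*distinct* admissible task types to M (M = 12 by default, i.e. every task
type must be admissible). Tasks are walked in the fixed presentation
order; a task type that fails in one repetition gets another chance in
the next. If the fourth repetition ends without reaching M, the test is
incomplete and its duration is the full battery length.

Sweeping tau yields a per-participant tau -> duration curve; its
trapezoidal area (AUC) summarises test length over the whole threshold
range, and a point comparison at a conventional tau (0.2) compares the
two battery variants directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import BatterySchedule, N_SLOTS
from .compare import UTestResult, mann_whitney_u, summarize
from .ldi import TaskLDI

__all__ = [
    "StoppingConfig",
    "StoppingResult",
    "ThresholdCurve",
    "is_admissible",
    "simulate_stopping",
    "sweep_thresholds",
    "repetitions_required",
    "cohort_summary",
    "compare_durations",
    "default_tau_grid",
]


@dataclass(frozen=True)
class StoppingConfig:
    """Parameters of the stopping rule.

    tau is the admissibility threshold on LDI; ``m_required`` the number
    of distinct admissible task types needed to stop; ``comparison``
    selects inclusive (``"le"``, the default) or strict (``"lt"``)
    admissibility.
    """

    tau: float
    m_required: int = 12
    comparison: str = "le"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if not 1 <= self.m_required <= N_SLOTS:
            raise ValueError(
                f"m_required must lie in 1..{N_SLOTS}, got {self.m_required}"
            )
        if self.comparison not in ("le", "lt"):
            raise ValueError(f"comparison must be 'le' or 'lt', got {self.comparison}")


@dataclass(frozen=True)
class StoppingResult:
    """Outcome of the stopping rule for one participant at one threshold."""

    complete: bool
    duration: float
    n_tasks_presented: int
    repetitions_used: int
    satisfied_slots: frozenset[str]


@dataclass(frozen=True)
class ThresholdCurve:
    """tau -> simulated test duration for one participant, with its AUC."""

    taus: tuple[float, ...]
    durations: tuple[float, ...]
    completes: tuple[bool, ...]
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.taus, "duration": self.durations, "complete": self.completes}
        )


def is_admissible(ldi: float, tau: float, comparison: str = "le") -> bool:
    """True iff a task with this LDI is retained at threshold tau.

    Inclusive by default (LDI <= tau); set ``comparison="lt"`` for the
    strict variant.
    """
    if comparison == "le":
        return ldi <= tau
    if comparison == "lt":
        return ldi < tau
    raise ValueError(f"comparison must be 'le' or 'lt', got {comparison}")


def _check_alignment(
    task_ldis: Sequence[TaskLDI], schedule: BatterySchedule
) -> None:
    if len(task_ldis) != len(schedule):
        raise ValueError(
            f"expected {len(schedule)} task LDIs, got {len(task_ldis)}"
        )
    for t, w in zip(task_ldis, schedule):
        if (
            t.window.index != w.index
            or t.window.spec.name != w.spec.name
            or abs(t.window.start - w.start) > 1e-9
            or abs(t.window.duration - w.duration) > 1e-9
        ):
            raise ValueError(
                f"task LDI at index {t.window.index} does not align with "
                f"schedule window {w.index} ({w.spec.name})"
            )


def simulate_stopping(
    task_ldis: Sequence[TaskLDI],
    schedule: BatterySchedule,
    cfg: StoppingConfig,
) -> StoppingResult:
    """Walk the battery in presentation order and apply the stopping rule.

    Duration accrues through the *end* of the completing task (whether the
    Mth type has just been satisfied can only be known once the task has
    run); there is no partial-task credit. An incomplete test runs the
    full battery.
    """
    _check_alignment(task_ldis, schedule)
    satisfied: set[str] = set()
    for i, (t, w) in enumerate(zip(task_ldis, schedule)):
        if is_admissible(t.ldi, cfg.tau, cfg.comparison):
            satisfied.add(w.spec.name)
        if len(satisfied) >= cfg.m_required:
            return StoppingResult(
                complete=True,
                duration=w.start + w.duration,
                n_tasks_presented=i + 1,
                repetitions_used=w.repetition,
                satisfied_slots=frozenset(satisfied),
            )
    return StoppingResult(
        complete=False,
        duration=schedule.total_duration(),
        n_tasks_presented=len(schedule),
        repetitions_used=schedule[-1].repetition,
        satisfied_slots=frozenset(satisfied),
    )


def default_tau_grid(step: float = 0.01, upper: float = 0.25) -> np.ndarray:
    """Default threshold grid for curves and AUC: 0 to ``upper`` in ``step``s."""
    n = int(round(upper / step))
    return np.round(np.linspace(0.0, upper, n + 1), 10)


def sweep_thresholds(
    task_ldis: Sequence[TaskLDI],
    schedule: BatterySchedule,
    m_required: int = 12,
    taus: Sequence[float] | None = None,
    comparison: str = "le",
) -> ThresholdCurve:
    """Simulate the stopping rule across a threshold grid.

    Durations are non-increasing in tau (raising the threshold can only
    admit more tasks). The AUC is the trapezoidal integral of duration
    (seconds) over tau, reported together with the grid that produced it.
    """
    taus = default_tau_grid() if taus is None else np.asarray(taus, dtype=float)
    if taus.size == 0:
        raise ValueError("threshold grid must be non-empty")
    if np.any(np.diff(taus) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    if taus[0] < 0 or taus[-1] > 1:
        raise ValueError("thresholds must lie in [0, 1]")
    durations = []
    completes = []
    for tau in taus:
        res = simulate_stopping(
            task_ldis,
            schedule,
            StoppingConfig(tau=float(tau), m_required=m_required, comparison=comparison),
        )
        durations.append(res.duration)
        completes.append(res.complete)
    auc = float(np.trapezoid(durations, taus)) if taus.size > 1 else 0.0
    return ThresholdCurve(
        taus=tuple(float(t) for t in taus),
        durations=tuple(durations),
        completes=tuple(completes),
        auc=auc,
    )


def repetitions_required(
    task_ldis: Sequence[TaskLDI],
    schedule: BatterySchedule,
    cfg: StoppingConfig,
) -> int | None:
    """Number of repetitions used when the rule completes, else None."""
    res = simulate_stopping(task_ldis, schedule, cfg)
    return res.repetitions_used if res.complete else None


def cohort_summary(
    results: Mapping[str, Sequence[StoppingResult]],
    tau: float,
) -> pd.DataFrame:
    """Per-variant completion and duration summary at one threshold.

    Parameters
    ----------
    results
        ``variant -> StoppingResult per participant`` at threshold ``tau``.

    Returns
    -------
    DataFrame with one row per variant: fraction incomplete, mean (SD)
    duration, and the distribution of repetitions used among completed
    tests.
    """
    if not results or any(len(v) == 0 for v in results.values()):
        raise ValueError("cohort must contain at least one participant per variant")
    rows = []
    for variant, rs in results.items():
        durations = [r.duration for r in rs]
        s = summarize(durations)
        n = len(rs)
        n_incomplete = sum(not r.complete for r in rs)
        reps = [r.repetitions_used for r in rs if r.complete]
        row = {
            "variant": variant,
            "tau": tau,
            "n": n,
            "n_incomplete": n_incomplete,
            "frac_incomplete": n_incomplete / n,
            "mean_duration": s.mean,
            "sd_duration": s.sd,
        }
        for k in range(1, 5):
            row[f"n_reps_{k}"] = sum(r == k for r in reps)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_durations(
    standard: Sequence[float],
    cartoon: Sequence[float],
    alpha: float = 0.10,
) -> UTestResult:
    """One-tailed U test that the cartoon test is *longer* (durations or AUC)."""
    return mann_whitney_u(cartoon, standard, alternative="greater", alpha=alpha)
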
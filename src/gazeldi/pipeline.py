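"""End-to-end orchestration: ingest or synthesize -> LDI -> comparisons.

A single :class:`PipelineConfig` (loadable from YAML) drives everything;
all randomness flows from one root seed, so re-running with the same
config reproduces every output byte for byte.

Outputs written to the configured directory:

``ldi_tasks.csv``
    Per-task LDI bookkeeping for every participant x variant.
``comparison.csv``
    Repetition-level between-variant comparison (U tests + summaries).
``stopping_curves.csv``
    Per-participant tau -> duration curves with their AUC.
``stopping_point.csv``
    Per-participant stopping outcome at the point threshold.
``cohort_summary.csv``
    Completion/duration summary per variant at the point threshold.
``stopping_tests.csv``
    U tests on durations (at the point tau) and on AUCs.
``run_log.txt``
    Every parameter of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .battery import VARIANTS, BatterySchedule, build_schedule
from .compare import ComparisonReport, compare_repetitions
from .io import GazeRecording, ScreenGeometry, read_gaze_table
from .ldi import TaskLDI, ldi_table, score_recording
from .stopping import (
    StoppingConfig,
    cohort_summary,
    compare_durations,
    default_tau_grid,
    simulate_stopping,
    sweep_thresholds,
)
from .synthetic import CohortConfig, default_study_params, simulate_cohort

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline",
           "task_ldis_from_table"]

logger = logging.getLogger("gazeldi")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and participant."""


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    ``mode`` is ``"synthetic"`` (generate a seeded cohort) or ``"tables"``
    (read gaze tables listed in ``tables``: dicts with ``participant_id``,
    ``variant``, ``path`` and optional ``interruption_t`` in ms).
    """

    mode: str = "synthetic"
    outdir: str = "gazeldi_out"
    seed: int = 0
    n_participants: int = 25
    blink_max_ms: float = 150.0
    tau: float = 0.2
    tau_step: float = 0.01
    tau_upper: float = 0.25
    m_required: int = 12
    admissibility: str = "le"
    alpha: float = 0.05
    alpha_stopping: float = 0.10
    slot_order: Sequence[str] | None = None
    screen_width: float = 1920.0
    screen_height: float = 1080.0
    screen_normalized: bool = False
    tables: Sequence[Mapping[str, object]] = field(default_factory=tuple)
    dialect: Mapping[str, str] | None = None
    #: optional per-variant EngagementParams overrides for synthetic mode,
    #: e.g. {"standard": {"p0": 0.0, "blink_rate": 0.0}, "cartoon": {...}}
    engagement: Mapping[str, Mapping[str, float]] | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @property
    def screen(self) -> ScreenGeometry:
        return ScreenGeometry(
            self.screen_width, self.screen_height, self.screen_normalized
        )


@dataclass
class PipelineResult:
    """Handles on every artefact a pipeline run produced."""

    outdir: Path
    ldi: pd.DataFrame
    comparison: ComparisonReport
    curves: pd.DataFrame
    point_results: pd.DataFrame
    summary: pd.DataFrame
    stopping_tests: pd.DataFrame


def _gather_recordings(
    cfg: PipelineConfig,
) -> dict[str, dict[str, GazeRecording]]:
    if cfg.mode == "synthetic":
        params = default_study_params()
        if cfg.engagement:
            from .synthetic import EngagementParams
            from dataclasses import replace as _replace

            for variant, overrides in cfg.engagement.items():
                base = params.get(variant, EngagementParams())
                params[variant] = _replace(base, **dict(overrides))
        members = simulate_cohort(
            CohortConfig(
                n_participants=cfg.n_participants,
                seed=cfg.seed,
                params=params,
            ),
            screen=cfg.screen,
        )
        return {m.participant_id: m.recordings for m in members}
    if cfg.mode != "tables":
        raise ValueError(f"unknown mode {cfg.mode!r}")
    recs: dict[str, dict[str, GazeRecording]] = {}
    for entry in cfg.tables:
        pid = str(entry["participant_id"])
        variant = str(entry["variant"])
        path = str(entry["path"])
        try:
            rec = read_gaze_table(
                path,
                cfg.screen,
                dialect=cfg.dialect,
                participant_id=pid,
                variant=variant,
                interruption_t=entry.get("interruption_t"),
            )
        except Exception as exc:
            raise PipelineError(
                f"stage=ingest participant={pid} file={path}: {exc}"
            ) from exc
        recs.setdefault(pid, {})[variant] = rec
    return recs


def task_ldis_from_table(
    df: pd.DataFrame, schedules: Mapping[str, BatterySchedule]
) -> dict[str, dict[str, list[TaskLDI]]]:
    """Rebuild per-participant TaskLDI sequences from a saved LDI table."""
    out: dict[str, dict[str, list[TaskLDI]]] = {}
    for (pid, variant), grp in df.groupby(["participant_id", "variant"]):
        sched = schedules[str(variant)]
        grp = grp.sort_values("index")
        tasks = [
            TaskLDI(
                window=sched[int(r["index"])],
                ldi=float(r["ldi"]),
                n_total=int(r["n_total"]),
                n_lost=int(r["n_lost"]),
                n_excused=int(r["n_excused"]),
                absent=bool(r["absent"]),
            )
            for _, r in grp.iterrows()
        ]
        out.setdefault(str(pid), {})[str(variant)] = tasks
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write every report table to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("pipeline config: %s", cfg)
        schedules = {
            v: build_schedule(v, order=cfg.slot_order) for v in VARIANTS
        }
        recordings = _gather_recordings(cfg)
        logger.info("gathered %d participants", len(recordings))

        cohort_ldis: dict[str, dict[str, list[TaskLDI]]] = {}
        ldi_frames = []
        for pid, per_variant in recordings.items():
            for variant, rec in per_variant.items():
                try:
                    tasks = score_recording(
                        rec, schedules[variant], blink_max_ms=cfg.blink_max_ms
                    )
                except Exception as exc:
                    raise PipelineError(
                        f"stage=ldi participant={pid} variant={variant}: {exc}"
                    ) from exc
                cohort_ldis.setdefault(pid, {})[variant] = tasks
                ldi_frames.append(ldi_table(tasks, pid, variant))
        ldi_df = pd.concat(ldi_frames, ignore_index=True)
        ldi_df.to_csv(outdir / "ldi_tasks.csv", index=False)

        report = compare_repetitions(cohort_ldis, alpha=cfg.alpha, seed=cfg.seed)
        report.to_csv(outdir / "comparison.csv")
        for label, res in report.tests.items():
            logger.info(
                "comparison %s: U=%.1f p=%.4g (alpha_bonf=%.4g)",
                label, res.u, res.p, res.alpha_bonf,
            )

        taus = default_tau_grid(cfg.tau_step, cfg.tau_upper)
        point_cfg = StoppingConfig(
            tau=cfg.tau, m_required=cfg.m_required, comparison=cfg.admissibility
        )
        curve_rows = []
        point_rows = []
        point_results: dict[str, list] = {v: [] for v in VARIANTS}
        aucs: dict[str, list[float]] = {v: [] for v in VARIANTS}
        for pid in sorted(cohort_ldis):
            for variant, tasks in cohort_ldis[pid].items():
                curve = sweep_thresholds(
                    tasks,
                    schedules[variant],
                    m_required=cfg.m_required,
                    taus=taus,
                    comparison=cfg.admissibility,
                )
                for tau, dur, comp in zip(
                    curve.taus, curve.durations, curve.completes
                ):
                    curve_rows.append(
                        {
                            "participant_id": pid,
                            "variant": variant,
                            "tau": tau,
                            "duration": dur,
                            "complete": comp,
                            "auc": curve.auc,
                        }
                    )
                aucs[variant].append(curve.auc)
                res = simulate_stopping(tasks, schedules[variant], point_cfg)
                point_results[variant].append(res)
                point_rows.append(
                    {
                        "participant_id": pid,
                        "variant": variant,
                        "tau": cfg.tau,
                        "complete": res.complete,
                        "duration": res.duration,
                        "n_tasks_presented": res.n_tasks_presented,
                        "repetitions_used": res.repetitions_used,
                    }
                )
        curves_df = pd.DataFrame(curve_rows)
        curves_df.to_csv(outdir / "stopping_curves.csv", index=False)
        point_df = pd.DataFrame(point_rows)
        point_df.to_csv(outdir / "stopping_point.csv", index=False)

        summary = cohort_summary(point_results, tau=cfg.tau)
        summary.to_csv(outdir / "cohort_summary.csv", index=False)

        dur_test = compare_durations(
            [r.duration for r in point_results["standard"]],
            [r.duration for r in point_results["cartoon"]],
            alpha=cfg.alpha_stopping,
        )
        auc_test = compare_durations(
            aucs["standard"], aucs["cartoon"], alpha=cfg.alpha_stopping
        )
        stopping_tests = pd.DataFrame(
            [
                {"quantity": f"duration_at_tau_{cfg.tau}", "u": dur_test.u,
                 "p": dur_test.p, "alternative": dur_test.alternative,
                 "alpha": dur_test.alpha},
                {"quantity": "auc", "u": auc_test.u, "p": auc_test.p,
                 "alternative": auc_test.alternative, "alpha": auc_test.alpha},
            ]
        )
        stopping_tests.to_csv(outdir / "stopping_tests.csv", index=False)
        logger.info(
            "stopping at tau=%.2f: duration p=%.3g, AUC p=%.3g",
            cfg.tau, dur_test.p, auc_test.p,
        )
        return PipelineResult(
            outdir=outdir,
            ldi=ldi_df,
            comparison=report,
            curves=curves_df,
            point_results=point_df,
            summary=summary,
            stopping_tests=stopping_tests,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
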
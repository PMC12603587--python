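# gazeldi

Data-quality and engagement analysis for task-segmented eye-tracking
batteries, built around the **Lost Data Index (LDI)**.

When young children sit in front of a screen-mounted eye tracker, a large
part of the recording is often unusable: the tracker loses the eyes, or
the child simply looks away. `gazeldi` quantifies this per task as

```
LDI = (missing samples + off-screen samples) / total nominal samples
```

with short interior gaps (< 150 ms), attributable to blinks, exempted.
LDI = 0 means every sample is usable; LDI = 1 means the task produced no
usable data (including tasks never reached because the session was
interrupted). Because off-screen gaze counts as loss and blinks do not,
the LDI reflects avoidable, participant-driven disruption — a proxy for
engagement as well as a bound on analysable data.

On top of the metric the package provides:

* **Battery timelines** for a 48-task protocol (4 repetitions × 12
  tasks: smooth pursuit, visual memory, cued attention, social
  orienting) in two variants — a *standard* presentation (432.4 s) and a
  longer gamified *cartoon* presentation (628 s) — with configurable
  orders and durations, and segmentation of recordings into task windows.
* **Engagement comparison**: duration-weighted LDI per repetition,
  one-tailed Mann-Whitney U tests between variants with Bonferroni
  correction (α/4 = .0125), plus preference/retention summaries.
* **Dynamic stopping simulation**: a task is admissible when LDI ≤ τ;
  the simulated test stops once M distinct task types are admissible
  (default M = 12). Threshold sweeps give per-participant τ → duration
  curves and their AUC, and cohort summaries of completion at a point
  threshold (default τ = 0.2).
* **A seeded synthetic cohort generator** with ground truth: baseline
  loss per variant, linear engagement decay, blink gaps, off-screen
  excursions, device dropouts, and interruption hazards, so every
  pipeline stage can be validated end to end without real recordings.

## Worked example

```python
import gazeldi as g

schedules = {v: g.build_schedule(v) for v in ("standard", "cartoon")}

# a seeded 25-child synthetic cohort, both variants per participant
members = g.simulate_cohort(g.CohortConfig(n_participants=25, seed=1))
cohort = {
    m.participant_id: {
        v: g.score_recording(rec, schedules[v])
        for v, rec in m.recordings.items()
    }
    for m in members
}

report = g.compare_repetitions(cohort)
print(report.table[["segment", "p", "standard_median", "cartoon_median"]]
      .round(4).to_string(index=False))
```

```
     segment      p  standard_median  cartoon_median
    complete 0.0037           0.5409          0.4324
repetition_1 0.0000           0.3067          0.1677
repetition_2 0.0039           0.4215          0.3357
repetition_3 0.0536           0.6016          0.5220
repetition_4 0.3623           0.7319          0.6936
```

The gamified variant loses significantly less data early in the session
(repetition 1: median LDI 0.17 vs 0.31, one-tailed U test p < .001,
well under the Bonferroni level .0125), and the gap closes as engagement
decays over the session — by repetition 4 the two variants are
indistinguishable. The stopping rule then turns low early LDI into
shorter tests:

```python
tasks = cohort["P000"]["cartoon"]
res = g.simulate_stopping(tasks, schedules["cartoon"], g.StoppingConfig(tau=0.2))
print(res.complete, res.duration)        # False 628.0  (ran the full battery)
curve = g.sweep_thresholds(tasks, schedules["cartoon"])
print(round(curve.auc, 2))               # 157.0  (τ ∈ [0, 0.25] grid)
```

The same analyses run from the shell:

```
gazeldi synth --n 25 --seed 1 --outdir cohort/      # gaze tables + ground truth
gazeldi run   --seed 1 --outdir reports/            # everything end to end
gazeldi compare  --ldi-table reports/ldi_tasks.csv  --out comparison.csv
gazeldi stopping --ldi-table reports/ldi_tasks.csv  --tau 0.2
```

`gazeldi run` writes per-task LDI tables, the repetition-level
comparison, stopping curves, cohort summaries and a run log; re-running
with the same seed reproduces every file byte for byte. Real recordings
enter as delimited text tables (TSV/CSV; columns configurable) listed in
a YAML config with `mode: tables`.

## Layout

```
src/gazeldi/
  io.py         gaze-table reading/writing, screen geometry, validation
  battery.py    task specs, 48-window timelines, segmentation
  ldi.py        slot classification, blink exemption, LDI aggregation
  compare.py    summaries, Mann-Whitney U, Bonferroni, feedback utilities
  stopping.py   admissibility, stopping walk, threshold sweeps, AUC
  synthetic.py  seeded gaze-cohort generator with ground truth
  pipeline.py   config-driven end-to-end runs
  cli.py        `gazeldi` command-line interface
docs/methods.md model, parameters, numerical choices, limitations
```
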
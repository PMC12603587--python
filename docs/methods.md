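# Methods

## The Lost Data Index

`gazeldi` analyses data quality and engagement in task-batterized
eye-tracking sessions recorded with a screen-mounted tracker at a nominal
60 Hz. The central statistic is the **Lost Data Index** of a task,

    LDI = (n_missing + n_off_screen) / n_total,

computed on the task's nominal sample grid (`n_total = round(duration ×
rate)`). It derives from *robustness*, the classical data-quality metric
(fraction of non-missing samples), with two changes:

1. Gaze that is detected but lies outside the screen counts as lost —
   a child looking away is a loss of engagement even though the device
   recorded a position.
2. Short gaps of missing samples (< 150 ms) flanked on both sides by valid
   on-screen data are attributed to blinks and *not* counted. Blinks are
   unavoidable and can be imputed downstream, so they carry no signal
   about engagement.

This turns a device property into a measure of avoidable, participant-
driven disruption: 0 means every sample usable, 1 means nothing usable. A
task with no recording at all — the session was interrupted before it —
scores LDI = 1 by convention.

### Numerical choices

* Slots are half-open intervals on the nominal grid aligned to the task
  window start; a sample maps to slot `floor((t − start) · rate + ε)`
  with ε = 1e-6 grid units to absorb float error at slot boundaries.
* If several samples fall in one slot, on-screen evidence wins over
  off-screen, which wins over missing.
* Gap duration is `run_length × 1000 / rate` ms and the blink bound is
  strict (< 150 ms): a 9-slot run at 60 Hz (exactly 150 ms) is lost.
* Gaps touching a task boundary are never exempted — there is no flanking
  evidence of a blink, and segmentation into tasks happens before
  classification. Off-screen runs are never exempted regardless of length.
* Exempted blink slots stay in the denominator; they are forgiven as loss,
  not removed from the task.
* Screen bounds are inclusive; device-invalid flags and non-finite
  coordinates are both treated as missing.
* The denominator uses the nominal grid rather than delivered device rows
  so stretches where the device delivered nothing remain countable; the
  per-task bookkeeping (`n_total`, `n_lost`, `n_excused`) is preserved in
  every output table.

## The battery timelines

Both test variants present the same 12 tasks per repetition — four
smooth-pursuit variants (horizontal/vertical × 1600/2400 ms period,
i.e. 0.625/≈0.42 Hz), six visual-memory variants, one cued-attention task
(4 modalities × 2.9 s = 11.6 s in the standard variant) and one
social-orienting task — repeated 4 times (48 tasks). Durations per type
(standard/cartoon, seconds): pursuit 9/10, memory 9/12, attention
11.6/37, social 6.5/8, giving repetition lengths 108.1/157 s and totals
432.4/628 s. Window start times are accumulated in integer milliseconds
to avoid float drift.

The exact within-repetition slot order is configurable. The default
alternates dynamic tasks with the memory tasks (SP, MEM, SP, MEM, ATT,
MEM, SP, MEM, SOC, MEM, SP, MEM). Every headline quantity — totals,
repetition starts, duration-weighted LDI, the stopping rule with M = 12 —
is invariant to the slot order, so this choice only matters for
window-level inspection.

## Between-variant comparison

Per participant and variant, the 48 task LDIs are aggregated to a
duration-weighted mean per repetition and over the whole test
(Σ LDIᵢ·dᵢ / Σ dᵢ). The variants are compared per repetition with
one-tailed Mann-Whitney U tests (alternative: the gamified variant has
stochastically smaller LDI); LDI is bounded in [0, 1] and non-normal, so
a rank test is appropriate. The four repetition tests carry a Bonferroni-
corrected level α/4 = .0125 at α = .05.

The U statistic uses rank sums with midranks; p-values are exact (full
enumeration) for tie-free samples with n₁+n₂ ≤ 12 and otherwise use the
normal approximation with tie and continuity corrections (delegated to
`scipy.stats.mannwhitneyu`; the test suite cross-checks the exact path
against an independent enumeration oracle). Group summaries report mean,
sample SD (n−1), median and quartiles by linear interpolation.

The published design is within-subject but the published test is
unpaired; `compare_repetitions` reproduces the unpaired test and offers a
paired sign-flip permutation test on per-participant differences behind
`paired=True`, clearly an extension.

## Dynamic stopping simulation

A task is *admissible* at threshold τ when LDI ≤ τ. The comparison is
inclusive by default — the source material is ambiguous between "below τ"
and "≤ τ", so the operator is configurable (`comparison="lt"`). Walking
the battery in presentation order, the test stops at the **end** of the
task that brings the number of distinct admissible task types to M
(default 12, i.e. all types). No partial-task credit is given: whether
the Mth type has been satisfied can only be known once the task has run.
A task type that fails gets another chance in the next repetition; if the
fourth repetition ends short of M, the test is incomplete and the
duration is the full battery length. Absent tasks (after an interruption)
have LDI 1 and are inadmissible for every τ < 1.

Sweeping τ over a grid (default 0 … 0.25 in steps of 0.01; the grid is a
config parameter and is always reported alongside) yields a
per-participant τ → duration curve, summarised by its trapezoidal AUC.
The cohort-level outputs are the fraction of incomplete tests, mean (SD)
duration and the distribution of repetitions used at a point threshold
(default τ = 0.2, a conventional admissibility threshold in
smooth-pursuit work), plus one-tailed U tests (α = .10, alternative:
gamified test longer) on point durations and AUCs.

## Synthetic cohort generator

No recordings are distributed with the package, so a seeded generator
provides ground-truthed input for every pipeline stage. Per task window
the expected non-retained fraction is

    p(t) = clip(p0 + slope · t + ε_task, 0, 1),  ε_task ~ N(0, task_sd²)

with t the window midpoint. The realized loss is an episode process
rather than per-sample coin flips, so run lengths are meaningful relative
to the 150 ms exemption: episode durations are uniform on 200–800 ms, a
fraction `offscreen_frac` (default 0.5) are realised as off-screen gaze
and the rest as missing-data gaps forced to ≥ 150 ms (shorter remnants
become off-screen) so the pipeline never excuses true loss. Episodes are
separated by at least one retained slot, and the target count
`round(p · n)` of lost slots is hit exactly, which is why parameter
recovery through the LDI pipeline is exact to the slot.

On top of the loss process the generator inserts blink gaps (Poisson at
`blink_rate`, default 0.25/s, durations uniform 66–133 ms) and spurious
1–2-sample device dropouts (default 0.05/s), both placed strictly inside
retained runs with at least one on-screen slot of margin — the pipeline
must forgive exactly these, and the ground-truth table does not count
them. An interruption hazard per task (standard 0.0106, cartoon 0.0053 by
default, optionally growing with task index) truncates the recording at
a task start and marks all later tasks absent.

Cohort defaults: n = 25 participants, variant order alternating
(standard-first for even indices: 13/12 split at n = 25), baseline p0 of
0.22 (standard) vs 0.11 (cartoon) matching the first-repetition levels
the two variants are expected to show, shared slope 0.0011/s so both
variants converge toward high loss by the fourth repetition.
Participant-level baselines are drawn from Beta distributions with these
means and concentration `cohort_conc = 20` (SD ≈ 0.09/0.07), giving the
repetition-1 effect enough contrast that the one-tailed U test at n = 25
rejects at .05 in ≥ 80% of seeds, while interruptions add the realistic
right tail of participants with near-total loss.

### What the generator does and does not emulate

It reproduces the *data-retention structure* of a session: baseline loss
levels and their ordering between variants, the approximately linear
engagement decay, blink/dropout forgiveness, interruptions, and
between-participant spread. It does **not** simulate gaze kinematics
(saccades, fixations, pursuit gain), task performance, or the strong
within-participant correlation of task quality seen in real children.
The last point matters for the stopping simulation: because per-task
jitter is independent, "all 12 task types admissible" is much rarer in
synthetic cohorts than in real ones, so completion fractions at stringent
thresholds (e.g. τ = 0.2 with M = 12) are pessimistic. Passing tests
therefore demonstrate the correctness and monotonicity of the stopping
machinery and the direction of between-variant effects, not realistic
completion rates.

## Problem sizes and determinism

All analyses run comfortably on one CPU: a full synthetic cohort (25
participants × 2 variants × ~630 s at 60 Hz) generates in about one
second and scores in well under a second; the 20-seed power check used in
the acceptance checks takes ~20 s. Every source of randomness flows from
a single root seed through `numpy.random.SeedSequence`, so identical
configurations reproduce identical cohorts and byte-identical report
files.

## Known limitations

* The generator's independence assumptions (see above) make cohort-level
  completion fractions qualitative only.
* Left/right-eye merging is out of scope; the reader assumes a single
  already-merged gaze stream, as exported by common vendor software.
* Proprietary binary tracker formats are not parsed; recordings enter as
  delimited text tables.
* The whole-test comparison aggregates with the same duration weighting
  as the repetition analyses; alternative aggregations are not offered.
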
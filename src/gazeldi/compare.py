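"""Between-variant engagement comparison on repetition-level LDI.

The headline analysis compares the duration-weighted LDI of the standard
and the cartoon (gamified) battery per repetition and over the whole test,
using one-tailed Mann-Whitney U tests (LDI is bounded in [0, 1], hence
non-normal) with a Bonferroni correction over the four repetition tests
(alpha_bonf = alpha / 4 = .0125 at alpha = .05). The fixed alternative is
that the cartoon variant has stochastically *smaller* LDI.

The published analysis uses an unpaired U test even though every
participant sees both variants; :func:`compare_repetitions` reproduces the
unpaired test and additionally offers a paired sign-flip permutation test
on per-participant differences behind ``paired=True`` as an extension.

Utilities for summarising the participants' stated preferences and the
retention rate round out the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ldi import TaskLDI, weighted_ldi

__all__ = [
    "GroupSummary",
    "UTestResult",
    "ComparisonReport",
    "summarize",
    "mann_whitney_u",
    "bonferroni_alpha",
    "compare_repetitions",
    "paired_sign_flip_test",
    "preference_summary",
    "retention_increase",
]


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, sample SD, median, and quartiles of one group of values."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class UTestResult:
    """Mann-Whitney U statistic with its one-tailed p and nominal levels."""

    u: float
    p: float
    alternative: str
    alpha: float = 0.05
    n_tests: int = 1

    @property
    def alpha_bonf(self) -> float:
        return bonferroni_alpha(self.alpha, self.n_tests)

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_bonf


def summarize(values: Sequence[float]) -> GroupSummary:
    """Summary statistics: mean, sample SD (n-1), median, quartiles.

    Quartiles use linear interpolation between order statistics. The SD of
    a single value is reported as 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return GroupSummary(
        n=int(v.size),
        mean=float(np.mean(v)),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "less",
    alpha: float = 0.05,
    n_tests: int = 1,
) -> UTestResult:
    """Mann-Whitney U test of ``a`` against ``b``.

    The U statistic is computed from rank sums with midranks for ties. The
    p-value is exact (full enumeration of rank splits) for small tie-free
    samples (n_a + n_b <= 12); otherwise the normal approximation with tie
    and continuity correction is used. ``alternative="less"`` tests that
    ``a`` is stochastically smaller than ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    use_exact = (a.size + b.size) <= 12 and not _has_ties(a, b)
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return UTestResult(
        u=float(res.statistic),
        p=float(res.pvalue),
        alternative=alternative,
        alpha=alpha,
        n_tests=n_tests,
    )


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance level: alpha / n_tests."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if n_tests < 1 or int(n_tests) != n_tests:
        raise ValueError(f"n_tests must be a positive integer, got {n_tests}")
    return alpha / int(n_tests)


def paired_sign_flip_test(
    diffs: Sequence[float],
    alternative: str = "less",
    n_permutations: int = 20_000,
    seed: int = 0,
) -> float:
    """Sign-flip permutation p-value for paired per-participant differences.

    Extension to the published unpaired analysis: under the null of no
    variant effect the sign of each within-participant difference is
    exchangeable. Exact enumeration is used for n <= 16, otherwise Monte
    Carlo with ``n_permutations`` draws.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one difference")
    obs = d.mean()
    n = d.size
    if n <= 16:
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)]
        )
        null = (signs * d).mean(axis=1)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        null = (signs * d).mean(axis=1)
    if alternative == "less":
        return float(np.mean(null <= obs + 1e-12))
    if alternative == "greater":
        return float(np.mean(null >= obs - 1e-12))
    return float(np.mean(np.abs(null) >= abs(obs) - 1e-12))


@dataclass
class ComparisonReport:
    """Repetition-level comparison of the two variants.

    ``table`` has one row per analysis segment (``complete`` plus
    ``repetition_1`` .. ``repetition_4``) with the U test p-value and the
    per-variant summary statistics, mirroring the standard reporting
    layout (p, mean, SD, Q1, Q3 per variant).
    """

    table: pd.DataFrame
    tests: Mapping[str, UTestResult]
    summaries: Mapping[str, Mapping[str, GroupSummary]]
    excluded: tuple[str, ...] = ()

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def _segment_values(
    tasks: Sequence[TaskLDI], repetition: int | None
) -> float:
    if repetition is None:
        return weighted_ldi(list(tasks))
    sub = [t for t in tasks if t.window.repetition == repetition]
    return weighted_ldi(sub)


def compare_repetitions(
    cohort_ldis: Mapping[str, Mapping[str, Sequence[TaskLDI]]],
    alpha: float = 0.05,
    paired: bool = False,
    seed: int = 0,
) -> ComparisonReport:
    """Compare per-repetition LDI between variants over a cohort.

    Parameters
    ----------
    cohort_ldis
        ``participant_id -> {variant -> 48 TaskLDI}`` (absent tasks scored
        at LDI 1). Participants missing either variant are excluded with a
        warning.
    alpha
        Nominal significance level; the four repetition tests carry a
        Bonferroni-corrected level ``alpha / 4``.
    paired
        Additionally compute the paired sign-flip permutation p-value per
        segment (reported in a ``p_paired`` column).

    Returns
    -------
    ComparisonReport
        Per-segment group summaries and one-tailed U tests with the
        alternative that the cartoon variant has smaller LDI.
    """
    complete_ids = []
    excluded = []
    for pid in sorted(cohort_ldis):
        tables = cohort_ldis[pid]
        if "standard" in tables and "cartoon" in tables:
            complete_ids.append(pid)
        else:
            excluded.append(pid)
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} participant(s) missing a variant: "
            f"{excluded}",
            stacklevel=2,
        )
    if not complete_ids:
        raise ValueError("no participant has both variants")

    reps_present = sorted(
        {
            t.window.repetition
            for pid in complete_ids
            for t in cohort_ldis[pid]["standard"]
        }
    )
    segments: list[tuple[str, int | None]] = [("complete", None)] + [
        (f"repetition_{k}", k) for k in reps_present
    ]
    n_rep_tests = len(reps_present)

    rows = []
    tests: dict[str, UTestResult] = {}
    summaries: dict[str, dict[str, GroupSummary]] = {}
    for label, rep in segments:
        std = [
            _segment_values(cohort_ldis[pid]["standard"], rep) for pid in complete_ids
        ]
        car = [
            _segment_values(cohort_ldis[pid]["cartoon"], rep) for pid in complete_ids
        ]
        n_tests = n_rep_tests if rep is not None else 1
        res = mann_whitney_u(car, std, alternative="less", alpha=alpha, n_tests=n_tests)
        tests[label] = res
        summaries[label] = {"standard": summarize(std), "cartoon": summarize(car)}
        row = {
            "segment": label,
            "p": res.p,
            "u": res.u,
            "alpha_bonf": res.alpha_bonf,
            "standard_mean": summaries[label]["standard"].mean,
            "standard_sd": summaries[label]["standard"].sd,
            "standard_median": summaries[label]["standard"].median,
            "standard_q1": summaries[label]["standard"].q1,
            "standard_q3": summaries[label]["standard"].q3,
            "cartoon_mean": summaries[label]["cartoon"].mean,
            "cartoon_sd": summaries[label]["cartoon"].sd,
            "cartoon_median": summaries[label]["cartoon"].median,
            "cartoon_q1": summaries[label]["cartoon"].q1,
            "cartoon_q3": summaries[label]["cartoon"].q3,
        }
        if paired:
            diffs = np.asarray(car) - np.asarray(std)
            row["p_paired"] = paired_sign_flip_test(
                diffs, alternative="less", seed=seed
            )
        rows.append(row)
    return ComparisonReport(
        table=pd.DataFrame(rows),
        tests=tests,
        summaries=summaries,
        excluded=tuple(excluded),
    )


def preference_summary(counts: Mapping[str, int]) -> dict[str, int]:
    """Percentage per answer, rounded to the nearest integer (half away from 0)."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("total count must be positive")
    return {
        k: int(math.floor(100.0 * c / total + 0.5)) for k, c in counts.items()
    }


def retention_increase(rate_new: float, rate_old: float) -> float:
    """Relative increase of a retention rate, in percent of the old rate."""
    if rate_old == 0:
        raise ValueError("old rate must be non-zero")
    return (rate_new - rate_old) / rate_old * 100.0
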
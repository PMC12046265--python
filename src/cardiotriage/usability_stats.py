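"""Usability statistics: SUS scoring, pooled summaries, two-group CIs,
adjective anchors, and usability-error tallies.

SUS scoring follows the standard instrument: odd items contribute
``response - 1``, even items ``5 - response``, and the sum is scaled by 2.5
onto 0-100. Group pooling uses the exact sum-of-squares decomposition with
sample (n-1) denominators at both levels, and the two-group comparison is a
pooled-variance Student t interval (df = n1 + n2 - 2).

Display rounding uses truncation toward zero at the printed precision
(:func:`truncate_decimal`); full precision is retained internally.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, NamedTuple, Sequence

import pandas as pd
from scipy import stats

from .core_model import ValidationError

__all__ = [
    "SusResponse",
    "GroupSummary",
    "UsabilityError",
    "sus_score",
    "pool_group_summaries",
    "two_sample_t_ci",
    "adjective_label",
    "adjective_value",
    "tally_errors",
    "summarize_scores",
    "load_sus_responses",
    "load_error_log",
    "truncate_decimal",
    "ADJECTIVE_LABELS",
]

N_SUS_ITEMS = 10

ADJECTIVE_LABELS = (
    "worst imaginable",
    "awful",
    "poor",
    "ok",
    "good",
    "excellent",
    "best imaginable",
)

ERROR_TYPES = ("navigation", "presentation", "control_use")
ERROR_PRIORITIES = ("high", "medium", "low")
SCENARIOS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class SusResponse:
    """One participant's 10-item SUS vector plus optional adjective anchor."""

    items: tuple[int, ...]
    adjective: int | None = None

    def __post_init__(self) -> None:
        if len(self.items) != N_SUS_ITEMS:
            raise ValidationError(f"SUS response needs exactly {N_SUS_ITEMS} items")
        for i, item in enumerate(self.items, start=1):
            if not isinstance(item, int) or isinstance(item, bool) or not 1 <= item <= 5:
                raise ValidationError(f"SUS item {i} = {item!r} outside [1, 5]")
        if self.adjective is not None and not 1 <= self.adjective <= 7:
            raise ValidationError(f"adjective rating {self.adjective} outside [1, 7]")


@dataclass(frozen=True)
class GroupSummary:
    """(mean, sample SD, n) for one group of scores."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be nonnegative")
        if self.n < 1:
            raise ValidationError("n must be positive")


@dataclass(frozen=True)
class UsabilityError:
    scenario: int
    type: str
    description: str
    priority: str

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"scenario {self.scenario} outside 1-5")
        if self.type not in ERROR_TYPES:
            raise ValidationError(f"unknown error type {self.type!r}")
        if self.priority not in ERROR_PRIORITIES:
            raise ValidationError(f"unknown priority {self.priority!r}")


def sus_score(response: SusResponse) -> float:
    """Score a 10-item SUS response onto the 0-100 scale.

    Odd items (1-indexed) contribute ``item - 1``; even items ``5 - item``;
    the total is multiplied by 2.5.
    """
    total = 0
    for i, item in enumerate(response.items, start=1):
        total += (item - 1) if i % 2 == 1 else (5 - item)
    return 2.5 * total


def summarize_scores(scores: Sequence[float]) -> GroupSummary:
    """Sample mean and SD (n-1 denominator) of a list of scores."""
    n = len(scores)
    if n < 2:
        raise ValidationError("need at least 2 scores to summarize")
    mean = sum(scores) / n
    ss = sum((s - mean) ** 2 for s in scores)
    return GroupSummary(mean=mean, sd=math.sqrt(ss / (n - 1)), n=n)


def pool_group_summaries(groups: Sequence[GroupSummary]) -> GroupSummary:
    """Pool per-group (mean, SD, n) summaries into one combined summary.

    Exact: combined mean is the n-weighted average, and the combined sample
    SD comes from the sum-of-squares decomposition

        SS_total = sum (n_i - 1) sd_i^2  +  sum n_i (m_i - m_bar)^2

    divided by (sum n_i - 1). Equivalent to computing mean/SD on any raw
    samples realizing the group summaries.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups to pool")
    for g in groups:
        if g.n < 2:
            raise ValidationError("every group must have n >= 2")
    n_total = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n_total
    ss_within = sum((g.n - 1) * g.sd**2 for g in groups)
    ss_between = sum(g.n * (g.mean - mean) ** 2 for g in groups)
    sd = math.sqrt((ss_within + ss_between) / (n_total - 1))
    return GroupSummary(mean=mean, sd=sd, n=n_total)


class TTestCI(NamedTuple):
    t_statistic: float
    df: int
    ci_low: float
    ci_high: float


def two_sample_t_ci(
    g1: GroupSummary,
    g2: GroupSummary,
    confidence: float = 0.95,
) -> TTestCI:
    """Pooled-variance two-sample Student t interval for ``g1.mean - g2.mean``.

    sp^2 = [(n1-1)s1^2 + (n2-1)s2^2] / (n1+n2-2); se = sp*sqrt(1/n1 + 1/n2);
    df = n1 + n2 - 2; CI = diff +/- t_crit * se.
    """
    if not 0 < confidence < 1:
        raise ValidationError("confidence must lie in (0, 1)")
    if g1.n < 2 or g2.n < 2:
        raise ValidationError("both groups need n >= 2")
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    se = math.sqrt(sp2) * math.sqrt(1 / g1.n + 1 / g2.n)
    diff = g1.mean - g2.mean
    t_stat = diff / se if se > 0 else math.inf * (1 if diff > 0 else -1) if diff else 0.0
    t_crit = float(stats.t.ppf(0.5 + confidence / 2, df))
    return TTestCI(
        t_statistic=t_stat,
        df=df,
        ci_low=diff - t_crit * se,
        ci_high=diff + t_crit * se,
    )


def adjective_label(value: int) -> str:
    """Map an adjective-anchor rating 1-7 to its label."""
    if not isinstance(value, int) or isinstance(value, bool) or not 1 <= value <= 7:
        raise ValidationError(f"adjective rating {value!r} outside [1, 7]")
    return ADJECTIVE_LABELS[value - 1]


def adjective_value(label: str) -> int:
    """Inverse of :func:`adjective_label`."""
    key = label.strip().lower()
    try:
        return ADJECTIVE_LABELS.index(key) + 1
    except ValueError:
        raise ValidationError(f"unknown adjective label {label!r}") from None


def tally_errors(log: Iterable[UsabilityError]) -> dict[tuple[int, str, str], int]:
    """Cross-tabulate errors by (scenario, type, priority); zeros included.

    The returned table is exhaustive over all 5 x 3 x 3 cells, and its
    values sum to the number of logged errors.
    """
    counts: Counter[tuple[int, str, str]] = Counter(
        (e.scenario, e.type, e.priority) for e in log
    )
    return {
        (s, t, p): counts.get((s, t, p), 0)
        for s in SCENARIOS
        for t in ERROR_TYPES
        for p in ERROR_PRIORITIES
    }


def truncate_decimal(value: float, ndigits: int) -> float:
    """Truncate toward zero at ``ndigits`` decimal places (display rounding)."""
    factor = 10**ndigits
    return math.trunc(value * factor) / factor


def load_sus_responses(path: str | Path) -> list[SusResponse]:
    """Read SUS responses from CSV: columns q1..q10 plus optional adjective."""
    frame = pd.read_csv(path)
    cols = [f"q{i}" for i in range(1, N_SUS_ITEMS + 1)]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValidationError(f"SUS table missing column(s): {missing}")
    responses = []
    for _, row in frame.iterrows():
        adjective = None
        if "adjective" in frame.columns and pd.notna(row["adjective"]):
            adjective = int(row["adjective"])
        responses.append(
            SusResponse(items=tuple(int(row[c]) for c in cols), adjective=adjective)
        )
    return responses


def load_error_log(path: str | Path) -> list[UsabilityError]:
    """Read a usability-error log from CSV: scenario, type, description, priority."""
    frame = pd.read_csv(path)
    return [
        UsabilityError(
            scenario=int(row["scenario"]),
            type=str(row["type"]),
            description=str(row.get("description", "")),
            priority=str(row["priority"]),
        )
        for _, row in frame.iterrows()
    ]
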
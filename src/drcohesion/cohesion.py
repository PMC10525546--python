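"""The two-variable dialogic-weight social cohesion index.

For one analysis week, annotations are tabulated into per-DR counts.  Each
DR belongs to one of two dimensions — *anticipation of future scenarios*
(x) or *shared management* (y) — and carries a dialogic weight dW on a
0–20 scale.  The weekly statistic is computed as

.. math::

    \\bar{x} = \\frac{\\sum_{d \\in X} n_d\\, w_d}{\\sum_{d \\in X} n_d},
    \\qquad
    \\bar{y} = \\frac{\\sum_{d \\in Y} n_d\\, w_d}{\\sum_{d \\in Y} n_d},

the frequency-weighted mean weight within each variable, and aggregated to
a scalar index in [0, 20].  The default aggregation ("xy-mean") is the
arithmetic mean of the two variable means; alternative rules can be
registered, and every result records which rule produced it.  A variable
with zero mass is reported as undefined (never imputed as zero); the index
then falls back to the defined mean with a visible flag.

Week-over-week deltas and multi-week trend series complete the
surveillance surface.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, timedelta
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .annotation import AnnotatedOccurrence
from .errors import CohesionError, ConfigurationError, EmptyWeekError
from .taxonomy import DialogicWeightRegistry, Variable

__all__ = [
    "Week",
    "WeeklyTabulation",
    "VariableMeans",
    "CohesionResult",
    "Delta",
    "TrendSeries",
    "round_half_up",
    "tabulate",
    "variable_means",
    "cohesion_index",
    "register_strategy",
    "available_strategies",
    "weekly_delta",
    "trend_series",
]

#: Below-reporting-precision threshold under which a delta counts as stable.
STABLE_THRESHOLD = 0.005


def round_half_up(value: float, digits: int = 2) -> float:
    """Round half away from zero at ``digits`` decimals (reporting rule).

    Computation stays at full precision; rounding happens only at the
    reporting boundary.
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Week:
    """An inclusive 7-day analysis window (day 1 through day 7)."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ConfigurationError(f"week end {self.end} precedes start {self.start}")

    @classmethod
    def starting(cls, start: date, days: int = 7) -> "Week":
        return cls(start, start + timedelta(days=days - 1))

    def __contains__(self, day: date) -> bool:
        return self.start <= day <= self.end

    @property
    def id(self) -> str:
        return f"{self.start.isoformat()}/{self.end.isoformat()}"


@dataclass(frozen=True)
class WeeklyTabulation:
    """Per-DR counts and 2-dp percentage shares for one week."""

    week: Week
    counts: Mapping[str, int]
    total: int
    shares: Mapping[str, float]
    n_out_of_window: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "dr": [d for d, _ in rows],
                "count": [c for _, c in rows],
                "share": [self.shares[d] for d, _ in rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def tabulate(
    annotations: Iterable[AnnotatedOccurrence],
    week: Week,
    registry: DialogicWeightRegistry,
) -> WeeklyTabulation:
    """Tabulate per-DR frequencies for one week.

    Labels are canonicalised through the registry; records dated outside
    the window are rejected (counted, not silently dropped); undated
    records are assumed pre-filtered and kept.  Shares are 100·count/total
    rounded half-up to 2 dp.  The result is invariant to input order.
    An empty week is an error: the index is undefined without mass.
    """
    counts: Counter[str] = Counter()
    out_of_window = 0
    for a in annotations:
        if a.published_at is not None and a.published_at not in week:
            out_of_window += 1
            continue
        counts[registry.resolve(a.dr_label)] += 1
    total = sum(counts.values())
    if total == 0:
        raise EmptyWeekError(
            f"no annotations within week {week.id} "
            f"({out_of_window} outside the window)"
        )
    shares = {d: round_half_up(100.0 * c / total) for d, c in counts.items()}
    return WeeklyTabulation(
        week=week,
        counts=dict(sorted(counts.items())),
        total=total,
        shares=shares,
        n_out_of_window=out_of_window,
    )


@dataclass(frozen=True)
class VariableMeans:
    """Frequency-weighted mean dW per variable; ``None`` marks zero mass."""

    x_mean: float | None
    y_mean: float | None
    n_x: int
    n_y: int


def variable_means(
    tabulation: WeeklyTabulation, registry: DialogicWeightRegistry
) -> VariableMeans:
    """Compute the per-variable frequency-weighted mean dialogic weights."""
    sums = {Variable.X: 0.0, Variable.Y: 0.0}
    ns = {Variable.X: 0, Variable.Y: 0}
    for name, count in tabulation.counts.items():
        var, weight = registry.get_weight(name)
        sums[var] += count * weight
        ns[var] += count
    return VariableMeans(
        x_mean=sums[Variable.X] / ns[Variable.X] if ns[Variable.X] else None,
        y_mean=sums[Variable.Y] / ns[Variable.Y] if ns[Variable.Y] else None,
        n_x=ns[Variable.X],
        n_y=ns[Variable.Y],
    )


# -- aggregation strategies ---------------------------------------------

StrategyFn = Callable[[VariableMeans], float]
_STRATEGIES: dict[str, StrategyFn] = {}


def register_strategy(name: str, fn: StrategyFn) -> None:
    """Register an aggregation rule mapping variable means to the index."""
    _STRATEGIES[name] = fn


def available_strategies() -> list[str]:
    return sorted(_STRATEGIES)


def _xy_mean(means: VariableMeans) -> float:
    defined = [m for m in (means.x_mean, means.y_mean) if m is not None]
    return sum(defined) / len(defined)


def _pooled_mean(means: VariableMeans) -> float:
    # overall frequency-weighted mean over all annotations, both variables pooled
    total = means.n_x + means.n_y
    acc = 0.0
    if means.x_mean is not None:
        acc += means.x_mean * means.n_x
    if means.y_mean is not None:
        acc += means.y_mean * means.n_y
    return acc / total


register_strategy("xy-mean", _xy_mean)
register_strategy("pooled-mean", _pooled_mean)


@dataclass(frozen=True)
class CohesionResult:
    """The weekly index with its provenance (variable means, strategy)."""

    week: Week
    x_mean: float | None
    y_mean: float | None
    n_x: int
    n_y: int
    index: float
    strategy: str
    single_variable: bool = False

    @property
    def rounded_index(self) -> float:
        return round_half_up(self.index)

    def to_dict(self) -> dict:
        return {
            "week_start": self.week.start.isoformat(),
            "week_end": self.week.end.isoformat(),
            "x_mean": self.x_mean,
            "y_mean": self.y_mean,
            "n_x": self.n_x,
            "n_y": self.n_y,
            "index": self.index,
            "index_2dp": self.rounded_index,
            "strategy": self.strategy,
            "single_variable": self.single_variable,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")


def cohesion_index(
    tabulation: WeeklyTabulation,
    registry: DialogicWeightRegistry,
    strategy: str = "xy-mean",
) -> CohesionResult:
    """Aggregate a weekly tabulation into the social cohesion index.

    The default "xy-mean" strategy averages the two variable means; if one
    variable carries no mass the index equals the defined mean and the
    result is flagged ``single_variable``.
    """
    if strategy not in _STRATEGIES:
        raise ConfigurationError(
            f"unknown strategy {strategy!r}; registered: {', '.join(available_strategies())}"
        )
    means = variable_means(tabulation, registry)
    index = _STRATEGIES[strategy](means)
    return CohesionResult(
        week=tabulation.week,
        x_mean=means.x_mean,
        y_mean=means.y_mean,
        n_x=means.n_x,
        n_y=means.n_y,
        index=index,
        strategy=strategy,
        single_variable=means.x_mean is None or means.y_mean is None,
    )


# -- deltas and trends ---------------------------------------------------


@dataclass(frozen=True)
class Delta:
    """Signed week-over-week index change with a direction flag."""

    delta: float
    direction: str  # increased | decreased | stable


def weekly_delta(current: CohesionResult, previous: CohesionResult) -> Delta:
    """Delta between consecutive weekly results (gap tolerated with warning)."""
    if current.week == previous.week:
        raise CohesionError(f"identical weeks: {current.week.id}")
    if previous.week.end + timedelta(days=1) != current.week.start:
        warnings.warn(
            f"weeks {previous.week.id} and {current.week.id} are not consecutive",
            stacklevel=2,
        )
    delta = current.index - previous.index
    if abs(delta) < STABLE_THRESHOLD:
        direction = "stable"
    elif delta > 0:
        direction = "increased"
    else:
        direction = "decreased"
    return Delta(delta=delta, direction=direction)


@dataclass(frozen=True)
class TrendSeries:
    """Ordered weekly (week, index) pairs with optional phase labels."""

    rows: tuple[tuple[Week, float, str | None], ...] = field(default_factory=tuple)

    def weeks_above(self, threshold: float) -> list[Week]:
        """Weeks whose index strictly exceeds the threshold."""
        return [w for w, idx, _ in self.rows if idx > threshold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week_start": [w.start.isoformat() for w, _, _ in self.rows],
                "week_end": [w.end.isoformat() for w, _, _ in self.rows],
                "index": [round_half_up(i) for _, i, _ in self.rows],
                "phase": [p or "" for _, _, p in self.rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def trend_series(
    results: Sequence[CohesionResult],
    phase_bands: Sequence[tuple[str, date, date]] | None = None,
) -> TrendSeries:
    """Assemble ordered weekly results into a trend series.

    ``phase_bands`` is an optional list of labelled date intervals (e.g.
    pandemic phases); a week takes the label of the first band containing
    its start date.  Input must already be sorted by week start.
    """
    starts = [r.week.start for r in results]
    if starts != sorted(starts):
        raise CohesionError("results must be sorted by week start")
    rows = []
    for r in results:
        phase = None
        for label, start, end in phase_bands or ():
            if start <= r.week.start <= end:
                phase = label
                break
        rows.append((r.week, r.index, phase))
    return TrendSeries(rows=tuple(rows))
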
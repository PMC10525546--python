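"""Observatory-style weekly reports and the end-to-end pipeline driver.

A weekly report is a deterministic markdown snapshot of one analysis week:
the per-DR frequency table, the two variable means, the social cohesion
index (2 dp), the week-over-week delta sentence when a previous result is
available, and optional thread tallies (pass-through content-analysis
tags).  Every number in the rendered report equals the corresponding
CSV/JSON artifact exactly.

:func:`run_pipeline` composes the whole workflow from a YAML-style config:
generate (or load) → filter → (sample) → tabulate → index → delta →
report, writing every artifact and propagating stage-named errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .annotation import AnnotatedOccurrence, read_annotations, write_annotations
from .cohesion import (
    CohesionResult,
    Delta,
    Week,
    WeeklyTabulation,
    cohesion_index,
    round_half_up,
    tabulate,
    trend_series,
    weekly_delta,
)
from .corpus import FilterCriteria, filter_occurrences
from .errors import CohesionError, ConfigurationError, StageError
from .synthetic_data import (
    WORKED_EXAMPLE_WEEK,
    GeneratorConfig,
    generate_corpus,
    generate_trend,
    replay_worked_example,
)
from .taxonomy import DialogicWeightRegistry, load_registry

__all__ = ["WeeklyReport", "build_report", "render_report", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeeklyReport:
    """All inputs of one rendered weekly snapshot."""

    tabulation: WeeklyTabulation
    result: CohesionResult
    previous: CohesionResult | None = None
    delta: Delta | None = None
    threads: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.tabulation.week != self.result.week:
            raise CohesionError("tabulation and result refer to different weeks")
        if self.tabulation.total != self.result.n_x + self.result.n_y:
            raise CohesionError("report totals inconsistent with tabulation")


def build_report(
    tabulation: WeeklyTabulation,
    result: CohesionResult,
    previous: CohesionResult | None = None,
    threads: Mapping[str, int] | None = None,
) -> WeeklyReport:
    """Assemble a report, computing the delta when a previous week is given."""
    delta = weekly_delta(result, previous) if previous is not None else None
    return WeeklyReport(
        tabulation=tabulation,
        result=result,
        previous=previous,
        delta=delta,
        threads=threads,
    )


def _fmt(value: float | None) -> str:
    return "undefined" if value is None else f"{round_half_up(value):.2f}"


def render_report(report: WeeklyReport, want_delta: bool = False) -> str:
    """Render a report to markdown; byte-identical for identical inputs.

    If a delta is requested but no previous week was supplied, a warning is
    emitted and the delta section omitted.
    """
    if want_delta and report.delta is None:
        warnings.warn("previous week unavailable; delta section omitted", stacklevel=2)
    week = report.tabulation.week
    lines = [
        f"# Weekly social cohesion report — {week.start.isoformat()} to {week.end.isoformat()}",
        "",
        "## Social cohesion index",
        "",
        f"- **Index: {report.result.rounded_index:.2f}** "
        f"(scale 0–20; strategy: {report.result.strategy})",
        f"- Anticipation of future scenarios (x): mean dW {_fmt(report.result.x_mean)} "
        f"over {report.result.n_x} annotation units",
        f"- Shared management (y): mean dW {_fmt(report.result.y_mean)} "
        f"over {report.result.n_y} annotation units",
    ]
    if report.result.single_variable:
        lines.append("- *Single-variable week: one dimension carried no annotations.*")
    if report.delta is not None and report.previous is not None:
        d = report.delta
        if d.direction == "stable":
            sentence = (
                f"The social cohesion index remained stable during the week "
                f"(from {report.previous.rounded_index:.2f} to {report.result.rounded_index:.2f})."
            )
        else:
            sentence = (
                f"The social cohesion index {d.direction} during the week "
                f"(from {report.previous.rounded_index:.2f} to {report.result.rounded_index:.2f}, "
                f"delta {round_half_up(d.delta):+.2f})."
            )
        lines += ["", "## Week-over-week change", "", sentence]
    lines += [
        "",
        "## Distribution of discursive repertoires",
        "",
        f"Total annotation units: **{report.tabulation.total}**",
        "",
        "| Discursive repertoire | Frequency | % |",
        "|---|---:|---:|",
    ]
    rows = sorted(report.tabulation.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for name, count in rows:
        lines.append(f"| {name} | {count} | {report.tabulation.shares[name]:.2f}% |")
    if report.threads:
        lines += ["", "## Content-analysis threads", ""]
        for label, count in sorted(report.threads.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"- {label}: {count}")
    lines.append("")
    return "\n".join(lines)


# -- pipeline ------------------------------------------------------------


def _parse_week(raw: Mapping | None, default: Week | None = None) -> Week:
    if raw is None:
        if default is None:
            raise ConfigurationError("config must specify a week")
        return default
    start = raw["start"] if isinstance(raw["start"], date) else date.fromisoformat(str(raw["start"]))
    if "end" in raw:
        end = raw["end"] if isinstance(raw["end"], date) else date.fromisoformat(str(raw["end"]))
        return Week(start, end)
    return Week.starting(start)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(
    config: Mapping | str | Path,
    out_dir: str | Path,
    registry: DialogicWeightRegistry | None = None,
) -> dict[str, Path]:
    """Run the full weekly workflow from a config mapping or YAML path.

    Config keys (input one of ``replay: true``, ``generator: {...}``,
    ``trend: {...}`` or ``annotations: <path>``)::

        week: {start: 2021-12-31, end: 2022-01-06}
        replay: true
        generator: {n_annotations: 1323, seed: 1}
        trend: {targets: [[2021-12-31, 13.0], ...], n_per_week: 5000, seed: 1}
        annotations: path.jsonl
        strategy: xy-mean
        previous_index: 11.24        # optional, for the delta sentence
        threads: {vaccini: 12}       # optional pass-through tallies

    Artifacts written to ``out_dir``: ``annotations.jsonl``,
    ``tabulation.csv``, ``result.json``, ``report.md``, ``trend.csv`` (for
    multi-week runs) and ``pipeline.log``-style log records.  Returns the
    artifact paths.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text(encoding="utf-8"))
    registry = registry or load_registry()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    strategy = config.get("strategy", "xy-mean")
    artifacts: dict[str, Path] = {}

    with _stage("input"):
        if config.get("replay"):
            weekly: list[tuple[Week, list[AnnotatedOccurrence]]] = [
                (WORKED_EXAMPLE_WEEK, replay_worked_example(registry))
            ]
        elif "trend" in config:
            t = config["trend"]
            targets = [
                (_parse_week({"start": w}), float(target)) for w, target in t["targets"]
            ]
            corpora = generate_trend(
                targets,
                n_per_week=int(t.get("n_per_week", 5000)),
                seed=int(t.get("seed", config.get("seed", 0))),
                registry=registry,
            )
            weekly = [(targets[i][0], corpora[i]) for i in range(len(corpora))]
        elif "generator" in config:
            g = dict(config["generator"])
            week = _parse_week(config.get("week"), WORKED_EXAMPLE_WEEK)
            g.setdefault("seed", config.get("seed", 0))
            gen_config = GeneratorConfig(week=week, **g)
            weekly = [(week, generate_corpus(gen_config, registry))]
        elif "annotations" in config:
            week = _parse_week(config.get("week"))
            weekly = [(week, read_annotations(config["annotations"], registry))]
        else:
            raise ConfigurationError(
                "config needs one of: replay, trend, generator, annotations"
            )

    if "filter" in config:
        with _stage("filter"):
            f = config["filter"]
            filtered: list[tuple[Week, list[AnnotatedOccurrence]]] = []
            for week, annotations in weekly:
                criteria = FilterCriteria(
                    window=(week.start, week.end),
                    keywords=f.get("keywords", None) or None,
                )
                occurrences = [a.occurrence for a in annotations if a.occurrence is not None]
                kept, tally = filter_occurrences(occurrences, criteria)
                kept_ids = {o.id for o in kept}
                filtered.append(
                    (week, [a for a in annotations if a.occurrence is None or a.occurrence_id in kept_ids])
                )
                log.info("week %s exclusion tally: %s", week.id, tally)
            weekly = filtered

    results: list[CohesionResult] = []
    tabulations: list[WeeklyTabulation] = []
    with _stage("tabulate"):
        for week, annotations in weekly:
            tabulations.append(tabulate(annotations, week, registry))
    with _stage("index"):
        for tab in tabulations:
            results.append(cohesion_index(tab, registry, strategy=strategy))

    with _stage("artifacts"):
        last_week, last_annotations = weekly[-1]
        ann_path = out / "annotations.jsonl"
        write_annotations(last_annotations, ann_path)
        artifacts["annotations"] = ann_path

        tab_path = out / "tabulation.csv"
        tabulations[-1].to_csv(tab_path)
        artifacts["tabulation"] = tab_path

        result_path = out / "result.json"
        results[-1].to_json(result_path)
        artifacts["result"] = result_path

        if len(results) > 1:
            trend_path = out / "trend.csv"
            trend_series(results).to_csv(trend_path)
            artifacts["trend"] = trend_path

    with _stage("report"):
        previous = results[-2] if len(results) > 1 else None
        if previous is None and "previous_index" in config:
            span = last_week.end - last_week.start
            prev_week = Week(
                last_week.start - span - timedelta(days=1),
                last_week.start - timedelta(days=1),
            )
            previous = CohesionResult(
                week=prev_week,
                x_mean=None,
                y_mean=None,
                n_x=0,
                n_y=0,
                index=float(config["previous_index"]),
                strategy=strategy,
                single_variable=False,
            )
        report = build_report(
            tabulations[-1], results[-1], previous=previous, threads=config.get("threads")
        )
        report_path = out / "report.md"
        report_path.write_text(render_report(report), encoding="utf-8")
        artifacts["report"] = report_path

    log.info("pipeline complete; artifacts: %s", sorted(artifacts))
    return artifacts
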
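"""Text occurrences: IO, selection criteria, quota sampling, keyword helper.

An *occurrence* is one retrieved text unit (a post, a comment, an article
snippet) from one of five configured source classes.  The surveillance
design retrieves roughly 2,500 social-media occurrences and 5,000 news
occurrences per day — 52,500 per analysis week — apportioned across sources
by fixed shares (Facebook 25%, Twitter 10%, Instagram 10%, national/regional
news 30%, local news 25%).

Selection criteria applied before annotation:

* **time** — published within the 7-day analysis window (day 1 to day 7);
* **content** — the text matches at least one topic keyword;
* **author** — an admitted author role (citizen, regional president,
  alderman, mayor, journalist, health professional);
* **geography** — an admitted province (the 7 Veneto provinces by default).

Quota sampling apportions a target count across sources by the
largest-remainder method and samples uniformly without replacement within
each source, reproducibly under a fixed seed.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RecordError

__all__ = [
    "Source",
    "AuthorRole",
    "VENETO_PROVINCES",
    "DEFAULT_KEYWORDS",
    "DEFAULT_SOURCE_SHARES",
    "Occurrence",
    "FilterCriteria",
    "SamplingPlan",
    "read_occurrences",
    "write_occurrences",
    "filter_occurrences",
    "build_sampling_plan",
    "largest_remainder",
    "sample_by_quota",
    "select_keywords",
]

log = logging.getLogger(__name__)


class Source(str, enum.Enum):
    FACEBOOK = "facebook"
    TWITTER = "twitter"
    INSTAGRAM = "instagram"
    NATIONAL_REGIONAL_NEWS = "national_regional_news"
    LOCAL_NEWS = "local_news"


class AuthorRole(str, enum.Enum):
    CITIZEN = "citizen"
    PRESIDENT = "president"
    ALDERMAN = "alderman"
    MAYOR = "mayor"
    JOURNALIST = "journalist"
    HEALTH_PROFESSIONAL = "health_professional"


VENETO_PROVINCES: tuple[str, ...] = (
    "Belluno",
    "Padova",
    "Rovigo",
    "Treviso",
    "Venezia",
    "Verona",
    "Vicenza",
)

#: The 8 shipped topic query strings (Italian), used for content filtering.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "Emergenza COVID-19",
    "Pandemia COVID-19",
    "COVID-19 Veneto",
    "Virus Veneto",
    "Contagi Veneto",
    "Virus COVID-19",
    "Emergenza sanitaria Veneto",
    "Crisi sanitaria",
)

#: Source shares of the retrieval design (sum to 1).
DEFAULT_SOURCE_SHARES: dict[Source, float] = {
    Source.FACEBOOK: 0.25,
    Source.TWITTER: 0.10,
    Source.INSTAGRAM: 0.10,
    Source.NATIONAL_REGIONAL_NEWS: 0.30,
    Source.LOCAL_NEWS: 0.25,
}


@dataclass(frozen=True)
class Occurrence:
    """One retrieved text unit."""

    id: str
    text: str
    source: Source
    author_role: AuthorRole
    province: str
    published_at: date


# -- IO ------------------------------------------------------------------

_FIELDS = ("id", "text", "source", "author_role", "province", "published_at")


def _occurrence_from_record(rec: Mapping[str, object], n: int) -> Occurrence:
    missing = [f for f in _FIELDS if f not in rec or rec[f] in (None, "")]
    if missing:
        raise RecordError(n, f"missing field(s): {', '.join(missing)}")
    try:
        source = Source(str(rec["source"]))
    except ValueError:
        raise RecordError(n, f"invalid source {rec['source']!r}") from None
    try:
        role = AuthorRole(str(rec["author_role"]))
    except ValueError:
        raise RecordError(n, f"invalid author_role {rec['author_role']!r}") from None
    raw_date = rec["published_at"]
    if isinstance(raw_date, date):
        published = raw_date
    else:
        try:
            published = date.fromisoformat(str(raw_date))
        except ValueError:
            raise RecordError(n, f"invalid date {raw_date!r} (expected YYYY-MM-DD)") from None
    return Occurrence(
        id=str(rec["id"]),
        text=str(rec["text"]),
        source=source,
        author_role=role,
        province=str(rec["province"]),
        published_at=published,
    )


def read_occurrences(path: str | Path, format: str | None = None) -> list[Occurrence]:
    """Read occurrences from JSONL or CSV, validating every record.

    The format is inferred from the suffix unless given.  Malformed records
    raise :class:`RecordError` naming the record number; duplicate ids are
    rejected.  An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    records: list[Occurrence] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for n, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as e:
                    raise RecordError(n, f"invalid JSON: {e}") from None
                records.append(_occurrence_from_record(rec, n))
    elif fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for n, rec in enumerate(csv.DictReader(fh), start=1):
                records.append(_occurrence_from_record(rec, n))
    else:
        raise ConfigurationError(f"unsupported occurrence format {fmt!r} (jsonl or csv)")
    seen: set[str] = set()
    for n, occ in enumerate(records, start=1):
        if occ.id in seen:
            raise RecordError(n, f"duplicate occurrence id {occ.id!r}")
        seen.add(occ.id)
    if not records:
        log.warning("no occurrences read from %s", path)
    return records


def write_occurrences(occurrences: Sequence[Occurrence], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    rows = [
        {
            "id": o.id,
            "text": o.text,
            "source": o.source.value,
            "author_role": o.author_role.value,
            "province": o.province,
            "published_at": o.published_at.isoformat(),
        }
        for o in occurrences
    ]
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_FIELDS))
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ConfigurationError(f"unsupported occurrence format {fmt!r} (jsonl or csv)")


# -- filtering -----------------------------------------------------------


def _norm(text: str) -> str:
    return " ".join(text.split()).casefold()


@dataclass(frozen=True)
class FilterCriteria:
    """Selection criteria for one analysis week.

    ``window`` is the inclusive (start, end) date pair; the default design
    is a 7-day window.  ``keywords=None`` disables content filtering;
    an explicitly empty keyword list is a configuration error.
    """

    window: tuple[date, date]
    keywords: Sequence[str] | None = DEFAULT_KEYWORDS
    roles: frozenset[AuthorRole] = frozenset(AuthorRole)
    provinces: frozenset[str] | None = frozenset(VENETO_PROVINCES)

    def __post_init__(self) -> None:
        start, end = self.window
        if end < start:
            raise ConfigurationError(f"window end {end} precedes start {start}")
        if self.keywords is not None and len(self.keywords) == 0:
            raise ConfigurationError("keyword filtering enabled with an empty keyword list")


def filter_occurrences(
    occurrences: Iterable[Occurrence], criteria: FilterCriteria
) -> tuple[list[Occurrence], dict[str, int]]:
    """Apply the selection criteria; return (retained, exclusion tally).

    Criteria are checked in order time → content → author → geography and a
    record is tallied against the first criterion it fails.  Keyword match
    is case-insensitive substring after whitespace normalisation.  Order is
    preserved and the operation is idempotent.
    """
    start, end = criteria.window
    keywords = None if criteria.keywords is None else [_norm(k) for k in criteria.keywords]
    provinces = (
        None if criteria.provinces is None else {p.casefold() for p in criteria.provinces}
    )
    tally = {"time": 0, "content": 0, "author": 0, "geography": 0}
    retained: list[Occurrence] = []
    for occ in occurrences:
        if not (start <= occ.published_at <= end):
            tally["time"] += 1
            continue
        if keywords is not None:
            text = _norm(occ.text)
            if not any(k in text for k in keywords):
                tally["content"] += 1
                continue
        if occ.author_role not in criteria.roles:
            tally["author"] += 1
            continue
        if provinces is not None and occ.province.casefold() not in provinces:
            tally["geography"] += 1
            continue
        retained.append(occ)
    excluded = sum(tally.values())
    if excluded:
        log.info("filter excluded %d occurrence(s): %s", excluded, tally)
    return retained, tally


# -- sampling plan -------------------------------------------------------


@dataclass(frozen=True)
class SamplingPlan:
    """Daily pool quotas, per-source shares and the window length.

    The default plan is the published design: 2,500/day for the pooled
    social-media sources plus 5,000/day for the pooled news sources over a
    7-day window — 52,500 occurrences per week.
    """

    daily_quota_per_pool: Mapping[str, int] = field(
        default_factory=lambda: {"social_media_pool": 2500, "news_pool": 5000}
    )
    source_shares: Mapping[Source, float] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_SHARES)
    )
    window_days: int = 7

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ConfigurationError("window_days must be positive")
        if not self.daily_quota_per_pool or any(q <= 0 for q in self.daily_quota_per_pool.values()):
            raise ConfigurationError("daily pool quotas must be positive")
        missing = set(Source) - set(self.source_shares)
        if missing:
            raise ConfigurationError(
                f"source shares missing for: {', '.join(sorted(s.value for s in missing))}"
            )
        total = sum(self.source_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"source shares sum to {total!r}, expected 1.0")

    @property
    def weekly_total(self) -> int:
        return sum(self.daily_quota_per_pool.values()) * self.window_days


def build_sampling_plan(
    daily_quota_per_pool: Mapping[str, int] | None = None,
    source_shares: Mapping[Source, float] | None = None,
    window_days: int = 7,
) -> SamplingPlan:
    """Build a validated :class:`SamplingPlan`; defaults give 52,500/week."""
    plan = SamplingPlan()
    if daily_quota_per_pool is not None:
        plan = replace(plan, daily_quota_per_pool=dict(daily_quota_per_pool))
    if source_shares is not None:
        plan = replace(plan, source_shares={Source(k): v for k, v in source_shares.items()})
    if window_days != 7:
        plan = replace(plan, window_days=window_days)
    return plan


def largest_remainder(shares: Mapping[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` across keys proportionally to ``shares``.

    Largest-remainder (Hamilton) method: floor each exact quota, then hand
    the leftover units to the largest fractional remainders, ties broken
    alphabetically by key.  Every count differs from its exact quota by
    less than 1.
    """
    if total < 0:
        raise ConfigurationError("apportionment total must be non-negative")
    share_sum = sum(shares.values())
    if share_sum <= 0:
        raise ConfigurationError("shares must have positive sum")
    exact = {k: total * v / share_sum for k, v in shares.items()}
    counts = {k: int(np.floor(q)) for k, q in exact.items()}
    leftover = total - sum(counts.values())
    by_remainder = sorted(exact, key=lambda k: (-(exact[k] - counts[k]), str(k)))
    for k in by_remainder[:leftover]:
        counts[k] += 1
    return counts


def sample_by_quota(
    occurrences: Sequence[Occurrence],
    plan: SamplingPlan,
    seed: int,
    target: int | None = None,
) -> tuple[list[Occurrence], dict[Source, int]]:
    """Sample a quota-balanced corpus; return (sample, per-source shortfalls).

    The target (default: the plan's weekly total) is apportioned across
    sources by largest remainder; within each source the draw is uniform
    without replacement.  If a source lacks supply, everything available is
    taken and the shortfall reported.  Input order is preserved in the
    output; a fixed seed gives a byte-identical sample.
    """
    if seed < 0:
        raise ConfigurationError("seed must be non-negative")
    if not plan.source_shares:
        raise ConfigurationError("sampling plan has no source shares")
    if target is None:
        target = plan.weekly_total
    if target < 0:
        raise ConfigurationError("target must be non-negative")

    quotas = largest_remainder(
        {s.value: w for s, w in plan.source_shares.items()}, target
    )
    by_source: dict[Source, list[int]] = {s: [] for s in plan.source_shares}
    for i, occ in enumerate(occurrences):
        if occ.source in by_source:
            by_source[occ.source].append(i)

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    shortfalls: dict[Source, int] = {}
    for source in sorted(by_source, key=lambda s: s.value):
        quota = quotas[source.value]
        pool = by_source[source]
        take = min(quota, len(pool))
        if take < quota:
            shortfalls[source] = quota - take
            log.warning(
                "source %s: quota %d but only %d available", source.value, quota, len(pool)
            )
        if take:
            chosen.extend(rng.choice(pool, size=take, replace=False).tolist())
    chosen.sort()
    return [occurrences[i] for i in chosen], shortfalls


# -- keyword helper ------------------------------------------------------


def select_keywords(
    reference_corpus: str,
    k: int = 8,
    stoplist: Iterable[str] = (),
) -> pd.DataFrame:
    """Rank candidate query terms by raw frequency in a reference corpus.

    Tokens are lowercased word characters; stopwords removed; ranking by
    descending count with alphabetical tie-break.  Returns the top ``k``
    as a frame with columns ``term``, ``count`` and an empty ``relevant``
    column for the analysts' manual relevance marking — the final keyword
    choice is an expert judgement, not automated here.
    """
    stop = {w.casefold() for w in stoplist}
    tokens = [t for t in re.findall(r"\w+", reference_corpus.casefold()) if t not in stop]
    if not tokens:
        raise ConfigurationError("reference corpus is empty after stopword removal")
    counts = Counter(tokens)
    if k > len(counts):
        log.warning("k=%d exceeds vocabulary size %d; returning all terms", k, len(counts))
        k = len(counts)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(
        {"term": [t for t, _ in ranked], "count": [c for _, c in ranked], "relevant": ""}
    )
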
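"""Seeded synthetic annotated corpora with the structure the analysis assumes.

No text corpus is distributable with this package, so every stage is
exercised on generated data:

* :func:`generate_corpus` draws DR labels from a configurable multinomial
  (defaulting to the empirical worked-example week distribution), stamps
  each record with a date uniform over the analysis week, a source, an
  author role and a province drawn from their mixes, and embeds one of the
  shipped topic keywords in the placeholder text so content filters pass
  by construction.
* :func:`replay_worked_example` rebuilds, deterministically and exactly,
  the published worked-example week (31 Dec 2021 – 6 Jan 2022; 1,323
  annotation units) under its original raw labels, so alias resolution and
  the index computation can be checked end to end.
* :func:`generate_trend` produces weekly corpora whose *expected* default
  index equals a requested target, via two-point mixtures of adjacent
  registry weights within each variable.

All randomness flows through one integer seed; a fixed seed yields an
identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .annotation import AnnotatedOccurrence
from .corpus import (
    DEFAULT_KEYWORDS,
    DEFAULT_SOURCE_SHARES,
    VENETO_PROVINCES,
    AuthorRole,
    Occurrence,
    Source,
)
from .cohesion import Week
from .errors import ConfigurationError
from .taxonomy import DialogicWeightRegistry, Variable, load_registry

__all__ = [
    "WORKED_EXAMPLE_COUNTS",
    "WORKED_EXAMPLE_WEEK",
    "GeneratorConfig",
    "generate_corpus",
    "replay_worked_example",
    "generate_trend",
]

#: The published worked-example week's per-DR frequencies, under the raw
#: labels of the source table (total 1,323 annotation units).
WORKED_EXAMPLE_COUNTS: dict[str, int] = {
    "Description": 242,
    "Proposal": 4,
    "Anticipation": 1,
    "Consideration": 6,
    "Declaration of aims": 8,
    "Possibility": 10,
    "Evaluation": 50,
    "Confirmation": 31,
    "Prescription": 24,
    "Specification": 63,
    "Implication": 7,
    "Reshaping": 22,
    "Comment": 254,
    "Judgement": 71,
    "Cause of action": 39,
    "Deresponsibility": 11,
    "Certify Reality": 321,
    "Opinion": 23,
    "Justification": 13,
    "Contraposition": 16,
    "Generalisation": 40,
    "Non answer": 29,
    "Prevision": 38,
}

WORKED_EXAMPLE_WEEK = Week(date(2021, 12, 31), date(2022, 1, 6))

#: Citizen-dominated author mix: most retrieved units are citizen comments,
#: with smaller journalist and institutional contributions.
DEFAULT_ROLE_MIX: dict[AuthorRole, float] = {
    AuthorRole.CITIZEN: 0.80,
    AuthorRole.JOURNALIST: 0.10,
    AuthorRole.MAYOR: 0.04,
    AuthorRole.ALDERMAN: 0.03,
    AuthorRole.HEALTH_PROFESSIONAL: 0.02,
    AuthorRole.PRESIDENT: 0.01,
}


def _worked_example_probabilities(registry: DialogicWeightRegistry) -> dict[str, float]:
    total = sum(WORKED_EXAMPLE_COUNTS.values())
    probs: dict[str, float] = {}
    for raw, count in WORKED_EXAMPLE_COUNTS.items():
        probs[registry.resolve(raw)] = probs.get(registry.resolve(raw), 0.0) + count / total
    return probs


def _validate_mix(name: str, mix: Mapping, tol: float = 1e-9) -> None:
    if not mix:
        raise ConfigurationError(f"{name} must be non-empty")
    if any(p < 0 for p in mix.values()):
        raise ConfigurationError(f"{name} has negative probabilities")
    total = sum(mix.values())
    if abs(total - 1.0) > tol:
        raise ConfigurationError(f"{name} sums to {total!r}, expected 1.0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic corpus generator.

    Defaults emulate the published design: DR probabilities from the
    worked-example week's empirical distribution, 1,323 annotation units
    over that same 7-day window, sources at the retrieval-design shares,
    a citizen-dominated role mix and uniform Veneto provinces.
    """

    dr_probabilities: Mapping[str, float] | None = None  # None -> worked-example shares
    n_annotations: int = 1323
    week: Week = WORKED_EXAMPLE_WEEK
    source_shares: Mapping[Source, float] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_SHARES)
    )
    role_mix: Mapping[AuthorRole, float] = field(default_factory=lambda: dict(DEFAULT_ROLE_MIX))
    province_mix: Mapping[str, float] = field(
        default_factory=lambda: {p: 1.0 / len(VENETO_PROVINCES) for p in VENETO_PROVINCES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_annotations <= 0:
            raise ConfigurationError("n_annotations must be positive")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")
        if self.dr_probabilities is not None:
            _validate_mix("dr_probabilities", self.dr_probabilities)
        _validate_mix("source_shares", self.source_shares)
        _validate_mix("role_mix", self.role_mix)
        _validate_mix("province_mix", self.province_mix)


def _draw(rng: np.random.Generator, mix: Mapping, n: int) -> list:
    keys = sorted(mix, key=str)
    p = np.asarray([mix[k] for k in keys], dtype=float)
    p = p / p.sum()  # guard residual float error
    idx = rng.choice(len(keys), size=n, p=p)
    return [keys[i] for i in idx]


def generate_corpus(
    config: GeneratorConfig,
    registry: DialogicWeightRegistry | None = None,
) -> list[AnnotatedOccurrence]:
    """Generate ``n_annotations`` seeded annotation records with occurrences.

    Labels are drawn i.i.d. from the configured multinomial; dates are
    uniform over the week; each placeholder text embeds a topic keyword so
    the corpus passes content filtering by construction.
    """
    registry = registry or load_registry()
    probs = (
        {registry.resolve(k): v for k, v in config.dr_probabilities.items()}
        if config.dr_probabilities is not None
        else _worked_example_probabilities(registry)
    )
    rng = np.random.default_rng(config.seed)
    n = config.n_annotations
    labels = _draw(rng, probs, n)
    day_offsets = rng.integers(0, (config.week.end - config.week.start).days + 1, size=n)
    sources = _draw(rng, config.source_shares, n)
    roles = _draw(rng, config.role_mix, n)
    provinces = _draw(rng, config.province_mix, n)
    keywords = rng.choice(len(DEFAULT_KEYWORDS), size=n)

    records: list[AnnotatedOccurrence] = []
    width = len(str(n))
    for i in range(n):
        published = config.week.start + timedelta(days=int(day_offsets[i]))
        keyword = DEFAULT_KEYWORDS[int(keywords[i])]
        occ = Occurrence(
            id=f"syn-{config.seed}-{i:0{width}d}",
            text=f"[testo sintetico] {keyword}: unità di annotazione {labels[i]}.",
            source=Source(sources[i]),
            author_role=AuthorRole(roles[i]),
            province=provinces[i],
            published_at=published,
        )
        records.append(
            AnnotatedOccurrence(
                occurrence_id=occ.id,
                dr_label=labels[i],
                raw_label=labels[i],
                annotator="synthetic-generator",
                published_at=published,
                occurrence=occ,
            )
        )
    return records


def replay_worked_example(
    registry: DialogicWeightRegistry | None = None,
) -> list[AnnotatedOccurrence]:
    """Deterministically rebuild the worked-example week, count for count.

    Records carry the source table's raw labels (spelling variants intact)
    so downstream alias resolution is exercised; dates cycle over the seven
    window days, sources/roles/provinces cycle over their admitted values.
    """
    registry = registry or load_registry()
    sources = sorted(Source, key=lambda s: s.value)
    roles = sorted(AuthorRole, key=lambda r: r.value)
    records: list[AnnotatedOccurrence] = []
    k = 0
    for raw_label, count in WORKED_EXAMPLE_COUNTS.items():
        canonical = registry.resolve(raw_label)
        for _ in range(count):
            published = WORKED_EXAMPLE_WEEK.start + timedelta(days=k % 7)
            keyword = DEFAULT_KEYWORDS[k % len(DEFAULT_KEYWORDS)]
            occ = Occurrence(
                id=f"we-{k:04d}",
                text=f"[replica settimana di esempio] {keyword}: {raw_label}.",
                source=sources[k % len(sources)],
                author_role=roles[k % len(roles)],
                province=VENETO_PROVINCES[k % len(VENETO_PROVINCES)],
                published_at=published,
            )
            records.append(
                AnnotatedOccurrence(
                    occurrence_id=occ.id,
                    dr_label=canonical,
                    raw_label=raw_label,
                    annotator="worked-example-replay",
                    published_at=published,
                    occurrence=occ,
                )
            )
            k += 1
    return records


# -- trend generation ----------------------------------------------------


def _bracket_mixture(target: float, weights: dict[str, float]) -> dict[str, float] | None:
    """Two-point mixture over one variable's DRs with mean exactly ``target``.

    Picks the adjacent pair of registry weights bracketing the target (the
    narrowest bracket, minimising sampling variance); returns None when the
    target lies outside the variable's weight range.
    """
    ordered = sorted(weights.items(), key=lambda kv: (kv[1], kv[0]))
    lo_w = ordered[0][1]
    hi_w = ordered[-1][1]
    if not (lo_w <= target <= hi_w):
        return None
    for name, w in ordered:
        if abs(w - target) < 1e-12:
            return {name: 1.0}
    below = max((kv for kv in ordered if kv[1] < target), key=lambda kv: kv[1])
    above = min((kv for kv in ordered if kv[1] > target), key=lambda kv: kv[1])
    p_hi = (target - below[1]) / (above[1] - below[1])
    return {below[0]: 1.0 - p_hi, above[0]: p_hi}


def mixture_for_target(
    target: float, registry: DialogicWeightRegistry | None = None
) -> dict[str, float]:
    """DR probability vector whose expected default index equals ``target``.

    Within each variable whose weight range contains the target, a
    two-point mixture of adjacent weights has mean exactly the target;
    splitting mass evenly across the feasible variables then makes the
    expected per-variable means — and hence the expected xy-mean index —
    equal the target.  Targets feasible for only one variable yield a
    single-variable corpus (flagged downstream).
    """
    registry = registry or load_registry()
    if not (registry.min_weight <= target <= registry.max_weight):
        raise ConfigurationError(
            f"target {target} outside attainable range "
            f"[{registry.min_weight}, {registry.max_weight}]"
        )
    mixtures = []
    for var in (Variable.X, Variable.Y):
        weights = {dr.name: dr.dialogic_weight for dr in registry.entries_for(var)}
        mix = _bracket_mixture(target, weights)
        if mix is not None:
            mixtures.append(mix)
    if not mixtures:
        raise ConfigurationError(f"target {target} attainable by neither variable")
    probs: dict[str, float] = {}
    for mix in mixtures:
        for name, p in mix.items():
            probs[name] = probs.get(name, 0.0) + p / len(mixtures)
    return probs


def generate_trend(
    weekly_targets: Sequence[tuple[Week, float]],
    n_per_week: int = 5000,
    seed: int = 0,
    registry: DialogicWeightRegistry | None = None,
) -> list[list[AnnotatedOccurrence]]:
    """Generate one corpus per (week, target-index) pair.

    Each week's DR mixture is solved so the corpus's expected default index
    equals its target; per-week seeds are derived from the base seed.
    """
    registry = registry or load_registry()
    corpora = []
    for i, (week, target) in enumerate(weekly_targets):
        probs = mixture_for_target(target, registry)
        config = GeneratorConfig(
            dr_probabilities=probs,
            n_annotations=n_per_week,
            week=week,
            seed=seed + i,
        )
        corpora.append(generate_corpus(config, registry))
    return corpora
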
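"""Discursive-repertoire annotations and the pluggable classifier seam.

The annotation unit is one DR instance, not one text: a single occurrence
may yield zero, one or many annotation records (weekly tabulations count
repertoires, not texts).  Expert coding — and any trained classifier —
plugs in through the :class:`Classifier` protocol; the shipped
:class:`LexiconClassifier` is a transparent keyword-rule baseline, a
stand-in that makes the pipeline runnable, never a claim to reproduce
expert coding.

Raw labels are preserved alongside their canonical resolution so alias
mapping stays auditable.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import yaml

from .corpus import Occurrence
from .errors import ConfigurationError, RecordError, UnknownLabelError
from .taxonomy import DialogicWeightRegistry

__all__ = [
    "AnnotatedOccurrence",
    "Classifier",
    "LexiconClassifier",
    "load_lexicon",
    "annotate",
    "annotate_corpus",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class AnnotatedOccurrence:
    """One annotation unit: a DR instance attributed to an occurrence."""

    occurrence_id: str
    dr_label: str  # canonical name in the active registry
    raw_label: str  # label as emitted by the annotator, pre-resolution
    annotator: str
    published_at: date | None = None
    occurrence: Occurrence | None = None


@runtime_checkable
class Classifier(Protocol):
    """Anything that labels a text with zero or more DR names."""

    id: str

    def label(self, text: str) -> list[str]: ...


_SENTENCE_SPLIT = re.compile(r"[.!?]+")


class LexiconClassifier:
    """Keyword-rule baseline: cue word/phrase → DR, applied per sentence.

    Each sentence is scanned for every cue (case-insensitive substring
    after whitespace normalisation); each cue that fires emits one label.
    Deterministic: cues are checked in sorted order.
    """

    def __init__(self, lexicon: Mapping[str, str], id: str = "lexicon-baseline"):
        if not lexicon:
            raise ConfigurationError("lexicon must be non-empty")
        self.id = id
        self._rules = sorted(
            (" ".join(cue.split()).casefold(), label) for cue, label in lexicon.items()
        )

    def label(self, text: str) -> list[str]:
        labels: list[str] = []
        for sentence in _SENTENCE_SPLIT.split(text):
            s = " ".join(sentence.split()).casefold()
            if not s:
                continue
            labels.extend(label for cue, label in self._rules if cue in s)
        return labels


def load_lexicon(path: str | Path | None = None) -> dict[str, str]:
    """Load a cue→DR lexicon from YAML; with no path, the shipped default."""
    if path is None:
        ref = resources.files("drcohesion.data") / "lexicon.yaml"
        with resources.as_file(ref) as p:
            return load_lexicon(p)
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: lexicon must be a mapping of cue -> DR name")
    return {str(k): str(v) for k, v in doc.items()}


def annotate(
    occurrence: Occurrence,
    classifier: Classifier,
    registry: DialogicWeightRegistry,
) -> list[AnnotatedOccurrence]:
    """Run a classifier over one occurrence; every emitted label must resolve.

    A classifier emitting a label outside the registry is a hard error —
    silent label loss would bias every downstream tabulation.
    """
    records = []
    for raw in classifier.label(occurrence.text):
        canonical = registry.resolve(raw)  # raises UnknownLabelError if not
        records.append(
            AnnotatedOccurrence(
                occurrence_id=occurrence.id,
                dr_label=canonical,
                raw_label=raw,
                annotator=classifier.id,
                published_at=occurrence.published_at,
                occurrence=occurrence,
            )
        )
    return records


def annotate_corpus(
    occurrences: Iterable[Occurrence],
    classifier: Classifier,
    registry: DialogicWeightRegistry,
) -> list[AnnotatedOccurrence]:
    out: list[AnnotatedOccurrence] = []
    for occ in occurrences:
        out.extend(annotate(occ, classifier, registry))
    return out


# -- IO ------------------------------------------------------------------

_FIELDS = ("occurrence_id", "dr_label", "raw_label", "annotator", "published_at")


def _record_from_row(
    row: Mapping[str, object], n: int, registry: DialogicWeightRegistry
) -> AnnotatedOccurrence:
    for f in ("occurrence_id", "dr_label", "annotator"):
        if f not in row or row[f] in (None, ""):
            raise RecordError(n, f"missing field {f!r}")
    raw = str(row.get("raw_label") or row["dr_label"])
    try:
        canonical = registry.resolve(str(row["dr_label"]))
    except UnknownLabelError as e:
        raise RecordError(n, str(e)) from None
    published = row.get("published_at")
    if published in (None, ""):
        published_at = None
    elif isinstance(published, date):
        published_at = published
    else:
        try:
            published_at = date.fromisoformat(str(published))
        except ValueError:
            raise RecordError(n, f"invalid date {published!r}") from None
    return AnnotatedOccurrence(
        occurrence_id=str(row["occurrence_id"]),
        dr_label=canonical,
        raw_label=raw,
        annotator=str(row["annotator"]),
        published_at=published_at,
    )


def read_annotations(
    path: str | Path,
    registry: DialogicWeightRegistry,
    format: str | None = None,
) -> list[AnnotatedOccurrence]:
    """Read annotation records (JSONL or CSV), resolving labels on the way in.

    Unresolvable labels are rejected with the record number and raw label;
    the original label is preserved in ``raw_label``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    records: list[AnnotatedOccurrence] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for n, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as e:
                    raise RecordError(n, f"invalid JSON: {e}") from None
                records.append(_record_from_row(row, n, registry))
    elif fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for n, row in enumerate(csv.DictReader(fh), start=1):
                records.append(_record_from_row(row, n, registry))
    else:
        raise ConfigurationError(f"unsupported annotation format {fmt!r} (jsonl or csv)")
    return records


def write_annotations(
    annotations: Sequence[AnnotatedOccurrence],
    path: str | Path,
    format: str | None = None,
) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    rows = [
        {
            "occurrence_id": a.occurrence_id,
            "dr_label": a.dr_label,
            "raw_label": a.raw_label,
            "annotator": a.annotator,
            "published_at": a.published_at.isoformat() if a.published_at else "",
        }
        for a in annotations
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
        raise ConfigurationError(f"unsupported annotation format {fmt!r} (jsonl or csv)")
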
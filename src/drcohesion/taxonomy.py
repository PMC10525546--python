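"""Discursive-repertoire taxonomy and dialogic weights.

Dialogic science formalises natural-language use into a closed set of
*discursive repertoires* (DRs): coded modalities such as *Description*,
*Judgement* or *Proposal*.  Each DR contributes to exactly one of the two
dimensions of social cohesion —

* variable **x**, *anticipation of future scenarios* (9 DRs), and
* variable **y**, *shared management* (14 DRs)

— with a fixed *dialogic weight* (dW) on a 0–20 scale.  High-weight
repertoires (Description 20, Anticipation 19.14, Proposal 18.27) are
modalities oriented to a shared, common goal; low-weight ones (Certify
Reality 0.87, Cause of Action 1.74) fix the status quo or pursue personal
aims.  The :class:`DialogicWeightRegistry` is the single lookup point the
rest of the pipeline uses to join annotation frequencies to weights.

The default registry ships 23 entries.  Published frequency tables use a few
spelling variants ("Prevision", "Deresponsibility", ...); the registry's
alias table maps those onto canonical names so tabulations always join.
"""

from __future__ import annotations

import csv
import difflib
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import RegistryError, UnknownLabelError

__all__ = [
    "Variable",
    "Typology",
    "DiscursiveRepertoire",
    "DialogicWeightRegistry",
    "load_registry",
    "write_registry",
]


class Variable(str, enum.Enum):
    """The two operationalised dimensions of social cohesion."""

    X = "x"  # anticipation of future scenarios
    Y = "y"  # shared management

    @property
    def description(self) -> str:
        return {
            Variable.X: "anticipation of future scenarios",
            Variable.Y: "shared management",
        }[self]


class Typology(str, enum.Enum):
    """DR typology: whether a modality promotes change, fixes the status quo,
    or takes either valence from context.  Metadata only — never alters dW."""

    GENERATIVE = "generative"
    STABILIZATION = "stabilization"
    HYBRID = "hybrid"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class DiscursiveRepertoire:
    """One coded discursive modality with its variable assignment and weight."""

    name: str
    variable: Variable
    dialogic_weight: float
    typology: Typology = Typology.UNKNOWN

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise RegistryError("repertoire name must be non-empty")
        if not (0.0 < self.dialogic_weight <= 20.0):
            raise RegistryError(
                f"dialogic weight of {self.name!r} is {self.dialogic_weight}; "
                "must lie in (0, 20]"
            )


def _key(label: str) -> str:
    """Normalisation used for lookups: trim and case-fold."""
    return " ".join(label.split()).casefold()


@dataclass(frozen=True)
class DialogicWeightRegistry:
    """Canonical weight table plus alias resolution.

    Immutable; :meth:`with_entry` returns an extended copy (the taxonomy
    nominally counts 24 DRs but only 23 weights are published, so user
    extension is supported rather than inventing a weight).
    """

    entries: tuple[DiscursiveRepertoire, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_key: dict[str, DiscursiveRepertoire] = {}
        for dr in self.entries:
            k = _key(dr.name)
            if k in by_key:
                raise RegistryError(f"duplicate repertoire name {dr.name!r}")
            by_key[k] = dr
        alias_map: dict[str, str] = {}
        for raw, canonical in dict(self.aliases).items():
            ck = _key(canonical)
            if ck not in by_key:
                raise RegistryError(
                    f"alias {raw!r} points to unknown repertoire {canonical!r}"
                )
            alias_map[_key(raw)] = by_key[ck].name
        object.__setattr__(self, "_by_key", by_key)
        object.__setattr__(self, "_alias_map", alias_map)

    # -- lookups ---------------------------------------------------------

    def resolve(self, raw_label: str) -> str:
        """Resolve a raw label to its canonical name.

        Trims, case-folds, then tries the canonical names and the alias
        table.  Resolution is idempotent.  Unresolvable labels raise
        :class:`UnknownLabelError` carrying the nearest candidates rather
        than being silently dropped.
        """
        k = _key(raw_label)
        if k in self._by_key:
            return self._by_key[k].name
        if k in self._alias_map:
            return self._alias_map[k]
        pool = list(self._by_key) + list(self._alias_map)
        near = difflib.get_close_matches(k, pool, n=3, cutoff=0.6)
        candidates = sorted({self._by_key[c].name if c in self._by_key else self._alias_map[c] for c in near})
        raise UnknownLabelError(raw_label, candidates)

    def get(self, name: str) -> DiscursiveRepertoire:
        return self._by_key[_key(self.resolve(name))]

    def get_weight(self, name: str) -> tuple[Variable, float]:
        """Return the unique ``(variable, dialogic_weight)`` pair for a DR."""
        dr = self.get(name)
        return dr.variable, dr.dialogic_weight

    def entries_for(self, variable: Variable) -> tuple[DiscursiveRepertoire, ...]:
        return tuple(dr for dr in self.entries if dr.variable is variable)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(dr.name for dr in self.entries)

    @property
    def min_weight(self) -> float:
        return min(dr.dialogic_weight for dr in self.entries)

    @property
    def max_weight(self) -> float:
        return max(dr.dialogic_weight for dr in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label: str) -> bool:
        try:
            self.resolve(label)
            return True
        except UnknownLabelError:
            return False

    def with_entry(self, dr: DiscursiveRepertoire) -> "DialogicWeightRegistry":
        """Return a new registry extended with ``dr`` (e.g. a 24th repertoire)."""
        return DialogicWeightRegistry(self.entries + (dr,), dict(self.aliases))


# -- document IO ---------------------------------------------------------

_VALID_VARIABLES = {v.value for v in Variable}


def _parse_rows(rows: Iterable[Mapping], aliases: Mapping[str, str]) -> DialogicWeightRegistry:
    entries = []
    for row in rows:
        var = str(row["variable"]).strip().casefold()
        if var not in _VALID_VARIABLES:
            raise RegistryError(f"unknown variable tag {row['variable']!r} for {row['name']!r}")
        typology = Typology(str(row.get("typology") or "unknown").strip().casefold())
        entries.append(
            DiscursiveRepertoire(
                name=str(row["name"]).strip(),
                variable=Variable(var),
                dialogic_weight=float(row["dw"]),
                typology=typology,
            )
        )
    return DialogicWeightRegistry(tuple(entries), dict(aliases))


def load_registry(path: str | Path | None = None) -> DialogicWeightRegistry:
    """Load a registry document (YAML or CSV); with no path, the shipped default.

    YAML layout::

        repertoires:
          - {name: Description, variable: x, dw: 20}
        aliases:
          Prevision: Prediction

    CSV layout: header ``name,variable,dw,typology,aliases`` where ``aliases``
    holds semicolon-separated raw variants of that row's name.
    """
    if path is None:
        ref = resources.files("drcohesion.data") / "registry.yaml"
        with resources.as_file(ref) as p:
            return load_registry(p)
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
        if not isinstance(doc, dict) or "repertoires" not in doc:
            raise RegistryError(f"{path}: registry document must contain a 'repertoires' list")
        return _parse_rows(doc["repertoires"], doc.get("aliases") or {})
    if path.suffix.lower() == ".csv":
        rows, aliases = [], {}
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                rows.append(row)
                for raw in filter(None, (row.get("aliases") or "").split(";")):
                    aliases[raw.strip()] = row["name"].strip()
        return _parse_rows(rows, aliases)
    raise RegistryError(f"unsupported registry format: {path.suffix!r}")


def write_registry(registry: DialogicWeightRegistry, path: str | Path) -> None:
    """Write a registry as YAML (inverse of :func:`load_registry`)."""
    path = Path(path)
    doc = {
        "repertoires": [
            {
                "name": dr.name,
                "variable": dr.variable.value,
                "dw": dr.dialogic_weight,
                "typology": dr.typology.value,
            }
            for dr in registry.entries
        ],
        "aliases": dict(registry.aliases),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8")
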
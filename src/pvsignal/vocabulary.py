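"""Drug-name normalization and adverse-event term grouping.

Verbatim drug names on spontaneous reports are noisy (salts, hydrates,
brand names); a :class:`DrugDictionary` maps them case-insensitively to
normalized products, each carrying its ingredient set (singletons for
monotherapies, two or three ingredients for fixed-dose combinations) and a
drug-class label (LAMA, SAMA, LABA, ICS, ...).

Event preferred terms are classified into named :class:`EventGroup` sets —
a broad system-organ-class-like group plus narrower standardized-query-like
subgroups.  Real MedDRA term lists are licensed and therefore user-supplied
via the vocabulary file; a small demo vocabulary of cardiac terms ships
with the package for tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .report_model import DrugRole, Report, SUSPECT_ROLES

__all__ = [
    "DrugDictionary",
    "EventGroup",
    "Vocabulary",
    "VocabularyError",
    "load_vocabulary",
    "demo_vocabulary",
    "normalize_drug",
    "classify_event",
    "exposure_products",
]


class VocabularyError(ValueError):
    """Raised when a vocabulary file is structurally invalid."""


@dataclass(frozen=True)
class EventGroup:
    """A named set of preferred terms; matching is case-insensitive exact."""

    group_id: str
    label: str
    terms: frozenset[str]  # stored upper-cased and trimmed

    def __post_init__(self) -> None:
        if not self.terms:
            raise VocabularyError(f"event group {self.group_id!r} has no terms")


@dataclass
class DrugDictionary:
    """Verbatim-name → product map plus product composition and class."""

    synonym_map: dict[str, str]            # lower-cased verbatim -> product_id
    products: dict[str, frozenset[str]]    # product_id -> ingredient ids
    class_map: dict[str, str] = field(default_factory=dict)  # ingredient -> class

    def __post_init__(self) -> None:
        for syn, pid in self.synonym_map.items():
            if pid not in self.products:
                raise VocabularyError(
                    f"synonym {syn!r} maps to unknown product {pid!r}")
        for pid, ingredients in self.products.items():
            if not ingredients:
                raise VocabularyError(f"product {pid!r} has no ingredients")

    def synonyms_of(self, product_id: str) -> list[str]:
        return sorted(s for s, p in self.synonym_map.items() if p == product_id)


@dataclass
class Vocabulary:
    """A drug dictionary together with the event-group definitions."""

    drugs: DrugDictionary
    event_groups: dict[str, EventGroup]

    def group(self, group_id: str) -> EventGroup:
        try:
            return self.event_groups[group_id]
        except KeyError:
            raise KeyError(f"unknown event group: {group_id!r}") from None


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a vocabulary YAML file (``drugs`` and ``event_groups`` sections).

    Each drug entry maps a product id to ``synonyms`` (list), ``ingredients``
    (list) and ``class`` (one label, applied to every ingredient unless an
    ingredient already has one from an earlier entry).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _build_vocabulary(doc)


def _build_vocabulary(doc: Mapping) -> Vocabulary:
    if not isinstance(doc, Mapping) or "drugs" not in doc or "event_groups" not in doc:
        raise VocabularyError("vocabulary must have 'drugs' and 'event_groups' sections")
    synonym_map: dict[str, str] = {}
    products: dict[str, frozenset[str]] = {}
    class_map: dict[str, str] = {}
    for pid, entry in doc["drugs"].items():
        ingredients = frozenset(entry.get("ingredients", [pid]))
        products[pid] = ingredients
        for syn in entry.get("synonyms", [pid]):
            synonym_map[str(syn).strip().lower()] = pid
        label = entry.get("class")
        if label:
            for ing in ingredients:
                class_map.setdefault(ing, label)
    groups = {}
    for gid, entry in doc["event_groups"].items():
        terms = frozenset(str(t).strip().upper() for t in entry.get("terms", []))
        groups[gid] = EventGroup(gid, entry.get("label", gid), terms)
    return Vocabulary(DrugDictionary(synonym_map, products, class_map), groups)


def demo_vocabulary() -> Vocabulary:
    """The bundled demonstration vocabulary (inhaled bronchodilator products
    and a compact cardiac-disorder term set with three subgroups)."""
    ref = resources.files("pvsignal") / "fixtures" / "demo_vocabulary.yaml"
    with resources.as_file(ref) as path:
        return load_vocabulary(path)


# ---------------------------------------------------------------------------
# operations

def normalize_drug(dictionary: DrugDictionary, verbatim: str) -> str | None:
    """Normalize a verbatim drug name to its product id.

    Matching is case-insensitive exact after trimming; returns None when the
    name is not in the dictionary (the caller decides how to treat unmatched
    drugs).
    """
    return dictionary.synonym_map.get(verbatim.strip().lower())


def classify_event(vocab: Vocabulary, pt: str) -> set[str]:
    """Return every event-group id whose term set contains the PT.

    Groups are not assumed disjoint: a term may belong to the broad group
    and to one or more subgroups at once.
    """
    needle = pt.strip().upper()
    return {gid for gid, g in vocab.event_groups.items() if needle in g.terms}


def exposure_products(
    dictionary: DrugDictionary,
    report: Report,
    roles: frozenset[DrugRole] = SUSPECT_ROLES,
) -> set[str]:
    """Normalized products among the report's drug mentions with a role in
    ``roles`` (default: suspect roles plus unknown)."""
    out = set()
    for mention in report.drugs:
        if mention.role in roles:
            pid = normalize_drug(dictionary, mention.verbatim_name)
            if pid is not None:
                out.add(pid)
    return out
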
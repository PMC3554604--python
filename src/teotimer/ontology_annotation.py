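"""Event-name normalization and ontology term mapping.

The same adverse event appears in reports under many surface forms
("FLU-LIKE SYMPTOMS", "Influenza-like illness", "flu-like illness"); only when
all of them are annotated with the same ontology term can a program recognize
them as one concept across reports. This module normalizes surface text and
maps it to identifiers in three vocabularies:

* **OAE** — Ontology of Adverse Events (the AE process terms, e.g. 'nausea AE'),
* **MedDRA** — the regulatory dictionary VAERS itself codes symptoms with,
* **VO** — the Vaccine Ontology (vaccine product terms, e.g. Engerix-B).

Mapping is exact-after-normalization against a packaged lexicon excerpt (a
versioned TSV, not a live ontology import): deterministic and auditable, with
no fuzzy matching. When a surface form is cross-referenced in both OAE and
MedDRA, both term references are attached. Unknown forms pass through
normalized but flagged unmapped — never dropped.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

from .errors import InvalidInputError
from .temporal_model import TemporalGraph, TermRef

__all__ = [
    "UnmappedTerm",
    "Lexicon",
    "default_lexicon",
    "normalize_label",
    "lookup_term",
    "annotate_events",
]

VOCABULARIES = ("OAE", "MedDRA", "VO")


@dataclass(frozen=True)
class UnmappedTerm:
    """Marker for a label with no lexicon entry; carries the normalized form."""

    normalized_label: str
    vocabulary: Optional[str] = None


def _normalize_base(surface: str) -> str:
    """Case folding plus punctuation/hyphen collapsing — no synonym mapping."""
    t = surface.lower()
    t = re.sub(r"[^\w\s]|_", " ", t)
    return re.sub(r"\s+", " ", t).strip()


def _canonical_of(preferred_label: str) -> str:
    # one canonical text per concept: the normalized preferred label with the
    # OAE process suffix (' AE') removed
    base = _normalize_base(preferred_label)
    return base[:-3] if base.endswith(" ae") else base


class Lexicon:
    """Surface form -> TermRef table with deterministic normalization."""

    def __init__(self, rows: list[tuple[str, str, str, str]]):
        self.entries: dict[str, list[TermRef]] = {}
        self.canonical: dict[str, str] = {}
        for surface, vocabulary, identifier, preferred_label in rows:
            ref = TermRef(vocabulary=vocabulary, identifier=identifier,
                          preferred_label=preferred_label)
            canon = _canonical_of(preferred_label)
            # each preferred label must resolve to its own term
            for key in (_normalize_base(surface), _normalize_base(preferred_label), canon):
                self.canonical.setdefault(key, canon)
                refs = self.entries.setdefault(key, [])
                if ref not in refs:
                    refs.append(ref)

    @classmethod
    def from_tsv(cls, path_or_file) -> "Lexicon":
        rows = []
        if hasattr(path_or_file, "read"):
            lines = path_or_file.read().splitlines()
        else:
            with open(path_or_file, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        for row in csv.reader(lines, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 4:
                raise InvalidInputError(f"lexicon row needs 4 columns, got {row!r}")
            rows.append(tuple(row))
        return cls(rows)

    def normalize(self, surface: str) -> str:
        base = _normalize_base(surface)
        return self.canonical.get(base, base)

    def lookup(self, label: str, vocabulary: str) -> Union[TermRef, UnmappedTerm]:
        if vocabulary not in VOCABULARIES:
            raise InvalidInputError(
                f"unknown vocabulary {vocabulary!r}; expected one of {VOCABULARIES}"
            )
        if not label:
            raise InvalidInputError("label must be non-empty")
        normalized = self.normalize(label)
        for key in (_normalize_base(label), normalized):
            for ref in self.entries.get(key, []):
                if ref.vocabulary == vocabulary:
                    return ref
        return UnmappedTerm(normalized_label=normalized, vocabulary=vocabulary)

    def lookup_all(self, label: str) -> list[TermRef]:
        """All term references (any vocabulary) for a surface form."""
        normalized = self.normalize(label)
        out = []
        for key in (_normalize_base(label), normalized):
            for ref in self.entries.get(key, []):
                if ref not in out:
                    out.append(ref)
        return out


_DEFAULT: Optional[Lexicon] = None


def default_lexicon() -> Lexicon:
    """The packaged lexicon excerpt (data/lexicon.tsv)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.files("teotimer.data").joinpath("lexicon.tsv").open(
            encoding="utf-8"
        ) as fh:
            _DEFAULT = Lexicon.from_tsv(fh)
    return _DEFAULT


def normalize_label(surface: str, lexicon: Optional[Lexicon] = None) -> str:
    """Canonical text for a surface form: lowercased, punctuation collapsed,
    synonym-mapped. Idempotent and total (unknown forms pass through)."""
    if not surface:
        raise InvalidInputError("surface form must be non-empty")
    return (lexicon or default_lexicon()).normalize(surface)


def lookup_term(label: str, vocabulary: str,
                lexicon: Optional[Lexicon] = None) -> Union[TermRef, UnmappedTerm]:
    """Map a label to its term in one vocabulary, or an unmapped marker."""
    return (lexicon or default_lexicon()).lookup(label, vocabulary)


def annotate_events(graph: TemporalGraph, lexicon: Optional[Lexicon] = None) -> TemporalGraph:
    """Extend every event's annotations with lexicon matches on its label.

    Events are never removed or relabeled; labels with no match are flagged
    ``unmapped`` and preserved.
    """
    lexicon = lexicon or default_lexicon()
    for eid in sorted(graph.events):
        event = graph.events[eid]
        refs = lexicon.lookup_all(event.label)
        for ref in refs:
            if ref not in event.annotations:
                event.annotations.append(ref)
        if not event.annotations:
            event.unmapped = True
    return graph
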
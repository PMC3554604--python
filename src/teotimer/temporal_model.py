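"""Core domain types for events, time stamps and qualitative temporal relations.

The model mirrors the Time Event Ontology (TEO) view of a clinical report:
*events* (processual entities such as a vaccination or a symptom onset) carry an
optional time stamp — a :class:`TimeInstant` or a :class:`TimeInterval` — and are
linked pairwise by Allen-style temporal relations, optionally annotated with a
quantitative :class:`Duration` offset ("eighteen days after vaccination").
A :class:`TemporalGraph` collects one report's events and assertions and is the
unit of reasoning (see :mod:`teotimer.allen_reasoner`) and serialization
(see :mod:`teotimer.rdf_io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import ConflictError, InvalidInputError, NotFoundError, StructuralError

__all__ = [
    "Granularity",
    "Duration",
    "TimeInstant",
    "TimeInterval",
    "PeriodicInterval",
    "TermRef",
    "Event",
    "ALLEN_RELATIONS",
    "ALLEN_INVERSE",
    "TemporalAssertion",
    "TemporalGraph",
    "add_event",
    "attach_time",
    "assert_relation",
    "validate_graph",
]


class Granularity(str, enum.Enum):
    """Precision of a time stamp or duration unit, finest to coarsest."""

    SECOND = "second"
    MINUTE = "minute"
    HOUR = "hour"
    DAY = "day"
    WEEK = "week"
    MONTH = "month"
    YEAR = "year"

    @property
    def rank(self) -> int:
        return _GRANULARITY_ORDER.index(self.value)

    @classmethod
    def coarsest(cls, *levels: "Granularity") -> "Granularity":
        return max(levels, key=lambda g: g.rank)

    @classmethod
    def from_text(cls, text: str) -> "Granularity":
        try:
            return cls(text)
        except ValueError:
            raise InvalidInputError(f"unknown granularity {text!r}") from None


_GRANULARITY_ORDER = ["second", "minute", "hour", "day", "week", "month", "year"]

#: Units allowed for durations — same controlled vocabulary as granularity.
DURATION_UNITS = tuple(_GRANULARITY_ORDER)


@dataclass(frozen=True)
class Duration:
    """A quantity of time: a value and a unit from the controlled vocabulary."""

    value: float
    unit: Granularity

    def __post_init__(self):
        if isinstance(self.unit, str) and not isinstance(self.unit, Granularity):
            object.__setattr__(self, "unit", Granularity.from_text(self.unit))
        if self.value < 0:
            raise InvalidInputError(f"duration value must be >= 0, got {self.value}")

    def __str__(self) -> str:
        v = int(self.value) if float(self.value).is_integer() else self.value
        return f"{v} {self.unit.value}{'' if v == 1 else 's'}"


# --- partial ISO-8601 helpers ------------------------------------------------
# Normalized time values are partial ISO strings:  "2006", "2006-07",
# "2006-07-06", or year-less "--07-06" / "--07" awaiting anchor completion.


def precision_of(normalized: str) -> Granularity:
    """Granularity implied by a partial ISO date string."""
    if normalized.startswith("--"):
        body = normalized[2:]
        return Granularity.DAY if "-" in body else Granularity.MONTH
    n = normalized.count("-")
    if n == 0:
        return Granularity.YEAR
    if n == 1:
        return Granularity.MONTH
    return Granularity.DAY


def truncate_normalized(normalized: str, granularity: Granularity) -> str:
    """Truncate a partial ISO string to ``granularity`` (never refines)."""
    if normalized.startswith("--"):
        return normalized
    parts = normalized.split("-")
    keep = {"year": 1, "month": 2}.get(granularity.value, 3)
    return "-".join(parts[:keep])


@dataclass
class TimeInstant:
    """A time stamp: the original text plus an optional normalized value.

    ``orig_text`` is preserved verbatim; ``normalized`` is a partial ISO-8601
    string whose precision must match ``granularity``. ``unresolved`` marks an
    instant whose year could not be completed from context.
    """

    orig_text: str
    normalized: Optional[str] = None
    granularity: Optional[Granularity] = None
    unresolved: bool = False

    def __post_init__(self):
        if isinstance(self.granularity, str):
            self.granularity = Granularity.from_text(self.granularity)
        if self.normalized is not None:
            prec = precision_of(self.normalized)
            if self.granularity is None:
                self.granularity = prec
            elif self.granularity != prec:
                raise InvalidInputError(
                    f"granularity {self.granularity.value!r} does not match the "
                    f"precision of normalized value {self.normalized!r} ({prec.value})"
                )

    @property
    def is_complete(self) -> bool:
        return self.normalized is not None and not self.normalized.startswith("--")


@dataclass
class TimeInterval:
    """A span of time with optional start, end and duration (at least one)."""

    start: Optional[TimeInstant] = None
    end: Optional[TimeInstant] = None
    duration: Optional[Duration] = None

    def __post_init__(self):
        if self.start is None and self.end is None and self.duration is None:
            raise InvalidInputError("a time interval needs a start, end or duration")
        if (
            self.start is not None
            and self.end is not None
            and self.duration is not None
            and self.start.is_complete
            and self.end.is_complete
        ):
            # consistency check at the stated (coarser endpoint) granularity
            from .time_normalization import add_duration_to_date, to_date

            gran = Granularity.coarsest(self.start.granularity, self.end.granularity)
            expected = add_duration_to_date(to_date(self.start.normalized), self.duration)
            stated = to_date(self.end.normalized)
            trunc = lambda d: truncate_normalized(d.isoformat(), gran)
            if trunc(expected) != trunc(stated):
                raise InvalidInputError(
                    f"interval start {self.start.normalized} + {self.duration} "
                    f"!= end {self.end.normalized} at {gran.value} granularity"
                )


@dataclass
class PeriodicInterval:
    """A repeating schedule: 'Exercise 20 minutes 3 times/day ... for 2 weeks'."""

    frequency_count: int
    frequency_period: Granularity
    per_occurrence: Optional[Duration] = None
    anchor_start: Optional[TimeInstant] = None
    span: Optional[Duration] = None

    def __post_init__(self):
        if isinstance(self.frequency_period, str):
            self.frequency_period = Granularity.from_text(self.frequency_period)
        if self.frequency_count < 1:
            raise InvalidInputError("frequency count must be >= 1")


@dataclass(frozen=True)
class TermRef:
    """A canonical identifier in OAE, MedDRA or VO for an event or vaccine."""

    vocabulary: str  # one of "OAE", "MedDRA", "VO"
    identifier: str
    preferred_label: str

    _PATTERNS = {
        "OAE": r"OAE_\d{7}",
        "MedDRA": r"\d{8}",
        "VO": r"VO_\d{7}",
    }

    def __post_init__(self):
        import re

        if self.vocabulary not in self._PATTERNS:
            raise InvalidInputError(f"unknown vocabulary {self.vocabulary!r}")
        if not re.fullmatch(self._PATTERNS[self.vocabulary], self.identifier):
            raise InvalidInputError(
                f"identifier {self.identifier!r} does not match the "
                f"{self.vocabulary} ID pattern"
            )


@dataclass
class Event:
    """A processual entity from a report: vaccination, symptom, hospitalization."""

    id: str
    label: str
    annotations: list[TermRef] = field(default_factory=list)
    time: Optional[Union[TimeInstant, TimeInterval]] = None
    unmapped: bool = False  # true when annotation found no lexicon match


# --- Allen relations ----------------------------------------------------------

ALLEN_RELATIONS = (
    "before",
    "after",
    "meets",
    "met_by",
    "overlaps",
    "overlapped_by",
    "starts",
    "started_by",
    "during",
    "contains",
    "finishes",
    "finished_by",
    "equals",
)

ALLEN_INVERSE = {
    "before": "after",
    "after": "before",
    "meets": "met_by",
    "met_by": "meets",
    "overlaps": "overlapped_by",
    "overlapped_by": "overlaps",
    "starts": "started_by",
    "started_by": "starts",
    "during": "contains",
    "contains": "during",
    "finishes": "finished_by",
    "finished_by": "finishes",
    "equals": "equals",
}

#: Relations an offset duration may annotate (gap between the two events).
OFFSET_RELATIONS = frozenset({"before", "after", "meets", "met_by"})


def _check_relation_name(name: str) -> str:
    if name not in ALLEN_RELATIONS:
        raise InvalidInputError(f"unknown Allen relation {name!r}")
    return name


@dataclass
class TemporalAssertion:
    """A (source, relation, target) temporal statement.

    ``relations`` is a set of Allen relation names — a singleton for stated
    assertions, possibly a disjunction for inferred ones. ``offset`` is the
    quantitative gap for before/after/meets/met_by. ``provenance`` records
    whether the assertion was stated in the report or inferred by the reasoner.
    """

    source: str
    relations: frozenset[str]
    target: str
    offset: Optional[Duration] = None
    provenance: str = "stated"

    def __post_init__(self):
        if isinstance(self.relations, str):
            self.relations = frozenset({self.relations})
        else:
            self.relations = frozenset(self.relations)
        for r in self.relations:
            _check_relation_name(r)
        if not self.relations:
            raise InvalidInputError("assertion needs at least one relation")
        if self.provenance not in ("stated", "inferred"):
            raise InvalidInputError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "stated" and len(self.relations) != 1:
            raise InvalidInputError("stated assertions must carry a single relation")
        if self.offset is not None and not self.relations <= OFFSET_RELATIONS:
            raise InvalidInputError(
                "a time offset is only meaningful with before/after/meets/met_by"
            )
        if self.source == self.target and self.relations != {"equals"}:
            raise InvalidInputError("an event cannot strictly relate to itself")

    @property
    def relation(self) -> str:
        """The single relation of a singleton assertion."""
        if len(self.relations) != 1:
            raise InvalidInputError("assertion carries a disjunction, not a single relation")
        return next(iter(self.relations))

    def key(self):
        offset = (self.offset.value, self.offset.unit.value) if self.offset else (-1, "")
        return (self.source, tuple(sorted(self.relations)), self.target,
                offset, self.provenance)


class TemporalGraph:
    """All events and temporal assertions of one report."""

    def __init__(self):
        self.events: dict[str, Event] = {}
        self.assertions: list[TemporalAssertion] = []
        self.consistency_status: str = "unknown"
        self._counter = 0

    # -- construction ---------------------------------------------------------

    def fresh_id(self) -> str:
        self._counter += 1
        eid = f"event{self._counter}"
        while eid in self.events:
            self._counter += 1
            eid = f"event{self._counter}"
        return eid

    def add_existing_event(self, event: Event) -> Event:
        if event.id in self.events:
            raise ConflictError(f"duplicate event id {event.id!r}")
        if not event.label:
            raise InvalidInputError("event label must be non-empty")
        self.events[event.id] = event
        return event

    def event(self, event_id: str) -> Event:
        try:
            return self.events[event_id]
        except KeyError:
            raise NotFoundError(f"no event with id {event_id!r}") from None

    def stated_assertions(self) -> list[TemporalAssertion]:
        return [a for a in self.assertions if a.provenance == "stated"]

    def copy(self) -> "TemporalGraph":
        import copy as _copy

        return _copy.deepcopy(self)

    def structurally_equal(self, other: "TemporalGraph") -> bool:
        if sorted(self.events) != sorted(other.events):
            return False
        ann_key = lambda refs: sorted((r.vocabulary, r.identifier, r.preferred_label) for r in refs)
        for eid, ev in self.events.items():
            oe = other.events[eid]
            # annotations compare as a set: RDF serialization has no list order
            if (ev.label, ann_key(ev.annotations), ev.time, ev.unmapped) != (
                oe.label,
                ann_key(oe.annotations),
                oe.time,
                oe.unmapped,
            ):
                return False
        return sorted(a.key() for a in self.assertions) == sorted(
            a.key() for a in other.assertions
        )


def add_event(graph: TemporalGraph, label: str, annotations=None) -> Event:
    """Create a new event with a fresh id and store it in the graph."""
    if not label:
        raise InvalidInputError("event label must be non-empty")
    event = Event(id=graph.fresh_id(), label=label, annotations=list(annotations or []))
    graph.events[event.id] = event
    return event


def attach_time(graph: TemporalGraph, event_id: str,
                time: Union[TimeInstant, TimeInterval]) -> Event:
    """Assign a time stamp to an event; a second assignment is an error."""
    event = graph.event(event_id)
    if event.time is not None:
        raise ConflictError(f"event {event_id!r} already has a time assigned")
    if not isinstance(time, (TimeInstant, TimeInterval)):
        raise InvalidInputError("time must be a TimeInstant or TimeInterval")
    event.time = time
    return event


def assert_relation(graph: TemporalGraph, source: str, relation: str,
                    target: str, offset: Optional[Duration] = None) -> TemporalAssertion:
    """Record a stated Allen relation between two existing events."""
    graph.event(source)
    graph.event(target)
    _check_relation_name(relation)
    if source == target and relation != "equals":
        raise InvalidInputError("a strict relation between an event and itself")
    assertion = TemporalAssertion(
        source=source, relations=frozenset({relation}), target=target,
        offset=offset, provenance="stated",
    )
    graph.assertions.append(assertion)
    return assertion


def validate_graph(graph: TemporalGraph) -> dict:
    """Check referential integrity and temporal consistency.

    Returns a report dict with keys ``consistent`` (bool) and ``conflicts``
    (offending assertion pairs / triangles, empty when consistent) and sets
    ``graph.consistency_status``.
    """
    missing = sorted(
        {a.source for a in graph.assertions if a.source not in graph.events}
        | {a.target for a in graph.assertions if a.target not in graph.events}
    )
    if missing:
        raise StructuralError(
            f"assertions reference missing events: {', '.join(missing)}", missing=missing
        )
    # direct contradictions between stated singleton pairs
    conflicts = []
    stated = graph.stated_assertions()
    for i, a in enumerate(stated):
        for b in stated[i + 1:]:
            if (a.source, a.target) == (b.source, b.target) and a.relation != b.relation:
                conflicts.append((a, b))
            elif (a.source, a.target) == (b.target, b.source) and a.relation != ALLEN_INVERSE[b.relation]:
                conflicts.append((a, b))
    from .allen_reasoner import check_consistency  # cycle-free at call time

    ok, culprits = check_consistency(graph)
    if not ok:
        conflicts.extend(culprits)
    graph.consistency_status = "consistent" if not conflicts else "inconsistent"
    return {"consistent": not conflicts, "conflicts": conflicts}
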
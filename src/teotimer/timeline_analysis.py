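"""Resolved timelines and cross-report comparison of adverse-event sequences.

After reasoning, each report's events can be laid out on a timeline anchored at
the vaccination event, with every date-resolved event at its calendar-day
offset from the anchor. Timelines from different reports are then comparable
by canonical ontology term (never by surface string) along the three patterns
that matter for time-trend reading of adverse events:

(i)   shared symptoms occurring at different day offsets,
(ii)  different per-report frequencies of a symptom,
(iii) pairs of symptoms occurring in opposite orders in different reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .allen_reasoner import ConstraintNetwork, infer_dates, propagate_constraints
from .errors import AnchorSelectionError, InvalidInputError, NotFoundError
from .ontology_annotation import _canonical_of
from .temporal_model import Granularity, TemporalGraph
from .time_normalization import calendar_days_between, to_date

__all__ = [
    "TimelineEntry",
    "Timeline",
    "OrderDifference",
    "CohortComparison",
    "build_timeline",
    "day_offset",
    "compare_timelines",
    "timelines_to_tsv",
]


@dataclass
class TimelineEntry:
    event_id: str
    label: str
    term: Optional[str]  # canonical concept text, None when unmapped
    vocabularies: frozenset
    date: Optional[str]  # normalized partial ISO, None when unresolved
    day_offset: Optional[int]
    unresolved: bool = False

    @property
    def is_vaccine(self) -> bool:
        return "VO" in self.vocabularies

    @property
    def is_symptom(self) -> bool:
        return self.term is not None and not self.is_vaccine


@dataclass
class Timeline:
    """One report's events in resolved temporal order, anchored at vaccination."""

    report_id: str
    anchor: str
    entries: list[TimelineEntry] = field(default_factory=list)

    def entry(self, event_id: str) -> TimelineEntry:
        for e in self.entries:
            if e.event_id == event_id:
                return e
        raise NotFoundError(f"no event {event_id!r} in timeline {self.report_id!r}")

    def symptom_entries(self) -> list[TimelineEntry]:
        return [e for e in self.entries if e.is_symptom]


def _event_term(event) -> tuple[Optional[str], frozenset]:
    vocabularies = frozenset(ref.vocabulary for ref in event.annotations)
    for vocab in ("OAE", "MedDRA", "VO"):  # deterministic preference order
        for ref in event.annotations:
            if ref.vocabulary == vocab:
                return _canonical_of(ref.preferred_label), vocabularies
    return None, vocabularies


def build_timeline(
    graph: TemporalGraph,
    anchor_label_hint: Optional[str] = None,
    report_id: str = "",
) -> Timeline:
    """Place a reasoned graph's events on an anchored timeline.

    The anchor is the earliest event annotated with a VO vaccine term
    (tie-break: narrative order), or the event matching ``anchor_label_hint``.
    Date-resolved events sort by date then narrative order; unresolved events
    are placed after their latest known predecessor and flagged.
    """
    if not getattr(graph, "resolved_dates", None):
        infer_dates(graph)
    resolved = graph.resolved_dates
    narrative_order = {eid: i for i, eid in enumerate(graph.events)}

    def day_date(eid):
        if eid in resolved:
            normalized, gran, _ = resolved[eid]
            if gran == Granularity.DAY:
                return to_date(normalized)
        return None

    vaccine_events = [
        eid for eid in graph.events
        if any(ref.vocabulary == "VO" for ref in graph.events[eid].annotations)
    ]
    anchor = None
    if vaccine_events:
        anchor = min(
            vaccine_events,
            key=lambda e: (
                day_date(e) is None,
                day_date(e) or to_date("9999-12-31"),
                narrative_order[e],
            ),
        )
    elif anchor_label_hint is not None:
        from .ontology_annotation import normalize_label

        hint = normalize_label(anchor_label_hint)
        for eid in graph.events:
            if normalize_label(graph.events[eid].label) == hint:
                anchor = eid
                break
    if anchor is None:
        raise AnchorSelectionError(
            "no vaccination (VO-annotated) event and no usable anchor hint"
        )
    anchor_date = day_date(anchor)

    # partial order for placing unresolved events: propagated 'strictly earlier'
    net = propagate_constraints(ConstraintNetwork.from_graph(graph))
    earlier = lambda a, b: net.get(a, b) <= frozenset({"before", "meets"})

    entries = []
    for eid in graph.events:
        event = graph.events[eid]
        term, vocabularies = _event_term(event)
        date = resolved.get(eid, (None, None, None))[0]
        d = day_date(eid)
        offset = (
            calendar_days_between(anchor_date, d)
            if anchor_date is not None and d is not None
            else None
        )
        entries.append(
            TimelineEntry(
                event_id=eid,
                label=event.label,
                term=term,
                vocabularies=vocabularies,
                date=date,
                day_offset=offset,
                unresolved=d is None,
            )
        )

    def sort_key(entry: TimelineEntry):
        d = day_date(entry.event_id)
        if d is not None:
            return (d, 0, narrative_order[entry.event_id])
        preds = [
            day_date(other.event_id)
            for other in entries
            if other.event_id != entry.event_id
            and day_date(other.event_id) is not None
            and earlier(other.event_id, entry.event_id)
        ]
        base = max(preds) if preds else (anchor_date or to_date("0001-01-01"))
        return (base, 1, narrative_order[entry.event_id])

    entries.sort(key=sort_key)
    return Timeline(report_id=report_id, anchor=anchor, entries=entries)


def day_offset(timeline: Timeline, event_id: str) -> Optional[int]:
    """Calendar-day distance of an event from the vaccination anchor."""
    return timeline.entry(event_id).day_offset


@dataclass
class OrderDifference:
    """A symptom pair observed in opposite strict (different-day) orders."""

    first: str
    second: str
    reports_first_then_second: list
    reports_second_then_first: list


@dataclass
class CohortComparison:
    shared_symptom_offsets: dict = field(default_factory=dict)
    frequency_table: dict = field(default_factory=dict)
    order_differences: list = field(default_factory=list)


def compare_timelines(timelines: list[Timeline]) -> CohortComparison:
    """Compare annotated timelines across reports.

    Symptoms are matched by canonical term. ``shared_symptom_offsets`` lists
    day offsets for every term present in at least two reports;
    ``frequency_table`` counts occurrences per report (zeros included);
    ``order_differences`` lists term pairs whose strict day order reverses
    between reports. Output is invariant to the input ordering.
    """
    if not timelines:
        raise InvalidInputError("need at least one timeline")
    for tl in timelines:
        if tl.entries and all(e.term is None for e in tl.entries):
            raise InvalidInputError(
                f"timeline {tl.report_id!r} has no ontology annotations; "
                f"run annotate_events before comparing"
            )
    timelines = sorted(timelines, key=lambda t: t.report_id)
    report_ids = [t.report_id for t in timelines]

    occurrences: dict[str, dict[str, list]] = {}
    for tl in timelines:
        for entry in tl.symptom_entries():
            occurrences.setdefault(entry.term, {}).setdefault(tl.report_id, []).append(
                entry.day_offset
            )

    comparison = CohortComparison()
    for term in sorted(occurrences):
        per_report = occurrences[term]
        comparison.frequency_table[term] = {
            rid: len(per_report.get(rid, [])) for rid in report_ids
        }
        if len(per_report) >= 2:
            comparison.shared_symptom_offsets[term] = [
                (rid, off)
                for rid in report_ids
                for off in per_report.get(rid, [])
                if off is not None
            ]

    # opposite strict orders: compare first occurrences per report
    first_offset: dict[str, dict[str, int]] = {}
    for term, per_report in occurrences.items():
        for rid, offs in per_report.items():
            known = [o for o in offs if o is not None]
            if known:
                first_offset.setdefault(term, {})[rid] = min(known)
    terms = sorted(first_offset)
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            ab, ba = [], []
            for rid in report_ids:
                if rid in first_offset[a] and rid in first_offset[b]:
                    if first_offset[a][rid] < first_offset[b][rid]:
                        ab.append(rid)
                    elif first_offset[a][rid] > first_offset[b][rid]:
                        ba.append(rid)
            if ab and ba:
                comparison.order_differences.append(
                    OrderDifference(
                        first=a,
                        second=b,
                        reports_first_then_second=ab,
                        reports_second_then_first=ba,
                    )
                )
    return comparison


def timelines_to_tsv(timelines: list[Timeline]) -> str:
    """Flat event-sequence export (report_id, term, day_offset) for
    LifeFlow-style sequence visualization tools."""
    lines = ["report_id\tterm\tday_offset"]
    for tl in timelines:
        for entry in tl.entries:
            term = entry.term if entry.term is not None else entry.label
            off = "" if entry.day_offset is None else str(entry.day_offset)
            lines.append(f"{tl.report_id}\t{term}\t{off}")
    return "\n".join(lines) + "\n"
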
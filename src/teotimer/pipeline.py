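"""End-to-end wiring: report record -> temporal graph -> reasoned timeline.

The narrative annotation list of a :class:`~teotimer.rdf_io.ReportRecord` is
compiled into a :class:`~teotimer.temporal_model.TemporalGraph`, term-annotated
against the lexicon, reasoned over (date inference + constraint propagation)
and laid out as an anchored :class:`~teotimer.timeline_analysis.Timeline`.
"""

from __future__ import annotations

from typing import Optional

from .errors import StructuralError
from .ontology_annotation import Lexicon, annotate_events
from .allen_reasoner import infer_dates
from .rdf_io import ReportRecord
from .temporal_model import (
    Event,
    TemporalGraph,
    TimeInterval,
    assert_relation,
    attach_time,
    validate_graph,
)
from .time_normalization import (
    NormalizationContext,
    parse_duration_expression,
    parse_time_expression,
    resolve_partial_date,
    to_date,
)
from .timeline_analysis import Timeline, build_timeline

__all__ = ["context_from_record", "graph_from_report", "process_report"]


def context_from_record(record: ReportRecord) -> NormalizationContext:
    """Normalization context anchored at the structured vaccination (or onset)
    date — the paper-trail source for completing year-less narrative dates."""
    anchor = None
    for fld in ("vaccinated", "onset"):
        normalized = record.structured_dates.get(fld)
        if normalized and not normalized.startswith("--") and normalized.count("-") == 2:
            anchor = to_date(normalized)
            break
    return NormalizationContext(anchor_date=anchor)


def graph_from_report(
    record: ReportRecord, ctx: Optional[NormalizationContext] = None
) -> TemporalGraph:
    """Compile narrative annotations into a temporal graph.

    Time annotations default to the ``after_anchor`` completion hint: adverse
    events follow the vaccination, so a year-less date that would precede the
    anchor rolls forward one year.
    """
    ctx = ctx or context_from_record(record)
    partial_ctx = NormalizationContext(
        date_order=ctx.date_order, two_digit_year_pivot=ctx.two_digit_year_pivot
    )
    graph = TemporalGraph()
    for ann in record.narrative_annotations:
        kind = ann["kind"]
        if kind == "event":
            eid = ann.get("id") or graph.fresh_id()
            graph.add_existing_event(Event(id=eid, label=ann["text"]))
        elif kind == "time":
            instant = parse_time_expression(ann["text"], partial_ctx)
            instant = resolve_partial_date(
                instant, ctx, ordering_hint=ann.get("hint", "after_anchor")
            )
            attach_time(graph, ann["event"], instant)
        elif kind == "duration":
            duration = parse_duration_expression(ann["text"])
            attach_time(graph, ann["event"], TimeInterval(duration=duration))
        elif kind == "relation":
            offset = ann.get("offset")
            assert_relation(
                graph,
                ann["source"],
                ann["relation"],
                ann["target"],
                offset=parse_duration_expression(offset) if offset else None,
            )
        else:  # pragma: no cover - read_report already screens kinds
            raise StructuralError(f"unknown annotation kind {kind!r}")
    return graph


def process_report(
    record: ReportRecord, lexicon: Optional[Lexicon] = None
) -> tuple[TemporalGraph, Timeline]:
    """Full pipeline for one report: build, annotate, validate, reason, place."""
    graph = graph_from_report(record)
    annotate_events(graph, lexicon)
    validate_graph(graph)
    infer_dates(graph)
    timeline = build_timeline(graph, report_id=record.report_id)
    return graph, timeline
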
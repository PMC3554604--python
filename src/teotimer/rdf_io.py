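"""Turtle serialization of temporal graphs and parsing of report files.

A :class:`~teotimer.temporal_model.TemporalGraph` serializes to RDF following
the TEO triple patterns: events are typed, labelled individuals; time stamps
hang off ``hasTime`` nodes carrying ``hasOrigTime`` / ``hasNormalizedTime`` /
``hasGranularity``; durations carry ``hasValue`` / ``hasUnit``; and an
offset-bearing temporal relation is reified as an OWL annotated axiom
(``owl:annotatedSource`` / ``owl:annotatedProperty`` / ``owl:annotatedTarget``
plus ``hasTimeOffset`` to a Duration node).

Serialization is canonical: no blank nodes (axiom and time nodes get skolem
IRIs derived from their owners), triples emitted in sorted order — so
write -> read -> write is byte-identical and golden-file tests are stable.
Normalized times serialize as ``xsd:date`` / ``xsd:gYearMonth`` / ``xsd:gYear``
matching their granularity, never fabricating precision.

The semi-structured report side of the package reads a documented JSON dialect
(structured fields plus a narrative annotation list) via :func:`read_report`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

from rdflib import Graph as RDFGraph
from rdflib import Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import InvalidInputError, ParseError, StructuralError
from .temporal_model import (
    Duration,
    Event,
    Granularity,
    TemporalAssertion,
    TemporalGraph,
    TermRef,
    TimeInstant,
    TimeInterval,
    precision_of,
)

__all__ = ["TEO", "write_graph", "read_graph", "ReportRecord", "read_report"]

#: Placeholder vocabulary namespace (the published TEO IRIs are not used here).
TEO = Namespace("http://example.org/teo#")
DEFAULT_BASE = "http://example.org/report/"

_ALLEN_PREDICATES = {
    name: TEO[name]
    for name in (
        "before after meets met_by overlaps overlapped_by starts started_by "
        "during contains finishes finished_by equals".split()
    )
}
_PRED_TO_RELATION = {str(v): k for k, v in _ALLEN_PREDICATES.items()}

_TERM_BASES = {
    "OAE": "http://purl.obolibrary.org/obo/",
    "VO": "http://purl.obolibrary.org/obo/",
    "MedDRA": "http://purl.bioontology.org/ontology/MEDDRA/",
}


def _format_value(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else str(value)


def _normalized_literal(normalized: str) -> Literal:
    if normalized.startswith("--"):
        return Literal(normalized)  # year-less partial: plain literal
    prec = precision_of(normalized)
    datatype = {
        Granularity.DAY: XSD.date,
        Granularity.MONTH: XSD.gYearMonth,
        Granularity.YEAR: XSD.gYear,
    }[prec]
    return Literal(normalized, datatype=datatype)


class _Emitter:
    """Collects triples and owns the skolem-IRI scheme."""

    def __init__(self, base: str):
        if not base or not (base.startswith("http://") or base.startswith("https://")):
            raise InvalidInputError(f"base namespace must be an http(s) IRI, got {base!r}")
        if not base.endswith(("/", "#")):
            base += "/"
        self.base = Namespace(base)
        self.graph = RDFGraph()
        self.graph.bind("teo", TEO)
        self.graph.bind("owl", OWL)
        self.graph.bind("rdf", RDF)
        self.graph.bind("rdfs", RDFS)
        self.graph.bind("xsd", XSD)
        self.graph.bind("", self.base)

    def add(self, s, p, o):
        self.graph.add((s, p, o))

    def emit_instant(self, node: URIRef, instant: TimeInstant):
        self.add(node, RDF.type, TEO.TimeInstant)
        self.add(node, TEO.hasOrigTime, Literal(instant.orig_text))
        if instant.normalized is not None:
            self.add(node, TEO.hasNormalizedTime, _normalized_literal(instant.normalized))
        if instant.granularity is not None:
            self.add(node, TEO.hasGranularity, Literal(instant.granularity.value))
        if instant.unresolved:
            self.add(node, TEO.unresolved, Literal(True))

    def emit_duration(self, node: URIRef, duration: Duration):
        self.add(node, RDF.type, TEO.Duration)
        self.add(node, TEO.hasValue, Literal(_format_value(duration.value)))
        self.add(node, TEO.hasUnit, Literal(duration.unit.value))

    def emit_term(self, ref: TermRef) -> URIRef:
        node = URIRef(_TERM_BASES[ref.vocabulary] + ref.identifier)
        self.add(node, RDF.type, TEO.Term)
        self.add(node, TEO.vocabulary, Literal(ref.vocabulary))
        self.add(node, TEO.identifier, Literal(ref.identifier))
        self.add(node, RDFS.label, Literal(ref.preferred_label))
        return node


def write_graph(graph: TemporalGraph, base_namespace: str = DEFAULT_BASE) -> str:
    """Serialize a temporal graph to canonical Turtle."""
    em = _Emitter(base_namespace)
    base = em.base
    for eid in sorted(graph.events):
        event = graph.events[eid]
        node = base[eid]
        em.add(node, RDF.type, TEO.Event)
        em.add(node, RDFS.label, Literal(event.label))
        if event.unmapped:
            em.add(node, TEO.unmapped, Literal(True))
        for ref in event.annotations:
            em.add(node, TEO.hasAnnotation, em.emit_term(ref))
        if isinstance(event.time, TimeInstant):
            tnode = base[f"{eid}-time"]
            em.add(node, TEO.hasTime, tnode)
            em.emit_instant(tnode, event.time)
        elif isinstance(event.time, TimeInterval):
            tnode = base[f"{eid}-time"]
            em.add(node, TEO.hasTime, tnode)
            em.add(tnode, RDF.type, TEO.TimeInterval)
            if event.time.start is not None:
                snode = base[f"{eid}-time-start"]
                em.add(tnode, TEO.hasStartTime, snode)
                em.emit_instant(snode, event.time.start)
            if event.time.end is not None:
                enode = base[f"{eid}-time-end"]
                em.add(tnode, TEO.hasEndTime, enode)
                em.emit_instant(enode, event.time.end)
            if event.time.duration is not None:
                dnode = base[f"{eid}-time-duration"]
                em.add(tnode, TEO.hasDuration, dnode)
                em.emit_duration(dnode, event.time.duration)

    for assertion in graph.assertions:
        src, tgt = base[assertion.source], base[assertion.target]
        singleton = len(assertion.relations) == 1
        if singleton and assertion.provenance == "stated":
            em.add(src, _ALLEN_PREDICATES[assertion.relation], tgt)
        needs_axiom = (
            assertion.offset is not None
            or assertion.provenance == "inferred"
            or not singleton
        )
        if needs_axiom:
            rels = ".".join(sorted(assertion.relations))
            if assertion.offset is not None:
                rels += f"-{_format_value(assertion.offset.value)}{assertion.offset.unit.value}"
            anode = base[
                f"axiom-{assertion.source}-{rels}-{assertion.target}-{assertion.provenance}"
            ]
            em.add(anode, RDF.type, OWL.Axiom)
            em.add(anode, OWL.annotatedSource, src)
            em.add(anode, OWL.annotatedTarget, tgt)
            for r in sorted(assertion.relations):
                em.add(anode, OWL.annotatedProperty, _ALLEN_PREDICATES[r])
            if assertion.offset is not None:
                dnode = base[str(anode)[len(str(base)):] + "-offset"]
                em.add(anode, TEO.hasTimeOffset, dnode)
                em.emit_duration(dnode, assertion.offset)
            if assertion.provenance == "inferred":
                em.add(anode, TEO.provenance, Literal("inferred"))

    for s, p, o in getattr(graph, "opaque_triples", []) or []:
        em.add(s, p, o)

    return _canonical_turtle(em.graph)


def _canonical_turtle(g: RDFGraph) -> str:
    nm = g.namespace_manager
    lines = []
    for prefix, ns in sorted(g.namespaces(), key=lambda x: x[0]):
        if prefix in ("", "teo", "owl", "rdf", "rdfs", "xsd"):
            lines.append(f"@prefix {prefix}: <{ns}> .")
    lines.append("")
    triples = sorted(
        ((s.n3(nm), p.n3(nm), o.n3(nm)) for s, p, o in g),
        key=lambda t: (t[0], t[1] != "rdf:type", t[1], t[2]),
    )
    current = None
    for s, p, o in triples:
        if s != current:
            if current is not None:
                lines[-1] = lines[-1][:-2] + " ."
            lines.append(f"{s} {p} {o} ;")
            current = s
        else:
            lines.append(f"    {p} {o} ;")
    if triples:
        lines[-1] = lines[-1][:-2] + " ."
    lines.append("")
    return "\n".join(lines)


def _local_name(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            iri = iri.rsplit(sep, 1)[1]
    return iri


def _read_instant(g: RDFGraph, node) -> TimeInstant:
    orig = g.value(node, TEO.hasOrigTime)
    normalized = g.value(node, TEO.hasNormalizedTime)
    granularity = g.value(node, TEO.hasGranularity)
    unresolved = bool(g.value(node, TEO.unresolved))
    return TimeInstant(
        orig_text=str(orig) if orig is not None else "",
        normalized=str(normalized) if normalized is not None else None,
        granularity=str(granularity) if granularity is not None else None,
        unresolved=unresolved,
    )


def _read_duration(g: RDFGraph, node) -> Duration:
    value = g.value(node, TEO.hasValue)
    unit = g.value(node, TEO.hasUnit)
    if value is None or unit is None:
        raise StructuralError(f"duration node {node} lacks hasValue/hasUnit")
    return Duration(value=float(str(value)), unit=Granularity(str(unit)))


def _read_term(g: RDFGraph, node) -> TermRef:
    return TermRef(
        vocabulary=str(g.value(node, TEO.vocabulary)),
        identifier=str(g.value(node, TEO.identifier)),
        preferred_label=str(g.value(node, RDFS.label)),
    )


def read_graph(doc: str) -> TemporalGraph:
    """Parse a Turtle document back into a TemporalGraph (inverse of
    :func:`write_graph`): ``read_graph(write_graph(g))`` is structurally ``g``."""
    g = RDFGraph()
    try:
        g.parse(data=doc, format="turtle")
    except Exception as exc:  # rdflib raises several parser error types
        raise ParseError(f"not valid Turtle: {exc}") from None

    out = TemporalGraph()
    max_counter = 0
    for subj in sorted(g.subjects(RDF.type, TEO.Event), key=str):
        eid = _local_name(str(subj))
        label = g.value(subj, RDFS.label)
        annotations = [
            _read_term(g, t) for t in sorted(g.objects(subj, TEO.hasAnnotation), key=str)
        ]
        event = Event(
            id=eid,
            label=str(label) if label is not None else eid,
            annotations=annotations,
            unmapped=bool(g.value(subj, TEO.unmapped)),
        )
        tnode = g.value(subj, TEO.hasTime)
        if tnode is not None:
            if (tnode, RDF.type, TEO.TimeInstant) in g:
                event.time = _read_instant(g, tnode)
            elif (tnode, RDF.type, TEO.TimeInterval) in g:
                start = g.value(tnode, TEO.hasStartTime)
                end = g.value(tnode, TEO.hasEndTime)
                dur = g.value(tnode, TEO.hasDuration)
                event.time = TimeInterval(
                    start=_read_instant(g, start) if start is not None else None,
                    end=_read_instant(g, end) if end is not None else None,
                    duration=_read_duration(g, dur) if dur is not None else None,
                )
        out.add_existing_event(event)
        if eid.startswith("event") and eid[5:].isdigit():
            max_counter = max(max_counter, int(eid[5:]))
    out._counter = max_counter

    # axiom-reified assertions (offset-bearing, inferred, or disjunctive)
    axiom_covered = set()
    for anode in sorted(g.subjects(RDF.type, OWL.Axiom), key=str):
        src = g.value(anode, OWL.annotatedSource)
        tgt = g.value(anode, OWL.annotatedTarget)
        if src is None or tgt is None:
            raise StructuralError(f"axiom node {anode} missing annotatedSource/Target")
        relations = frozenset(
            _PRED_TO_RELATION[str(p)] for p in g.objects(anode, OWL.annotatedProperty)
        )
        if not relations:
            raise StructuralError(f"axiom node {anode} has no annotatedProperty")
        offset_node = g.value(anode, TEO.hasTimeOffset)
        provenance = str(g.value(anode, TEO.provenance) or "stated")
        assertion = TemporalAssertion(
            source=_local_name(str(src)),
            relations=relations,
            target=_local_name(str(tgt)),
            offset=_read_duration(g, offset_node) if offset_node is not None else None,
            provenance=provenance,
        )
        out.assertions.append(assertion)
        if len(relations) == 1 and provenance == "stated":
            axiom_covered.add((str(src), next(iter(relations)), str(tgt)))

    # plain relation triples not already covered by an axiom
    for s, p, o in sorted(g, key=lambda t: tuple(map(str, t))):
        rel = _PRED_TO_RELATION.get(str(p))
        if rel is None or (str(s), rel, str(o)) in axiom_covered:
            continue
        out.assertions.append(
            TemporalAssertion(
                source=_local_name(str(s)),
                relations=frozenset({rel}),
                target=_local_name(str(o)),
                provenance="stated",
            )
        )

    missing = sorted(
        {a.source for a in out.assertions if a.source not in out.events}
        | {a.target for a in out.assertions if a.target not in out.events}
    )
    if missing:
        raise StructuralError(
            f"assertions reference undeclared events: {', '.join(missing)}",
            missing=missing,
        )
    return out


# --- semi-structured report files ----------------------------------------------

STRUCTURED_DATE_FIELDS = ("vaccinated", "onset", "submitted", "entered")
ANNOTATION_KINDS = ("event", "time", "duration", "relation")


@dataclass
class ReportRecord:
    """A parsed semi-structured adverse-event report.

    ``structured_dates`` maps field names to normalized partial ISO dates;
    ``narrative_annotations`` preserves the annotation list in document order.
    """

    report_id: str
    age: Optional[dict] = None
    sex: Optional[str] = None
    structured_dates: dict = field(default_factory=dict)
    vaccines: list = field(default_factory=list)
    symptoms: list = field(default_factory=list)
    narrative_annotations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def read_report(source: Union[str, dict]) -> ReportRecord:
    """Read a report in the documented JSON dialect.

    ``source`` may be a path, a JSON string, or an already-decoded dict.
    A missing ``report_id`` is a structural error; unknown fields are kept and
    warned about, never dropped.
    """
    from .time_normalization import NormalizationContext, parse_time_expression

    if isinstance(source, dict):
        data = source
    else:
        text = source
        if not str(source).lstrip().startswith("{"):
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"report is not valid JSON: {exc}") from None

    if "report_id" not in data or not data["report_id"]:
        raise StructuralError("report lacks a report_id", missing=["report_id"])

    record = ReportRecord(report_id=str(data["report_id"]))
    known = {"report_id", "age", "sex", "structured_dates", "vaccines",
             "symptoms", "narrative_annotations"}
    for key in data:
        if key not in known and not key.startswith("_"):  # _fields are comments
            record.warnings.append(f"unknown field {key!r} kept verbatim")

    record.age = data.get("age")
    record.sex = data.get("sex")
    record.vaccines = list(data.get("vaccines", []))
    record.symptoms = list(data.get("symptoms", []))

    ctx = NormalizationContext()
    for name, value in (data.get("structured_dates") or {}).items():
        if name not in STRUCTURED_DATE_FIELDS:
            record.warnings.append(f"unknown structured date field {name!r} kept")
        instant = parse_time_expression(str(value), ctx)
        record.structured_dates[name] = instant.normalized

    for i, ann in enumerate(data.get("narrative_annotations") or []):
        kind = ann.get("kind")
        if kind not in ANNOTATION_KINDS:
            raise StructuralError(
                f"annotation {i} has unknown kind {kind!r}; expected {ANNOTATION_KINDS}"
            )
        record.narrative_annotations.append(dict(ann))
    return record
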
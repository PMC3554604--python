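"""Qualitative and quantitative temporal inference over a report's event graph.

Two complementary mechanisms recover the orderings and dates a report leaves
implicit:

* **Qualitative**: Allen's interval algebra. The thirteen base relations are
  defined by the order of interval endpoints; composition is computed by
  composing endpoint (point-algebra) constraints, and a path-consistency pass
  (PC-1 iteration to fixpoint) tightens every pairwise relation set through
  each intermediate event, detecting inconsistencies as emptied edges.
* **Quantitative**: calendar arithmetic along offset-bearing relation chains
  ("eighteen days after vaccination ... 2 wks later"), anchored at events with
  known dates, yielding concrete dates at the coarsest granularity seen along
  the chain.

Events are treated as intervals; an event with a single time stamp is a
zero-width interval, so date-resolved events compare by point algebra
({before, equals, after}) at the coarser of the two granularities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from .errors import ConflictError, InconsistencyError, InvalidInputError, NotFoundError
from .temporal_model import (
    ALLEN_INVERSE,
    ALLEN_RELATIONS,
    Duration,
    Granularity,
    TemporalGraph,
    TimeInstant,
    TimeInterval,
    truncate_normalized,
)
from .time_normalization import add_duration_to_date, to_date

__all__ = [
    "invert_relation",
    "compose_relations",
    "composition_table",
    "relation_from_endpoints",
    "ConstraintNetwork",
    "propagate_constraints",
    "check_consistency",
    "infer_dates",
    "derive_relation",
]

FULL_SET = frozenset(ALLEN_RELATIONS)


def invert_relation(relation: str) -> str:
    """The converse relation: inv(before) = after, inv(equals) = equals."""
    try:
        return ALLEN_INVERSE[relation]
    except KeyError:
        raise InvalidInputError(f"unknown Allen relation {relation!r}") from None


# --- endpoint semantics -------------------------------------------------------
# Each base relation is characterized by the 2x2 matrix of point relations
# between the endpoints of A = [a-, a+] and B = [b-, b+]. The matrices are
# derived from one canonical placement per relation.

_CANONICAL = {
    "before": ((0, 1), (2, 3)),
    "meets": ((0, 1), (1, 2)),
    "overlaps": ((0, 2), (1, 3)),
    "starts": ((0, 1), (0, 2)),
    "during": ((1, 2), (0, 3)),
    "finishes": ((1, 3), (0, 3)),
    "equals": ((0, 1), (0, 1)),
}


def _cmp(x, y) -> str:
    return "<" if x < y else ("=" if x == y else ">")


def _matrix(a, b):
    (as_, ae), (bs, be) = a, b
    return (_cmp(as_, bs), _cmp(as_, be), _cmp(ae, bs), _cmp(ae, be))


_REL_MATRIX: dict[str, tuple] = {}
for _name, (_a, _b) in _CANONICAL.items():
    _REL_MATRIX[_name] = _matrix(_a, _b)
    _REL_MATRIX[ALLEN_INVERSE[_name]] = _matrix(_b, _a)
_MATRIX_REL = {m: r for r, m in _REL_MATRIX.items()}


def relation_from_endpoints(a_start, a_end, b_start, b_end) -> str:
    """The base relation between proper intervals given concrete endpoints."""
    if not (a_start < a_end and b_start < b_end):
        raise InvalidInputError("intervals must have start < end")
    return _MATRIX_REL[_matrix((a_start, a_end), (b_start, b_end))]


# --- composition via point algebra --------------------------------------------

_PA_ALL = frozenset("<=>")
_PA_COMPOSE = {
    ("<", "<"): frozenset("<"), ("<", "="): frozenset("<"), ("<", ">"): _PA_ALL,
    ("=", "<"): frozenset("<"), ("=", "="): frozenset("="), ("=", ">"): frozenset(">"),
    (">", "<"): _PA_ALL, (">", "="): frozenset(">"), (">", ">"): frozenset(">"),
}


def _pa_compose_sets(s1: frozenset, s2: frozenset) -> frozenset:
    out = set()
    for x in s1:
        for y in s2:
            out |= _PA_COMPOSE[(x, y)]
    return frozenset(out)


def _compose_base(r1: str, r2: str) -> frozenset:
    m1, m2 = _REL_MATRIX[r1], _REL_MATRIX[r2]
    # point constraints A-endpoints vs C-endpoints, composed through both
    # B endpoints and intersected
    idx = {("s", "s"): 0, ("s", "e"): 1, ("e", "s"): 2, ("e", "e"): 3}
    constraint = {}
    for x in ("s", "e"):      # endpoint of A
        for z in ("s", "e"):  # endpoint of C
            possible = _PA_ALL
            for y in ("s", "e"):  # endpoint of B
                via = _pa_compose_sets(
                    frozenset(m1[idx[(x, y)]]), frozenset(m2[idx[(y, z)]])
                )
                possible &= via
            constraint[(x, z)] = possible
    return frozenset(
        r3
        for r3, m3 in _REL_MATRIX.items()
        if all(m3[idx[(x, z)]] in constraint[(x, z)] for x in "se" for z in "se")
    )


_COMPOSITION: Optional[dict] = None


def composition_table() -> dict:
    """The full 13x13 Allen composition table, built once from endpoint semantics."""
    global _COMPOSITION
    if _COMPOSITION is None:
        _COMPOSITION = {
            (r1, r2): _compose_base(r1, r2)
            for r1 in ALLEN_RELATIONS
            for r2 in ALLEN_RELATIONS
        }
    return _COMPOSITION


def compose_relations(r1: str, r2: str) -> frozenset:
    """Composition of two base relations: the set of relations A may bear to C
    when A r1 B and B r2 C."""
    if r1 not in ALLEN_RELATIONS or r2 not in ALLEN_RELATIONS:
        raise InvalidInputError(f"unknown Allen relation in ({r1!r}, {r2!r})")
    return composition_table()[(r1, r2)]


def _compose_sets(s1: frozenset, s2: frozenset) -> frozenset:
    if s1 == FULL_SET and s2 == FULL_SET:
        return FULL_SET
    table = composition_table()
    out = set()
    for r1 in s1:
        for r2 in s2:
            out |= table[(r1, r2)]
            if len(out) == 13:
                return FULL_SET
    return frozenset(out)


# --- constraint networks ------------------------------------------------------


@dataclass
class ConstraintNetwork:
    """Working structure for propagation: a complete graph of relation sets.

    Only edges (i, j) with i < j (sorted node order) are stored; the converse
    direction is implied. ``tightened`` records edges strictly narrowed by
    propagation (inferred knowledge).
    """

    nodes: list[str]
    edges: dict[tuple[str, str], frozenset] = field(default_factory=dict)
    tightened: set[tuple[str, str]] = field(default_factory=set)

    def get(self, i: str, j: str) -> frozenset:
        if i == j:
            return frozenset({"equals"})
        if (i, j) in self.edges:
            return self.edges[(i, j)]
        if (j, i) in self.edges:
            return frozenset(ALLEN_INVERSE[r] for r in self.edges[(j, i)])
        return FULL_SET

    def set(self, i: str, j: str, rels: frozenset) -> None:
        if i == j:
            return
        if (j, i) in self.edges:
            self.edges[(j, i)] = frozenset(ALLEN_INVERSE[r] for r in rels)
        else:
            self.edges[(i, j)] = frozenset(rels)

    def copy(self) -> "ConstraintNetwork":
        return ConstraintNetwork(
            nodes=list(self.nodes), edges=dict(self.edges), tightened=set(self.tightened)
        )

    @classmethod
    def from_graph(cls, graph: TemporalGraph, include_dates: bool = False) -> "ConstraintNetwork":
        net = cls(nodes=sorted(graph.events))
        for a in graph.assertions:
            current = net.get(a.source, a.target)
            new = current & a.relations
            if not new:
                raise InconsistencyError(
                    f"assertion {a.source} {sorted(a.relations)} {a.target} "
                    f"contradicts accumulated constraint {sorted(current)}",
                    culprits=[(a.source, a.target)],
                )
            net.set(a.source, a.target, new)
        if include_dates and getattr(graph, "resolved_dates", None):
            for i, j in itertools.combinations(net.nodes, 2):
                ds = _date_relation_set(graph, i, j)
                if ds is None:
                    continue
                new = net.get(i, j) & ds
                if not new:
                    raise InconsistencyError(
                        f"resolved dates of {i} and {j} contradict stated relations",
                        culprits=[(i, j)],
                    )
                net.set(i, j, new)
        return net


def propagate_constraints(net: ConstraintNetwork) -> ConstraintNetwork:
    """Path-consistency closure (PC-1): tighten every edge through every
    intermediate node until fixpoint. Monotone and idempotent.

    Raises :class:`InconsistencyError` citing the triangle (i, j, k) whose
    composition empties an edge.
    """
    out = net.copy()
    nodes = sorted(out.nodes)
    changed = True
    while changed:
        changed = False
        for k in nodes:
            for i in nodes:
                if i == k:
                    continue
                for j in nodes:
                    if j in (i, k):
                        continue
                    rij = out.get(i, j)
                    composed = _compose_sets(out.get(i, k), out.get(k, j))
                    new = rij & composed
                    if new != rij:
                        if not new:
                            raise InconsistencyError(
                                f"no relation between {i} and {j} is compatible "
                                f"with the path through {k}",
                                culprits=[(i, k, j)],
                            )
                        out.set(i, j, new)
                        out.tightened.add((i, j) if i < j else (j, i))
                        changed = True
    return out


def _scenario_search(net: ConstraintNetwork) -> Optional[dict]:
    """Backtracking search for a consistent atomic scenario (small networks)."""
    try:
        pc = propagate_constraints(net)
    except InconsistencyError:
        return None
    pending = [
        (i, j)
        for i, j in itertools.combinations(sorted(pc.nodes), 2)
        if len(pc.get(i, j)) > 1
    ]
    if not pending:
        return {(i, j): pc.get(i, j) for i, j in itertools.combinations(sorted(pc.nodes), 2)}
    pending.sort(key=lambda e: len(pc.get(*e)))
    i, j = pending[0]
    for r in sorted(pc.get(i, j)):
        trial = pc.copy()
        trial.set(i, j, frozenset({r}))
        result = _scenario_search(trial)
        if result is not None:
            return result
    return None


def check_consistency(graph: TemporalGraph) -> tuple[bool, list]:
    """Path consistency, plus a complete backtracking decision for graphs of
    at most 12 events. Returns (consistent, culprit pairs/triangles)."""
    try:
        net = ConstraintNetwork.from_graph(graph, include_dates=True)
        propagate_constraints(net)
    except InconsistencyError as exc:
        return False, exc.culprits
    if len(graph.events) <= 12:
        if _scenario_search(ConstraintNetwork.from_graph(graph, include_dates=True)) is None:
            return False, [tuple(sorted(graph.events))]
    return True, []


# --- quantitative (calendar) inference ----------------------------------------

_UNIT_GRANULARITY = {
    "second": Granularity.DAY,
    "minute": Granularity.DAY,
    "hour": Granularity.DAY,
    "day": Granularity.DAY,
    "week": Granularity.DAY,  # weeks are exactly 7 days
    "month": Granularity.MONTH,
    "year": Granularity.YEAR,
}


def _stated_instant(event) -> Optional[TimeInstant]:
    t = event.time
    if isinstance(t, TimeInstant):
        return t
    if isinstance(t, TimeInterval) and t.start is not None:
        return t.start
    return None


def _offset_steps(graph: TemporalGraph):
    """Directed date-arithmetic steps (from_event, to_event, duration, sign)."""
    steps = []
    for a in graph.assertions:
        if a.offset is None or len(a.relations) != 1:
            continue
        r = a.relation
        if r in ("after", "met_by"):
            # source happened offset after target
            steps.append((a.target, a.source, a.offset, +1, a))
            steps.append((a.source, a.target, a.offset, -1, a))
        elif r in ("before", "meets"):
            steps.append((a.source, a.target, a.offset, +1, a))
            steps.append((a.target, a.source, a.offset, -1, a))
    return steps


def _shift(normalized: str, gran: Granularity, dur: Duration, sign: int):
    """Shift a (possibly coarse) normalized value; returns (normalized, granularity)."""
    out_gran = Granularity.coarsest(gran, _UNIT_GRANULARITY[dur.unit.value])
    parts = normalized.split("-")
    rep = to_date(
        "-".join(parts + ["01"] * (3 - len(parts)))  # fill to a representative day
    )
    shifted = add_duration_to_date(rep, dur, sign)
    return truncate_normalized(shifted.isoformat(), out_gran), out_gran


def infer_dates(graph: TemporalGraph) -> TemporalGraph:
    """Resolve calendar dates for every event reachable from a date-anchored
    event through offset-bearing before/after chains.

    Results go to ``graph.resolved_dates`` as
    ``event_id -> (normalized, granularity, provenance)``; stated time stamps
    are never modified. Two chains implying different dates for one event
    raise :class:`ConflictError` listing both derivations.
    """
    resolved: dict[str, tuple[str, Granularity, str]] = {}
    derivations: dict[str, list[str]] = {}
    for eid in sorted(graph.events):
        inst = _stated_instant(graph.events[eid])
        if inst is not None and inst.is_complete:
            resolved[eid] = (inst.normalized, inst.granularity, "stated")
            derivations[eid] = [f"{eid}: stated {inst.normalized}"]

    steps = _offset_steps(graph)
    frontier = sorted(resolved)
    while frontier:
        eid = frontier.pop()
        for src, dst, dur, sign, assertion in steps:
            if src != eid:
                continue
            base_norm, base_gran, _ = resolved[src]
            new_norm, new_gran = _shift(base_norm, base_gran, dur, sign)
            trace = derivations[src] + [
                f"{dst}: {src} {'+' if sign > 0 else '-'} {dur} -> {new_norm}"
            ]
            if dst in resolved:
                old_norm, old_gran, _ = resolved[dst]
                cmp_gran = Granularity.coarsest(old_gran, new_gran)
                if truncate_normalized(old_norm, cmp_gran) != truncate_normalized(
                    new_norm, cmp_gran
                ):
                    raise ConflictError(
                        f"two derivations disagree on the date of {dst!r}: "
                        f"{old_norm} vs {new_norm}",
                        derivations=[derivations[dst], trace],
                    )
                if new_gran.rank < old_gran.rank:  # strictly finer, consistent
                    resolved[dst] = (new_norm, new_gran, "inferred")
                    derivations[dst] = trace
                    frontier.append(dst)
            else:
                resolved[dst] = (new_norm, new_gran, "inferred")
                derivations[dst] = trace
                frontier.append(dst)

    graph.resolved_dates = resolved
    graph.date_derivations = derivations
    return graph


def _date_relation_set(graph: TemporalGraph, e1: str, e2: str) -> Optional[frozenset]:
    resolved = getattr(graph, "resolved_dates", None) or {}
    if e1 not in resolved or e2 not in resolved:
        return None
    n1, g1, _ = resolved[e1]
    n2, g2, _ = resolved[e2]
    gran = Granularity.coarsest(g1, g2)
    t1, t2 = truncate_normalized(n1, gran), truncate_normalized(n2, gran)
    if t1 < t2:
        return frozenset({"before"})
    if t1 > t2:
        return frozenset({"after"})
    # equal at the comparison granularity: coarse stamps cannot order the pair
    return frozenset({"before", "equals", "after"})


def derive_relation(graph: TemporalGraph, e1: str, e2: str) -> frozenset:
    """The tightest relation set between two events the graph supports.

    Combines the date-implied point relation (when both events have resolved
    dates) with the path-consistency closure of the stated assertions; in a
    consistent graph the result never contradicts a stated relation.
    """
    for eid in (e1, e2):
        if eid not in graph.events:
            raise NotFoundError(f"no event with id {eid!r}")
    if e1 == e2:
        return frozenset({"equals"})
    if not getattr(graph, "resolved_dates", None):
        infer_dates(graph)
    net = propagate_constraints(ConstraintNetwork.from_graph(graph))
    qualitative = net.get(e1, e2)
    date_set = _date_relation_set(graph, e1, e2)
    if date_set is None:
        return qualitative
    combined = qualitative & date_set
    if not combined:
        raise InconsistencyError(
            f"dates of {e1} and {e2} contradict the stated temporal relations",
            culprits=[(e1, e2)],
        )
    return combined
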
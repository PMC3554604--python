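"""Independent brute-force oracles used to validate the reasoner.

These deliberately avoid the package's composition/propagation code paths:
relations are read off concrete integer endpoint placements, compositions are
collected by enumerating all qualitative placements of three intervals, and
date chains are recomputed with plain ``datetime`` arithmetic.
"""

from __future__ import annotations

import datetime as dt
import itertools

ALLEN = (
    "before", "after", "meets", "met_by", "overlaps", "overlapped_by",
    "starts", "started_by", "during", "contains", "finishes", "finished_by",
    "equals",
)


def relation_of(a: tuple, b: tuple) -> str:
    """Base relation between concrete proper intervals, by endpoint comparison."""
    (as_, ae), (bs, be) = a, b
    if ae < bs:
        return "before"
    if be < as_:
        return "after"
    if ae == bs:
        return "meets"
    if be == as_:
        return "met_by"
    if as_ == bs and ae == be:
        return "equals"
    if as_ == bs:
        return "starts" if ae < be else "started_by"
    if ae == be:
        return "finishes" if as_ > bs else "finished_by"
    if bs < as_ and ae < be:
        return "during"
    if as_ < bs and be < ae:
        return "contains"
    return "overlaps" if as_ < bs else "overlapped_by"


def brute_force_composition_table() -> dict:
    """All 169 composition cells from integer assignments of 6 endpoints.

    Six endpoints over values 0..5 realize every qualitative configuration of
    three proper intervals.
    """
    table = {(r1, r2): set() for r1 in ALLEN for r2 in ALLEN}
    pairs = list(itertools.combinations(range(6), 2))
    for a in pairs:
        for b in pairs:
            r1 = relation_of(a, b)
            for c in pairs:
                table[(r1, relation_of(b, c))].add(relation_of(a, c))
    return {k: frozenset(v) for k, v in table.items()}


def enumerate_scenarios(nodes: list, edges: dict, max_value: int = 9) -> list:
    """All concrete placements (endpoints in 0..max_value) satisfying the
    singleton constraints in ``edges`` (keys (i, j) with i, j in nodes;
    missing edges unconstrained). Returns a list of {node: (start, end)}.

    n intervals have 2n endpoints, so a network is satisfiable iff it is
    satisfiable with endpoint values in 0..2n-1 <= max_value.
    """
    pairs = list(itertools.combinations(range(max_value + 1), 2))
    solutions = []

    def constraint(i, j):
        if (i, j) in edges:
            return edges[(i, j)]
        return None

    def backtrack(placed: dict, remaining: list):
        if not remaining:
            solutions.append(dict(placed))
            return
        node = remaining[0]
        for interval in pairs:
            ok = True
            for other, other_iv in placed.items():
                want = constraint(other, node)
                if want is not None and relation_of(other_iv, interval) not in want:
                    ok = False
                    break
                want_rev = constraint(node, other)
                if want_rev is not None and relation_of(interval, other_iv) not in want_rev:
                    ok = False
                    break
            if ok:
                placed[node] = interval
                backtrack(placed, remaining[1:])
                del placed[node]

    backtrack({}, list(nodes))
    return solutions


def feasible_relations(nodes: list, edges: dict, max_value: int = 9) -> dict:
    """The minimal network by enumeration: for every node pair, the set of
    relations realized in some satisfying concrete placement."""
    out = {pair: set() for pair in itertools.combinations(nodes, 2)}
    for solution in enumerate_scenarios(nodes, edges, max_value):
        for i, j in out:
            out[(i, j)].add(relation_of(solution[i], solution[j]))
    return {k: frozenset(v) for k, v in out.items()}


def calendar_chain(anchor: dt.date, *day_offsets: int) -> dt.date:
    """Plain-datetime oracle for summed day offsets along a chain."""
    return anchor + dt.timedelta(days=sum(day_offsets))
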
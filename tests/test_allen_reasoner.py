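import datetime as dt
import itertools
import random

import pytest

from teotimer.allen_reasoner import (
    ConstraintNetwork,
    compose_relations,
    composition_table,
    derive_relation,
    infer_dates,
    invert_relation,
    propagate_constraints,
    relation_from_endpoints,
)
from teotimer.errors import ConflictError, InconsistencyError, InvalidInputError
from teotimer.temporal_model import (
    ALLEN_INVERSE,
    ALLEN_RELATIONS,
    Duration,
    Granularity,
    TemporalGraph,
    TimeInstant,
    add_event,
    assert_relation,
    attach_time,
)

from oracles import (
    brute_force_composition_table,
    enumerate_scenarios,
    feasible_relations,
    relation_of,
)


class TestInversion:
    @pytest.mark.parametrize(
        "relation,inverse",
        [("before", "after"), ("equals", "equals"), ("meets", "met_by"),
         ("during", "contains"), ("starts", "started_by")],
    )
    def test_known_pairs(self, relation, inverse):
        assert invert_relation(relation) == inverse

    def test_involution(self):
        for r in ALLEN_RELATIONS:
            assert invert_relation(invert_relation(r)) == r

    def test_unknown_relation(self):
        with pytest.raises(InvalidInputError):
            invert_relation("near")


class TestComposition:
    def test_all_169_cells_match_brute_force_oracle(self):
        oracle = brute_force_composition_table()
        table = composition_table()
        assert set(table) == set(oracle)
        for key in oracle:
            assert table[key] == oracle[key], key

    def test_before_before_is_before(self):
        assert compose_relations("before", "before") == {"before"}

    def test_equals_is_identity(self):
        for r in ALLEN_RELATIONS:
            assert compose_relations("equals", r) == {r}
            assert compose_relations(r, "equals") == {r}

    def test_inverse_law(self):
        table = composition_table()
        for r1, r2 in itertools.product(ALLEN_RELATIONS, repeat=2):
            expected = frozenset(ALLEN_INVERSE[r] for r in table[(r1, r2)])
            assert table[(ALLEN_INVERSE[r2], ALLEN_INVERSE[r1])] == expected

    def test_never_empty(self):
        for cell in composition_table().values():
            assert cell


def _chain_graph(labels_relations):
    g = TemporalGraph()
    events = {}
    for label in {x for pair in labels_relations for x in (pair[0], pair[2])}:
        events[label] = add_event(g, label).id
    for src, rel, tgt in labels_relations:
        assert_relation(g, events[src], rel, events[tgt])
    return g, events


def _scenario_network(rng: random.Random, n: int = 5):
    """Atomic network read off a random concrete placement of n intervals."""
    nodes = [f"n{i}" for i in range(n)]
    placement = {}
    for node in nodes:
        s = rng.randint(0, 7)
        placement[node] = (s, rng.randint(s + 1, 8))
    net = ConstraintNetwork(nodes=nodes)
    for i, j in itertools.combinations(nodes, 2):
        net.set(i, j, frozenset({relation_of(placement[i], placement[j])}))
    return net, placement


class TestPropagation:
    def test_inference_chain_yields_transitive_before(self):
        g, ev = _chain_graph(
            [("vaccination", "before", "fever"),
             ("fever", "before", "vasculitis"),
             ("vasculitis", "before", "hospitalization")]
        )
        net = propagate_constraints(ConstraintNetwork.from_graph(g))
        assert net.get(ev["vaccination"], ev["hospitalization"]) == {"before"}

    def test_direct_contradiction_detected(self):
        g, _ = _chain_graph([("e1", "before", "e2"), ("e2", "before", "e1")])
        with pytest.raises(InconsistencyError):
            propagate_constraints(ConstraintNetwork.from_graph(g))

    def test_idempotent_and_monotone(self):
        rng = random.Random(42)
        for _ in range(25):
            net, _ = _scenario_network(rng)
            # widen some edges so propagation has work to do
            for i, j in itertools.combinations(net.nodes, 2):
                if rng.random() < 0.4:
                    net.set(i, j, frozenset(ALLEN_RELATIONS))
            once = propagate_constraints(net)
            twice = propagate_constraints(once)
            for i, j in itertools.combinations(net.nodes, 2):
                assert once.get(i, j) <= net.get(i, j)  # monotone
                assert twice.get(i, j) == once.get(i, j)  # idempotent

    def test_closure_of_singleton_networks_matches_concrete_oracle(self):
        rng = random.Random(7)
        for _ in range(20):
            net, _ = _scenario_network(rng)
            closed = propagate_constraints(net)
            oracle = feasible_relations(
                net.nodes,
                {(i, j): net.get(i, j) for i, j in itertools.combinations(net.nodes, 2)},
            )
            for pair, want in oracle.items():
                assert closed.get(*pair) == want

    def test_mutated_singleton_networks_agree_with_oracle_on_consistency(self):
        rng = random.Random(11)
        for _ in range(20):
            net, _ = _scenario_network(rng)
            i, j = rng.sample(net.nodes, 2)
            current = next(iter(net.get(i, j)))
            net.set(i, j, frozenset({rng.choice([r for r in ALLEN_RELATIONS if r != current])}))
            edges = {(a, b): net.get(a, b) for a, b in itertools.combinations(net.nodes, 2)}
            oracle_consistent = bool(enumerate_scenarios(net.nodes, edges))
            try:
                propagate_constraints(net)
                pc_consistent = True
            except InconsistencyError:
                pc_consistent = False
            assert pc_consistent == oracle_consistent

    def test_tightened_edges_are_tracked(self):
        g, ev = _chain_graph([("a", "before", "b"), ("b", "before", "c")])
        net = propagate_constraints(ConstraintNetwork.from_graph(g))
        key = tuple(sorted((ev["a"], ev["c"])))
        assert key in net.tightened


class TestInferDates:
    def test_worked_chain(self, mmr_graph):
        infer_dates(mmr_graph)
        dates = {eid: v[0] for eid, v in mmr_graph.resolved_dates.items()}
        # independent calendar oracle
        anchor = dt.date(2006, 7, 6)
        assert dates["event2"] == (anchor + dt.timedelta(days=18)).isoformat()
        assert dates["event4"] == (anchor + dt.timedelta(days=18 + 14)).isoformat()
        assert mmr_graph.resolved_dates["event2"][2] == "inferred"
        assert mmr_graph.resolved_dates["event1"][2] == "stated"

    def test_no_anchor_leaves_graph_unchanged(self):
        g = TemporalGraph()
        a, b = add_event(g, "a"), add_event(g, "b")
        assert_relation(g, b.id, "after", a.id, offset=Duration(3, Granularity.DAY))
        infer_dates(g)
        assert g.resolved_dates == {}

    def test_divergent_chains_conflict(self):
        g = TemporalGraph()
        a = add_event(g, "anchor")
        attach_time(g, a.id, TimeInstant(orig_text="x", normalized="2006-07-06"))
        b = add_event(g, "b")
        assert_relation(g, b.id, "after", a.id, offset=Duration(3, Granularity.DAY))
        assert_relation(g, b.id, "after", a.id, offset=Duration(5, Granularity.DAY))
        with pytest.raises(ConflictError) as exc:
            infer_dates(g)
        assert len(exc.value.derivations) == 2

    def test_chain_equals_summed_offset(self):
        offsets = [3, 8, 2, 11]
        g = TemporalGraph()
        prev = add_event(g, "anchor")
        attach_time(g, prev.id, TimeInstant(orig_text="x", normalized="1990-03-29"))
        for i, off in enumerate(offsets):
            nxt = add_event(g, f"step {i}")
            assert_relation(g, nxt.id, "after", prev.id, offset=Duration(off, Granularity.DAY))
            prev = nxt
        infer_dates(g)
        expected = dt.date(1990, 3, 29) + dt.timedelta(days=sum(offsets))
        assert g.resolved_dates[prev.id][0] == expected.isoformat()

    def test_granularity_coarsens_along_month_offsets(self):
        g = TemporalGraph()
        a = add_event(g, "anchor")
        attach_time(g, a.id, TimeInstant(orig_text="x", normalized="2006-07-06"))
        b = add_event(g, "b")
        assert_relation(g, b.id, "after", a.id, offset=Duration(1, Granularity.MONTH))
        infer_dates(g)
        normalized, gran, _ = g.resolved_dates[b.id]
        assert gran == Granularity.MONTH
        assert normalized == "2006-08"


class TestDeriveRelation:
    def test_dates_order_unstated_events(self, mmr_graph):
        infer_dates(mmr_graph)
        assert derive_relation(mmr_graph, "event4", "event5") == {"before"}
        assert derive_relation(mmr_graph, "event5", "event4") == {"after"}

    def test_self_relation_is_equals(self, mmr_graph):
        assert derive_relation(mmr_graph, "event1", "event1") == {"equals"}

    def test_same_day_events_are_unordered(self, mmr_graph):
        infer_dates(mmr_graph)
        # fever and rash both resolve 18 days after vaccination
        assert derive_relation(mmr_graph, "event2", "event3") == {"before", "equals", "after"}

    def test_unanchored_pair_falls_back_to_propagation(self):
        g, ev = _chain_graph([("a", "before", "b"), ("b", "before", "c")])
        net = propagate_constraints(ConstraintNetwork.from_graph(g))
        assert derive_relation(g, ev["a"], ev["c"]) == net.get(ev["a"], ev["c"])

    def test_inconsistent_graph_raises(self):
        g, ev = _chain_graph([("a", "before", "b"), ("b", "before", "a")])
        with pytest.raises(InconsistencyError):
            derive_relation(g, ev["a"], ev["b"])


def test_relation_from_endpoints_covers_all_13():
    seen = set()
    for a in itertools.combinations(range(5), 2):
        for b in itertools.combinations(range(5), 2):
            seen.add(relation_from_endpoints(*a, *b))
    assert seen == set(ALLEN_RELATIONS)
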
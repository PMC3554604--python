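import copy

import pytest

from teotimer.errors import (
    ConflictError,
    InvalidInputError,
    NotFoundError,
    StructuralError,
)
from teotimer.temporal_model import (
    ALLEN_INVERSE,
    ALLEN_RELATIONS,
    Duration,
    Granularity,
    TemporalAssertion,
    TemporalGraph,
    TermRef,
    TimeInstant,
    TimeInterval,
    add_event,
    assert_relation,
    attach_time,
    validate_graph,
)


class TestEvents:
    def test_add_event_stores_label_verbatim_and_increments_count(self):
        g = TemporalGraph()
        e = add_event(g, "vaccinated w/MMR")
        assert e.label == "vaccinated w/MMR"
        assert e.time is None and e.annotations == []
        n = len(g.events)
        add_event(g, "BRIEF GENERALIZED SEIZURE")
        assert len(g.events) == n + 1

    def test_event_ids_are_unique(self):
        g = TemporalGraph()
        ids = {add_event(g, f"event {i}").id for i in range(20)}
        assert len(ids) == 20

    def test_empty_label_rejected(self):
        with pytest.raises(InvalidInputError):
            add_event(TemporalGraph(), "")

    def test_adding_never_mutates_stored_entities(self):
        g = TemporalGraph()
        e1 = add_event(g, "first")
        snapshot = copy.deepcopy(e1)
        add_event(g, "second")
        assert_relation(g, "event1", "before", "event2")
        assert g.events["event1"] == snapshot


class TestAttachTime:
    def test_orig_text_preserved(self):
        g = TemporalGraph()
        e = add_event(g, "vaccinated w/MMR")
        attach_time(g, e.id, TimeInstant(orig_text="July 6^th^"))
        assert g.events[e.id].time.orig_text == "July 6^th^"

    def test_second_attachment_conflicts(self):
        g = TemporalGraph()
        e = add_event(g, "x")
        attach_time(g, e.id, TimeInstant(orig_text="a"))
        with pytest.raises(ConflictError):
            attach_time(g, e.id, TimeInstant(orig_text="b"))

    def test_unknown_event_not_found(self):
        with pytest.raises(NotFoundError):
            attach_time(TemporalGraph(), "nope", TimeInstant(orig_text="a"))


class TestAssertRelation:
    def test_offset_assertion(self):
        g = TemporalGraph()
        vac = add_event(g, "vaccination")
        fever = add_event(g, "fever")
        a = assert_relation(g, fever.id, "after", vac.id, offset=Duration(18, Granularity.DAY))
        assert a.relation == "after"
        assert a.offset == Duration(18, Granularity.DAY)
        assert a.provenance == "stated"

    def test_offset_free_assertion(self):
        g = TemporalGraph()
        dtp = add_event(g, "DTP")
        seizure = add_event(g, "BRIEF GENERALIZED SEIZURE")
        a = assert_relation(g, seizure.id, "after", dtp.id)
        assert a.offset is None

    def test_strict_self_relation_rejected(self):
        g = TemporalGraph()
        e = add_event(g, "x")
        with pytest.raises(InvalidInputError):
            assert_relation(g, e.id, "before", e.id)

    @pytest.mark.parametrize("relation", ["during", "overlaps", "equals", "starts"])
    def test_offset_requires_gap_relation(self, relation):
        g = TemporalGraph()
        a, b = add_event(g, "a"), add_event(g, "b")
        with pytest.raises(InvalidInputError):
            assert_relation(g, a.id, relation, b.id, offset=Duration(1, Granularity.DAY))

    def test_stated_assertions_are_singletons(self):
        with pytest.raises(InvalidInputError):
            TemporalAssertion(source="a", relations=frozenset({"before", "after"}),
                              target="b", provenance="stated")


class TestValidateGraph:
    def test_worked_case_is_consistent(self, mmr_graph):
        report = validate_graph(mmr_graph)
        assert report["consistent"]
        assert mmr_graph.consistency_status == "consistent"
        assert len(mmr_graph.events) == 5  # count stable under validation

    def test_direct_contradiction_cites_both_assertions(self):
        g = TemporalGraph()
        a, b = add_event(g, "a"), add_event(g, "b")
        x = assert_relation(g, a.id, "before", b.id)
        y = assert_relation(g, b.id, "before", a.id)
        report = validate_graph(g)
        assert not report["consistent"]
        assert (x, y) in report["conflicts"] or (y, x) in report["conflicts"]

    def test_empty_graph_consistent(self):
        assert validate_graph(TemporalGraph())["consistent"]

    def test_dangling_reference_is_structural_error(self):
        g = TemporalGraph()
        add_event(g, "a")
        g.assertions.append(
            TemporalAssertion(source="event1", relations=frozenset({"before"}), target="ghost")
        )
        with pytest.raises(StructuralError) as exc:
            validate_graph(g)
        assert "ghost" in exc.value.missing


class TestTimeEntities:
    def test_interval_needs_at_least_one_field(self):
        with pytest.raises(InvalidInputError):
            TimeInterval()

    def test_interval_start_end_duration_consistency(self):
        start = TimeInstant(orig_text="s", normalized="2006-07-06")
        good_end = TimeInstant(orig_text="e", normalized="2006-07-24")
        TimeInterval(start=start, end=good_end, duration=Duration(18, Granularity.DAY))
        bad_end = TimeInstant(orig_text="e", normalized="2006-07-25")
        with pytest.raises(InvalidInputError):
            TimeInterval(start=start, end=bad_end, duration=Duration(18, Granularity.DAY))

    def test_instant_granularity_must_match_precision(self):
        with pytest.raises(InvalidInputError):
            TimeInstant(orig_text="x", normalized="2006-07", granularity=Granularity.DAY)

    def test_negative_duration_rejected(self):
        with pytest.raises(InvalidInputError):
            Duration(-1, Granularity.DAY)

    def test_unknown_granularity_rejected(self):
        with pytest.raises(InvalidInputError):
            Granularity.from_text("fortnight")


class TestTermRef:
    @pytest.mark.parametrize(
        "vocab,identifier",
        [("OAE", "OAE_0000100"), ("MedDRA", "10022004"), ("VO", "VO_0010711")],
    )
    def test_valid_patterns(self, vocab, identifier):
        TermRef(vocabulary=vocab, identifier=identifier, preferred_label="x")

    @pytest.mark.parametrize(
        "vocab,identifier",
        [("OAE", "10022004"), ("MedDRA", "OAE_0000100"), ("VO", "VO_12"), ("LOINC", "123")],
    )
    def test_invalid_patterns(self, vocab, identifier):
        with pytest.raises(InvalidInputError):
            TermRef(vocabulary=vocab, identifier=identifier, preferred_label="x")


def test_every_relation_has_exactly_one_inverse_and_equals_is_self_inverse():
    assert set(ALLEN_INVERSE) == set(ALLEN_RELATIONS)
    for r, inv in ALLEN_INVERSE.items():
        assert ALLEN_INVERSE[inv] == r
    assert ALLEN_INVERSE["equals"] == "equals"
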
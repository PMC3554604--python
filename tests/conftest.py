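import random

import pytest

from teotimer.cases import engerix_report, mmr_case, mmr_context, synthetic_hep_cohort
from teotimer.ontology_annotation import annotate_events, default_lexicon
from teotimer.temporal_model import (
    ALLEN_RELATIONS,
    Duration,
    Event,
    Granularity,
    TemporalAssertion,
    TemporalGraph,
    TimeInstant,
    TimeInterval,
)


@pytest.fixture
def mmr_graph():
    return mmr_case()


@pytest.fixture
def annotated_mmr_graph():
    return annotate_events(mmr_case())


@pytest.fixture
def mmr_ctx():
    return mmr_context()


@pytest.fixture
def lexicon():
    return default_lexicon()


@pytest.fixture
def engerix_record():
    return engerix_report()


@pytest.fixture
def hep_cohort():
    return synthetic_hep_cohort()


def random_temporal_graph(rng: random.Random, n_events: int = 5) -> TemporalGraph:
    """A structurally varied graph for serialization round-trip tests."""
    lex = default_lexicon()
    surfaces = sorted(lex.entries)
    graph = TemporalGraph()
    for i in range(1, n_events + 1):
        event = Event(id=f"event{i}", label=rng.choice(surfaces) or f"event {i}")
        style = rng.random()
        if style < 0.4:
            event.time = TimeInstant(
                orig_text=f"{rng.randint(1,12):02d}-{rng.randint(1,28):02d}",
                normalized=f"19{rng.randint(90,99)}-{rng.randint(1,12):02d}-{rng.randint(1,28):02d}",
            )
        elif style < 0.55:
            event.time = TimeInstant(orig_text="sometime", normalized=None,
                                     granularity=Granularity.DAY, unresolved=True)
        elif style < 0.7:
            event.time = TimeInterval(
                duration=Duration(rng.randint(1, 30), Granularity(rng.choice(["day", "week"])))
            )
        if rng.random() < 0.6:
            for ref in lex.lookup_all(event.label):
                event.annotations.append(ref)
        if not event.annotations:
            event.unmapped = rng.random() < 0.5
        graph.add_existing_event(event)
    graph._counter = n_events
    ids = sorted(graph.events)
    used_pairs = set()
    for _ in range(rng.randint(0, n_events) if n_events >= 2 else 0):
        src, tgt = rng.sample(ids, 2)
        if (src, tgt) in used_pairs:  # RDF is a set: duplicates would merge
            continue
        used_pairs.add((src, tgt))
        if rng.random() < 0.5:
            graph.assertions.append(
                TemporalAssertion(
                    source=src,
                    relations=frozenset({rng.choice(("before", "after"))}),
                    target=tgt,
                    offset=Duration(rng.randint(1, 21), Granularity.DAY),
                )
            )
        elif rng.random() < 0.5:
            graph.assertions.append(
                TemporalAssertion(
                    source=src,
                    relations=frozenset({rng.choice(ALLEN_RELATIONS)}),
                    target=tgt,
                )
            )
        else:
            rels = frozenset(rng.sample(ALLEN_RELATIONS, rng.randint(2, 4)))
            graph.assertions.append(
                TemporalAssertion(source=src, relations=rels, target=tgt,
                                  provenance="inferred")
            )
    return graph
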